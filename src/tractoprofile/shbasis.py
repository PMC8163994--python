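"""Real even-order spherical-harmonic basis for FODs.

Basis convention (the single dialect used throughout this package)
------------------------------------------------------------------
Coefficients are ordered by degree ``l = 0, 2, 4, ..., lmax`` (even only,
because FODs are antipodally symmetric) and, within each degree, by order
``m = -l, ..., 0, ..., +l``.  With ``Y_l^m`` the orthonormal complex
spherical harmonics (Condon-Shortley phase, polar angle ``theta`` from +z,
azimuth ``phi`` from +x), the real basis function for (l, m) is::

    m < 0 :  sqrt(2) * Im( Y_l^{|m|} )
    m = 0 :  Y_l^0                      (real)
    m > 0 :  sqrt(2) * Re( Y_l^{m} )

This basis is orthonormal on the sphere, so the spherical integral of an
expansion equals ``c[0] * 2 * sqrt(pi)`` and its L2 norm is ``||c||``.
"""

from __future__ import annotations

import numpy as np
from scipy.special import sph_harm_y


def n_coefficients(sh_order: int) -> int:
    """Number of real even-order SH coefficients up to ``sh_order``."""
    if sh_order < 0 or sh_order % 2:
        raise ValueError(f"sh_order must be even and >= 0, got {sh_order}")
    return (sh_order + 1) * (sh_order + 2) // 2


def order_from_ncoef(n: int) -> int:
    """Invert :func:`n_coefficients`; raises if ``n`` is not attainable."""
    lmax = int(round((np.sqrt(8 * n + 1) - 3) / 2))
    if lmax < 0 or lmax % 2 or n_coefficients(lmax) != n:
        raise ValueError(f"{n} is not a valid even-order SH coefficient count")
    return lmax


def degrees_orders(sh_order: int) -> tuple[np.ndarray, np.ndarray]:
    """Arrays of (l, m) for each coefficient index."""
    ls, ms = [], []
    for l in range(0, sh_order + 1, 2):
        for m in range(-l, l + 1):
            ls.append(l)
            ms.append(m)
    return np.asarray(ls), np.asarray(ms)


def cart_to_spherical(directions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit vectors -> (polar theta, azimuth phi)."""
    d = np.atleast_2d(np.asarray(directions, dtype=float))
    d = d / np.linalg.norm(d, axis=-1, keepdims=True)
    theta = np.arccos(np.clip(d[..., 2], -1.0, 1.0))
    phi = np.arctan2(d[..., 1], d[..., 0])
    return theta, phi


def basis_matrix(sh_order: int, directions: np.ndarray) -> np.ndarray:
    """Real even SH design matrix, shape (n_directions, n_coefficients).

    ``amplitudes = basis_matrix(order, dirs) @ coefficients``.
    """
    theta, phi = cart_to_spherical(directions)
    ls, ms = degrees_orders(sh_order)
    # sph_harm_y broadcasts over (l, m) x directions
    ylm = sph_harm_y(ls[:, None], np.abs(ms)[:, None], theta[None, :], phi[None, :])
    out = np.empty((theta.size, ls.size))
    neg, zero, pos = ms < 0, ms == 0, ms > 0
    out[:, neg] = np.sqrt(2.0) * ylm[neg].imag.T
    out[:, zero] = ylm[zero].real.T
    out[:, pos] = np.sqrt(2.0) * ylm[pos].real.T
    return out


def sphere_integral(coefficients: np.ndarray) -> float:
    """Analytic whole-sphere integral of an SH expansion."""
    return float(np.asarray(coefficients)[..., 0] * 2.0 * np.sqrt(np.pi))


def zonal_coefficients(kernel, sh_order: int, n_quad: int = 128) -> np.ndarray:
    """Project an axially symmetric kernel ``f(cos_theta)`` onto zonal SH.

    Returns ``z[l]`` for even ``l`` such that
    ``f(cos theta) ~= sum_l z[l] * Y_l^0(theta)``, computed by Gauss-Legendre
    quadrature in ``t = cos(theta)``:
    ``z_l = 2*pi * integral_{-1}^{1} f(t) Y_l^0(arccos t) dt``.
    """
    t, w = np.polynomial.legendre.leggauss(n_quad)
    theta = np.arccos(t)
    f = kernel(t)
    ls = np.arange(0, sh_order + 1, 2)
    y = sph_harm_y(ls[:, None], np.zeros_like(ls)[:, None], theta[None, :], 0.0).real
    return 2.0 * np.pi * (y * (f * w)[None, :]).sum(axis=1)


def rotate_zonal_to(zonal: np.ndarray, axis: np.ndarray, sh_order: int) -> np.ndarray:
    """Full coefficient vector of a zonal expansion re-oriented along ``axis``.

    By the addition theorem, a zonal function rotated so its symmetry axis
    points along ``u`` has coefficients
    ``c_{lm} = z_l * sqrt(4*pi / (2l+1)) * Y_{lm}(u)`` in the real basis.
    """
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    ls, _ = degrees_orders(sh_order)
    b = basis_matrix(sh_order, axis[None, :])[0]
    z_per_coef = np.asarray(zonal)[(ls // 2)]
    return z_per_coef * np.sqrt(4.0 * np.pi / (2 * ls + 1)) * b
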