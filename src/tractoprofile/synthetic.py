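"""Synthetic bundles, fields, and cohorts for end-to-end testing.

No subject MRI data ship with this package.  This module generates the
whole chain of inputs the pipeline consumes:

* tube-like streamline bundles around a smooth spline centerline;
* voxelwise FOD fields whose lobes follow the local fiber direction and
  integrate to a prescribed apparent fiber density, and axially symmetric
  tensor fields with a prescribed FA, both modulated along the tract;
* two-group cohorts (tinnitus vs control) whose confound distributions
  (hearing loss, age, THI, tinnitus duration, and the age-hearing-loss
  correlation) default to the reference study's demographics, with optional
  group effects injected into contiguous along-tract segment windows.

With all effect sizes at zero the two groups are exchangeable by
construction: the metric fields do not depend on the confounds, so group
labels carry no information and permutation-based error control can be
calibrated against this null.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
from scipy import interpolate

from . import shbasis, tractometry
from .fod_metrics import FODField, TensorField
from .tractometry import CentroidProfile, StreamlineBundle, N_SEGMENTS

DEFAULT_KERNEL_CONCENTRATION = 8.0  # exp(-k sin^2 theta) lobe sharpness

# Confound distributions of the reference cohort: mean, sd per group.
DEFAULT_CONFOUNDS = {
    "tinnitus": {
        "hl_db": (20.2, 10.3),
        "age_y": (42.5, 11.6),
        "thi": (16.2, 10.5),
        "duration_y": (11.6, 7.6),
    },
    "control": {
        "hl_db": (13.2, 3.8),
        "age_y": (42.5, 11.9),
        "thi": (0.0, 0.0),
        "duration_y": (0.0, 0.0),
    },
}
DEFAULT_AGE_HL_CORRELATION = 0.545


# ---------------------------------------------------------------------------
# Bundles
# ---------------------------------------------------------------------------

@dataclass
class BundleSpec:
    """Recipe for one synthetic bundle (a noisy tube around a spline)."""

    name: str
    centerline_control_points: np.ndarray
    n_streamlines: int = 500
    radial_dispersion_mm: float = 2.0
    points_per_streamline: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        self.centerline_control_points = np.asarray(
            self.centerline_control_points, dtype=float
        )
        pts = np.unique(self.centerline_control_points, axis=0)
        if self.centerline_control_points.ndim != 2 or pts.shape[0] < 2:
            raise ValueError(
                f"bundle '{self.name}': centerline needs >= 2 distinct control points"
            )
        if self.n_streamlines < 1:
            raise ValueError("n_streamlines must be >= 1")
        if self.radial_dispersion_mm < 0:
            raise ValueError("radial_dispersion_mm must be >= 0")
        if self.points_per_streamline < 2:
            raise ValueError("points_per_streamline must be >= 2")


def _spline_centerline(control: np.ndarray, n_points: int) -> np.ndarray:
    k = min(3, control.shape[0] - 1)
    tck, _ = interpolate.splprep(control.T, s=0.0, k=k)
    u = np.linspace(0.0, 1.0, n_points)
    return np.array(interpolate.splev(u, tck)).T


def _normal_frames(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit normals per point, continuous along the polyline."""
    tang = np.gradient(points, axis=0)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    ref = np.array([0.0, 0.0, 1.0])
    if np.abs(tang @ ref).max() > 0.95:
        ref = np.array([0.0, 1.0, 0.0])
    n1 = np.cross(tang, ref)
    n1 /= np.linalg.norm(n1, axis=1, keepdims=True)
    n2 = np.cross(tang, n1)
    return n1, n2


def make_bundle(spec: BundleSpec) -> StreamlineBundle:
    """Generate a bundle: spline centerline plus per-streamline radial offsets.

    Each streamline is the centerline displaced by a constant radial offset
    (Gaussian amplitude with sd ``radial_dispersion_mm`` in a uniformly
    random normal direction) plus a small per-point jitter (isotropic
    Gaussian, sd = 5% of the dispersion).  Fully determined by the spec,
    including its seed.
    """
    rng = np.random.default_rng(spec.seed)
    center = _spline_centerline(spec.centerline_control_points, spec.points_per_streamline)
    n1, n2 = _normal_frames(center)
    jitter_sd = 0.05 * spec.radial_dispersion_mm
    streamlines = []
    for _ in range(spec.n_streamlines):
        amp = rng.normal(0.0, spec.radial_dispersion_mm) if spec.radial_dispersion_mm else 0.0
        phi = rng.uniform(0.0, 2.0 * np.pi)
        offset = amp * (np.cos(phi) * n1 + np.sin(phi) * n2)
        jitter = rng.normal(0.0, jitter_sd, size=center.shape) if jitter_sd else 0.0
        streamlines.append(center + offset + jitter)
    return StreamlineBundle(spec.name, streamlines)


# ---------------------------------------------------------------------------
# Voxel grids and fields
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VoxelGrid:
    """Axis-aligned voxel grid: shape plus voxel->world affine."""

    shape: tuple[int, int, int]
    affine: np.ndarray

    @staticmethod
    def around(
        bundles: Sequence[StreamlineBundle],
        voxel_size_mm: float = 1.3,
        margin_mm: float = 4.0,
    ) -> "VoxelGrid":
        pts = np.vstack([s for b in bundles for s in b.streamlines])
        lo = pts.min(axis=0) - margin_mm
        hi = pts.max(axis=0) + margin_mm
        shape = tuple(int(np.ceil(d / voxel_size_mm)) + 1 for d in hi - lo)
        affine = np.eye(4)
        affine[:3, :3] *= voxel_size_mm
        affine[:3, 3] = lo
        return VoxelGrid(shape, affine)


def _lobe_zonal(sh_order: int, concentration: float) -> np.ndarray:
    """Unit-integral zonal coefficients of the axially symmetric lobe kernel."""
    z = shbasis.zonal_coefficients(
        lambda t: np.exp(-concentration * (1.0 - t * t)), sh_order
    )
    return z / (z[0] * 2.0 * np.sqrt(np.pi))


def _voxel_orientations(
    bundle: StreamlineBundle, grid: VoxelGrid, centroid: CentroidProfile | None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(voxel indices, mean axis, centroid-segment index) for traversed voxels.

    The mean axis is the principal eigenvector of the orientation tensor of
    all streamline-segment directions crossing the voxel; the segment index
    maps each voxel onto the along-tract coordinate (0 when no centroid is
    given).
    """
    inv = np.linalg.inv(grid.affine)
    mids, dirs, segs = [], [], []
    if centroid is not None:
        from scipy.spatial import cKDTree

        tree = cKDTree(centroid.segment_midpoints)
    for s in bundle.streamlines:
        m = 0.5 * (s[:-1] + s[1:])
        d = np.diff(s, axis=0)
        norm = np.linalg.norm(d, axis=1, keepdims=True)
        keep = norm[:, 0] > 0
        mids.append(m[keep])
        dirs.append(d[keep] / norm[keep])
        if centroid is not None:
            _, idx = tree.query(m[keep])
            segs.append(idx)
    mids = np.vstack(mids)
    dirs = np.vstack(dirs)
    segs = np.concatenate(segs) if centroid is not None else np.zeros(len(mids), int)
    vox = np.round(mids @ inv[:3, :3].T + inv[:3, 3]).astype(int)
    vox = np.clip(vox, 0, np.array(grid.shape) - 1)
    flat = np.ravel_multi_index(vox.T, grid.shape)
    uniq, inverse = np.unique(flat, return_inverse=True)
    axes = np.empty((uniq.size, 3))
    seg_of = np.empty(uniq.size, int)
    for i in range(uniq.size):
        sel = inverse == i
        dd = dirs[sel]
        tensor = dd.T @ dd
        _, vecs = np.linalg.eigh(tensor)
        axes[i] = vecs[:, -1]
        seg_of[i] = int(np.median(segs[sel]))
    return np.array(np.unravel_index(uniq, grid.shape)).T, axes, seg_of


def make_fod_field(
    bundle: StreamlineBundle,
    baseline_afd: float,
    sh_order: int,
    grid: VoxelGrid,
    crossing: tuple[np.ndarray, float] | None = None,
    afd_profile: np.ndarray | None = None,
    centroid: CentroidProfile | None = None,
    kernel_concentration: float = DEFAULT_KERNEL_CONCENTRATION,
    accumulate: FODField | None = None,
) -> FODField:
    """FOD field of a bundle: an oriented lobe kernel in traversed voxels.

    In each voxel crossed by the bundle the FOD is the axially symmetric
    kernel ``exp(-k sin^2 theta)`` aligned with the local mean streamline
    axis and scaled so its analytic sphere integral equals ``baseline_afd``
    (optionally modulated along the tract by ``afd_profile`` indexed through
    the centroid's segments).  ``crossing=(direction, fraction)`` adds a
    second fiber population carrying ``fraction`` of the integral.
    Elsewhere all coefficients are zero.
    """
    if sh_order % 2 or sh_order < 2:
        raise ValueError("sh_order must be a positive even integer")
    if afd_profile is not None and centroid is None:
        raise ValueError("afd_profile requires a centroid for segment lookup")
    n_sh = shbasis.n_coefficients(sh_order)
    if accumulate is not None:
        fieldobj = accumulate
    else:
        fieldobj = FODField(
            np.zeros(grid.shape + (n_sh,)), grid.affine.copy(), sh_order
        )
    if baseline_afd == 0 and afd_profile is None:
        return fieldobj
    zonal = _lobe_zonal(sh_order, kernel_concentration)
    vox, axes, seg_of = _voxel_orientations(bundle, grid, centroid)
    main_frac = 1.0 if crossing is None else 1.0 - crossing[1]
    for (i, j, k), axis, seg in zip(vox, axes, seg_of):
        afd = baseline_afd if afd_profile is None else float(afd_profile[seg])
        coef = main_frac * afd * shbasis.rotate_zonal_to(zonal, axis, sh_order)
        if crossing is not None:
            coef = coef + crossing[1] * afd * shbasis.rotate_zonal_to(
                zonal, np.asarray(crossing[0], float), sh_order
            )
        fieldobj.coefficients[i, j, k] += coef
    return fieldobj


def _axial_tensor(axis: np.ndarray, fa: float, md: float) -> np.ndarray:
    """Symmetric tensor with given FA, mean diffusivity, and principal axis.

    For eigenvalues ``md*(1+2*delta), md*(1-delta), md*(1-delta)`` the FA is
    ``3*delta / sqrt(3 + 6*delta^2)``; inverting gives
    ``delta = fa * sqrt(3 / (9 - 6*fa^2))``.
    """
    fa = float(np.clip(fa, 0.0, 0.999))
    delta = fa * np.sqrt(3.0 / (9.0 - 6.0 * fa * fa))
    l_par = md * (1.0 + 2.0 * delta)
    l_perp = md * (1.0 - delta)
    a = axis / np.linalg.norm(axis)
    D = l_perp * np.eye(3) + (l_par - l_perp) * np.outer(a, a)
    return np.array([D[0, 0], D[0, 1], D[0, 2], D[1, 1], D[1, 2], D[2, 2]])


def make_tensor_field(
    bundle: StreamlineBundle,
    baseline_fa: float,
    grid: VoxelGrid,
    mean_diffusivity: float = 0.7e-3,
    fa_profile: np.ndarray | None = None,
    centroid: CentroidProfile | None = None,
    accumulate: TensorField | None = None,
) -> TensorField:
    """Tensor field: axially symmetric tensors along the local fiber axis.

    Background voxels hold an isotropic tensor with the same mean
    diffusivity (FA = 0), so interpolation near the bundle edge degrades FA
    smoothly instead of mixing with zeros.
    """
    if accumulate is not None:
        fieldobj = accumulate
    else:
        tensors = np.zeros(grid.shape + (6,))
        tensors[..., [0, 3, 5]] = mean_diffusivity  # isotropic background
        fieldobj = TensorField(tensors, grid.affine.copy())
    vox, axes, seg_of = _voxel_orientations(bundle, grid, centroid)
    for (i, j, k), axis, seg in zip(vox, axes, seg_of):
        fa = baseline_fa if fa_profile is None else float(fa_profile[seg])
        fieldobj.tensors[i, j, k] = _axial_tensor(axis, fa, mean_diffusivity)
    return fieldobj


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class EffectWindow:
    """A localized group effect: +delta*noise_sd on the tinnitus group."""

    bundle: str
    metric: str
    segment_start: int
    segment_stop: int  # half-open
    delta: float

    def __post_init__(self) -> None:
        if not (0 <= self.segment_start < self.segment_stop <= N_SEGMENTS):
            raise ValueError("effect window must lie within [0, 100)")
        if not np.isfinite(self.delta):
            raise ValueError("delta must be finite")

    def mask(self, n_segments: int = N_SEGMENTS) -> np.ndarray:
        m = np.zeros(n_segments, dtype=bool)
        m[self.segment_start : self.segment_stop] = True
        return m


@dataclass
class CohortSpec:
    """Recipe for a two-group cohort with confounds and injected effects."""

    n_per_group: int = 19
    confound_means_sds: dict = dc_field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_CONFOUNDS.items()}
    )
    age_hl_correlation: float = DEFAULT_AGE_HL_CORRELATION
    effect_windows: list[EffectWindow] = dc_field(default_factory=list)
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.age_hl_correlation) >= 1:
            raise ValueError("|age_hl_correlation| must be < 1")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


def _latent_mean(target_mean: float, sd: float) -> float:
    """Latent Gaussian mean whose 0-truncated expectation equals the target.

    The reference demographics are moments of observed (nonnegative) data,
    so the generator matches the *truncated* mean to them:
    ``E[X | X >= 0] = mu + sd * phi(mu/sd) / Phi(mu/sd)`` is solved for mu.
    """
    from scipy.optimize import brentq
    from scipy.stats import norm

    if sd == 0 or target_mean > 6 * sd:
        return float(target_mean)

    def f(mu):
        return mu + sd * norm.pdf(mu / sd) / norm.cdf(mu / sd) - target_mean

    return float(brentq(f, target_mean - 6 * sd, target_mean + 1e-9))


def _truncated_normal(rng, mean, sd, size):
    """Nonnegative Gaussian draws whose mean matches ``mean`` (moment-matched)."""
    if sd == 0:
        return np.full(size, float(mean))
    mu = _latent_mean(mean, sd)
    out = rng.normal(mu, sd, size)
    for _ in range(100):
        neg = out < 0
        if not neg.any():
            break
        out[neg] = rng.normal(mu, sd, int(neg.sum()))
    return np.maximum(out, 0.0)


def pooled_correlation_attenuation(cspec: "CohortSpec") -> float:
    """Ratio pooled-sample r / within-group latent rho for age vs HL.

    Pooling the two groups mixes within-group covariance (rho times the
    mean of the per-group sd products) with between-group mean differences
    (uncorrelated between age and HL), attenuating the pooled correlation.
    """
    groups = list(cspec.confound_means_sds.values())
    sd_a = np.array([g["age_y"][1] for g in groups])
    sd_h = np.array([g["hl_db"][1] for g in groups])
    m_a = np.array([g["age_y"][0] for g in groups])
    m_h = np.array([g["hl_db"][0] for g in groups])
    cov_w = (sd_a * sd_h).mean()
    var_a = (sd_a**2).mean() + m_a.var()
    var_h = (sd_h**2).mean() + m_h.var()
    return cov_w / np.sqrt(var_a * var_h)


def _truncated_bivariate(rng, mean1, sd1, mean2, sd2, rho, size):
    """Correlated (age, HL) pairs, jointly resampled until both nonnegative."""
    mu1, mu2 = _latent_mean(mean1, sd1), _latent_mean(mean2, sd2)
    cov = np.array([[sd1**2, rho * sd1 * sd2], [rho * sd1 * sd2, sd2**2]])
    out = rng.multivariate_normal([mu1, mu2], cov, size)
    for _ in range(100):
        neg = (out < 0).any(axis=1)
        if not neg.any():
            break
        out[neg] = rng.multivariate_normal([mu1, mu2], cov, int(neg.sum()))
    return np.maximum(out, 0.0)


def sample_confounds(cspec: CohortSpec, rng: np.random.Generator):
    """Cohort table: 2*n_per_group rows of subject, group, and confounds.

    Age and hearing loss are drawn jointly per group; the within-group
    latent correlation is raised by the pooled-attenuation factor so that
    the *pooled* sample correlation targets ``age_hl_correlation`` (the
    quantity the reference study reports over the whole cohort).  THI and
    duration are zero for controls.
    """
    import pandas as pd

    rho_latent = float(
        np.clip(
            cspec.age_hl_correlation / pooled_correlation_attenuation(cspec),
            -0.99,
            0.99,
        )
    )
    rows = []
    for group in ("tinnitus", "control"):
        p = cspec.confound_means_sds[group]
        age_hl = _truncated_bivariate(
            rng,
            p["age_y"][0], p["age_y"][1],
            p["hl_db"][0], p["hl_db"][1],
            rho_latent,
            cspec.n_per_group,
        )
        thi = _truncated_normal(rng, *p["thi"], cspec.n_per_group)
        dur = _truncated_normal(rng, *p["duration_y"], cspec.n_per_group)
        for i in range(cspec.n_per_group):
            rows.append(
                {
                    "subject": f"{'T' if group == 'tinnitus' else 'C'}{i + 1:03d}",
                    "group": group,
                    "hl_db": age_hl[i, 1],
                    "thi": thi[i],
                    "duration_y": dur[i],
                    "age_y": age_hl[i, 0],
                }
            )
    return pd.DataFrame(rows)


def _baseline_profile(rng: np.random.Generator, level: float, n_segments: int) -> np.ndarray:
    """Smooth random baseline: level * (1 + low-frequency sinusoidal ripple)."""
    s = np.linspace(0.0, 1.0, n_segments)
    ripple = sum(
        rng.uniform(0.05, 0.15) * np.sin(2 * np.pi * (f * s + rng.uniform()))
        for f in (1, 2)
    )
    return level * (1.0 + ripple)


METRIC_BASE_LEVELS = {"AFD": 0.5, "peak_amplitude": 0.6, "FA": 0.5}


def make_profile_cohort(
    cspec: CohortSpec,
    bundle_names: Sequence[str] = ("bundle_a", "bundle_b", "bundle_c"),
    metrics: Sequence[str] = ("AFD",),
    n_segments: int = N_SEGMENTS,
):
    """Cohort sampled directly at the profile level (no voxel fields).

    Returns ``(cohort_table, profiles)`` where ``profiles[metric][bundle]``
    is a (2*n_per_group, n_segments) matrix in cohort row order.  Each
    subject's profile is the bundle's smooth baseline plus i.i.d. Gaussian
    segment noise (sd ``noise_sd``); tinnitus-group subjects additionally
    receive ``delta * noise_sd`` inside each matching effect window.  This
    is the generator used for statistical calibration, where the voxel and
    streamline stages are exercised separately.
    """
    rng = np.random.default_rng(cspec.seed)
    cohort = sample_confounds(cspec, rng)
    is_tin = (cohort["group"] == "tinnitus").to_numpy()
    n = len(cohort)
    profiles: dict[str, dict[str, np.ndarray]] = {m: {} for m in metrics}
    for bundle in bundle_names:
        baselines = {
            m: _baseline_profile(rng, METRIC_BASE_LEVELS.get(m, 0.5), n_segments)
            for m in metrics
        }
        for m in metrics:
            mat = baselines[m][None, :] + rng.normal(0.0, cspec.noise_sd, (n, n_segments))
            for w in cspec.effect_windows:
                if w.bundle == bundle and w.metric == m:
                    mat[np.ix_(is_tin, w.mask(n_segments))] += w.delta * cspec.noise_sd
            profiles[m][bundle] = mat
    return cohort, profiles


@dataclass
class SubjectFields:
    """One subject's voxel fields and bundles (shared grid and affine)."""

    subject_id: str
    fod: FODField | None
    tensor: TensorField | None
    bundle_set: dict[str, StreamlineBundle]


def make_cohort(
    cspec: CohortSpec,
    bundle_specs: Sequence[BundleSpec],
    sh_order: int = 8,
    voxel_size_mm: float = 1.3,
    with_fod: bool = True,
    with_tensors: bool = True,
):
    """Full field-level cohort: per-subject FOD/tensor fields and bundles.

    Streamline geometry and field noise are regenerated per subject from
    subject-specific seeds derived from the cohort seed; the AFD and FA
    baselines are modulated along the tract by smooth bundle profiles, with
    group effects injected as in :func:`make_profile_cohort`.  Deterministic
    per spec.
    """
    rng = np.random.default_rng(cspec.seed)
    cohort = sample_confounds(cspec, rng)
    ref_bundles = [make_bundle(spec) for spec in bundle_specs]
    centroids = {b.name: tractometry.centroid(b) for b in ref_bundles}
    grid = VoxelGrid.around(ref_bundles, voxel_size_mm=voxel_size_mm)
    baselines = {
        b.name: {
            m: _baseline_profile(rng, METRIC_BASE_LEVELS[m], N_SEGMENTS)
            for m in ("AFD", "FA")
        }
        for b in ref_bundles
    }
    subjects = []
    for row in cohort.itertuples():
        sub_seed = int(rng.integers(0, 2**31 - 1))
        sub_rng = np.random.default_rng(sub_seed)
        fod = None
        tensor = None
        bundle_set = {}
        for spec in bundle_specs:
            sub_spec = BundleSpec(
                spec.name,
                spec.centerline_control_points,
                spec.n_streamlines,
                spec.radial_dispersion_mm,
                spec.points_per_streamline,
                seed=int(sub_rng.integers(0, 2**31 - 1)),
            )
            bundle = make_bundle(sub_spec)
            bundle_set[spec.name] = bundle
            profiles = {}
            for m in ("AFD", "FA"):
                prof = baselines[spec.name][m] + sub_rng.normal(
                    0.0, cspec.noise_sd, N_SEGMENTS
                )
                for w in cspec.effect_windows:
                    if (
                        w.bundle == spec.name
                        and w.metric == m
                        and row.group == "tinnitus"
                    ):
                        prof[w.mask()] += w.delta * cspec.noise_sd
                profiles[m] = np.maximum(prof, 0.0)
            if with_fod:
                fod = make_fod_field(
                    bundle,
                    baseline_afd=1.0,
                    sh_order=sh_order,
                    grid=grid,
                    afd_profile=profiles["AFD"],
                    centroid=centroids[spec.name],
                    accumulate=fod,
                )
            if with_tensors:
                tensor = make_tensor_field(
                    bundle,
                    baseline_fa=0.5,
                    grid=grid,
                    fa_profile=np.clip(profiles["FA"], 0.0, 0.95),
                    centroid=centroids[spec.name],
                    accumulate=tensor,
                )
        subjects.append(SubjectFields(row.subject, fod, tensor, bundle_set))
    return cohort, subjects
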