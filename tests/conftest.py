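import numpy as np
import pytest

from tractoprofile import synthetic as syn
from tractoprofile.sphere import icosphere_mesh


@pytest.fixture(scope="session")
def mesh3():
    """642-vertex icosphere: the desk-scale quadrature grid."""
    return icosphere_mesh(3)


@pytest.fixture(scope="session")
def mesh4():
    """2562-vertex icosphere: the default quadrature grid."""
    return icosphere_mesh(4)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def curved_bundle():
    """Small curved bundle used across tractometry tests."""
    spec = syn.BundleSpec(
        "curved",
        np.array([[0, 0, 0], [20, 6, 0], [40, 0, 6], [60, 0, 0]], dtype=float),
        n_streamlines=15,
        radial_dispersion_mm=1.5,
        points_per_streamline=60,
        seed=11,
    )
    return syn.make_bundle(spec)


def single_lobe_field(axis, afd=1.0, sh_order=8, n_vox=3, voxel_mm=2.0):
    """Uniform field: the same oriented lobe in every voxel (no empty mixing)."""
    from tractoprofile import shbasis
    from tractoprofile.fod_metrics import FODField
    from tractoprofile.synthetic import DEFAULT_KERNEL_CONCENTRATION, _lobe_zonal

    zonal = _lobe_zonal(sh_order, DEFAULT_KERNEL_CONCENTRATION)
    coef = afd * shbasis.rotate_zonal_to(zonal, np.asarray(axis, float), sh_order)
    grid = np.broadcast_to(coef, (n_vox, n_vox, n_vox, coef.size)).copy()
    affine = np.eye(4)
    affine[:3, :3] *= voxel_mm
    return FODField(grid, affine, sh_order)
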