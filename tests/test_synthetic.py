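"""Synthetic bundle, field, and cohort generator behavior."""

import numpy as np
import pytest

from tractoprofile import synthetic as syn, tractometry as tm
from tractoprofile.fod_metrics import evaluate_fod, segment_lobes
from tractoprofile.shbasis import sphere_integral
from tractoprofile.synthetic import BundleSpec, CohortSpec, EffectWindow


STRAIGHT = np.array([[0.0, 0, 0], [20, 0, 0], [40, 0, 0]])
CURVED = np.array([[0.0, 0, 0], [15, 8, 0], [30, 0, 5], [45, 0, 0]])


class TestMakeBundle:
    def test_zero_dispersion_collapses_to_centerline(self):
        spec = BundleSpec("b", CURVED, n_streamlines=3, radial_dispersion_mm=0.0, seed=4)
        bundle = syn.make_bundle(spec)
        assert len(bundle) == 3
        for s in bundle.streamlines[1:]:
            np.testing.assert_allclose(s, bundle.streamlines[0], atol=1e-12)

    def test_deterministic_per_seed(self):
        spec = dict(n_streamlines=5, radial_dispersion_mm=2.0, seed=1)
        a = syn.make_bundle(BundleSpec("b", CURVED, **spec))
        b = syn.make_bundle(BundleSpec("b", CURVED, **spec))
        for x, y in zip(a.streamlines, b.streamlines):
            np.testing.assert_array_equal(x, y)
        c = syn.make_bundle(BundleSpec("b", CURVED, n_streamlines=5,
                                       radial_dispersion_mm=2.0, seed=2))
        assert not np.allclose(a.streamlines[0], c.streamlines[0])

    def test_radial_dispersion_monte_carlo(self):
        """Mean distance to the centerline approximates sd * sqrt(2/pi)."""
        sigma = 2.0
        spec = BundleSpec(
            "b", STRAIGHT, n_streamlines=500, radial_dispersion_mm=sigma, seed=9
        )
        bundle = syn.make_bundle(spec)
        # straight centerline along x: radial distance is the (y, z) norm
        dists = np.array(
            [np.linalg.norm(s[:, 1:], axis=1).mean() for s in bundle.streamlines]
        )
        expected = sigma * np.sqrt(2 / np.pi)
        assert dists.mean() == pytest.approx(expected, rel=0.2)

    def test_degenerate_centerline_rejected(self):
        with pytest.raises(ValueError):
            BundleSpec("b", np.array([[1.0, 1, 1], [1, 1, 1]]))


class TestMakeFODField:
    def test_zero_baseline_all_zero(self):
        bundle = syn.make_bundle(BundleSpec("b", STRAIGHT, n_streamlines=5, seed=1))
        grid = syn.VoxelGrid.around([bundle], voxel_size_mm=2.0)
        field = syn.make_fod_field(bundle, 0.0, 8, grid)
        assert np.all(field.coefficients == 0)

    def test_odd_order_rejected(self):
        bundle = syn.make_bundle(BundleSpec("b", STRAIGHT, n_streamlines=2, seed=1))
        grid = syn.VoxelGrid.around([bundle])
        with pytest.raises(ValueError):
            syn.make_fod_field(bundle, 1.0, 5, grid)

    def test_traversed_voxel_integral_matches_quadrature_oracle(self, mesh4):
        """Analytic sphere integral equals fine quadrature within 0.5%."""
        bundle = syn.make_bundle(
            BundleSpec("b", STRAIGHT, n_streamlines=30, radial_dispersion_mm=0.5, seed=2)
        )
        grid = syn.VoxelGrid.around([bundle], voxel_size_mm=2.0)
        field = syn.make_fod_field(bundle, 1.0, 8, grid)
        # pick a voxel on the centerline, query at its exact center
        ijk = np.round(
            np.linalg.inv(field.affine)[:3, :3] @ [20.0, 0, 0]
            + np.linalg.inv(field.affine)[:3, 3]
        ).astype(int)
        center_mm = field.affine[:3, :3] @ ijk + field.affine[:3, 3]
        coef = field.coefficients[tuple(ijk)]
        assert sphere_integral(coef) == pytest.approx(1.0, rel=1e-9)
        quad = mesh4.integrate(evaluate_fod(field, center_mm, mesh4.vertices))
        assert quad == pytest.approx(1.0, rel=0.005)

    def test_lobe_aligned_with_tangent(self, mesh4):
        bundle = syn.make_bundle(
            BundleSpec("b", STRAIGHT, n_streamlines=30, radial_dispersion_mm=0.5, seed=2)
        )
        grid = syn.VoxelGrid.around([bundle], voxel_size_mm=2.0)
        field = syn.make_fod_field(bundle, 1.0, 8, grid)
        lobes = segment_lobes(field, [20.0, 0, 0], mesh4)
        assert abs(lobes[0].peak_direction @ [1.0, 0, 0]) > 0.99

    def test_crossing_populations_recovered(self, mesh4):
        """A 0.6/0.4 crossing built by the generator splits into two lobes."""
        b1 = syn.make_bundle(
            BundleSpec("b1", STRAIGHT, n_streamlines=20, radial_dispersion_mm=0.3, seed=3)
        )
        grid = syn.VoxelGrid.around([b1], voxel_size_mm=2.0)
        field = syn.make_fod_field(
            b1, 1.0, 8, grid, crossing=(np.array([0.0, 0, 1.0]), 0.4)
        )
        # query at an exact traversed voxel center (no partial-volume mixing)
        inv = np.linalg.inv(field.affine)
        ijk = np.round(inv[:3, :3] @ [20.0, 0, 0] + inv[:3, 3]).astype(int)
        center_mm = field.affine[:3, :3] @ ijk + field.affine[:3, 3]
        lobes = segment_lobes(field, center_mm, mesh4, amplitude_floor_frac=0.01)
        main = [lb for lb in lobes if abs(lb.peak_direction @ [1, 0, 0]) > 0.9]
        cross = [lb for lb in lobes if abs(lb.peak_direction @ [0, 0, 1]) > 0.9]
        assert main and cross
        assert main[0].integral == pytest.approx(0.6, rel=0.04)
        assert cross[0].integral == pytest.approx(0.4, rel=0.04)


class TestCohortSampling:
    def test_table_shape_and_groups(self):
        cohort = syn.sample_confounds(CohortSpec(seed=0), np.random.default_rng(0))
        assert len(cohort) == 38
        assert (cohort["group"] == "tinnitus").sum() == 19
        assert (cohort.loc[cohort.group == "control", "thi"] == 0).all()
        assert (cohort[["hl_db", "thi", "duration_y", "age_y"]] >= 0).all().all()

    def test_group_mean_sampling_oracle(self):
        """Across replicates the tinnitus HL mean approaches 20.2 dB.

        Truncation at 0 is moment-matched, so the observed mean equals the
        configured one despite the nonnegativity constraint.
        """
        rng = np.random.default_rng(123)
        cs = CohortSpec(seed=0)
        means = []
        for _ in range(2000):
            p = cs.confound_means_sds["tinnitus"]["hl_db"]
            means.append(syn._truncated_normal(rng, *p, 19).mean())
        assert np.mean(means) == pytest.approx(20.2, abs=0.2)

    def test_age_hl_correlation_target(self):
        """Mean pooled sample r is close to the configured 0.545."""
        rs = []
        for rep in range(400):
            cohort = syn.sample_confounds(
                CohortSpec(seed=rep), np.random.default_rng(rep)
            )
            rs.append(np.corrcoef(cohort["age_y"], cohort["hl_db"])[0, 1])
        # residual truncation attenuation leaves the mean a touch below target
        assert np.mean(rs) == pytest.approx(0.545, abs=0.04)

    def test_invalid_correlation_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(age_hl_correlation=1.0)


class TestProfileCohort:
    def test_determinism(self):
        cs = CohortSpec(n_per_group=5, seed=42)
        c1, p1 = syn.make_profile_cohort(cs)
        c2, p2 = syn.make_profile_cohort(cs)
        assert c1.equals(c2)
        for b in p1["AFD"]:
            np.testing.assert_array_equal(p1["AFD"][b], p2["AFD"][b])

    def test_null_exchangeability(self):
        """With delta=0 both groups are draws from the same distribution."""
        cs = CohortSpec(n_per_group=19, seed=3)
        cohort, profs = syn.make_profile_cohort(cs)
        mat = profs["AFD"]["bundle_a"]
        tin = (cohort["group"] == "tinnitus").to_numpy()
        # group means agree within Monte-Carlo error of the shared noise
        diff = mat[tin].mean() - mat[~tin].mean()
        se = cs.noise_sd * np.sqrt(2 / (19 * 100))
        assert abs(diff) < 5 * se

    def test_effect_window_injected_where_requested(self):
        w = EffectWindow("bundle_b", "AFD", 10, 30, 3.0)
        cs = CohortSpec(n_per_group=19, effect_windows=[w], seed=3)
        cohort, profs = syn.make_profile_cohort(cs)
        tin = (cohort["group"] == "tinnitus").to_numpy()
        null_cs = CohortSpec(n_per_group=19, seed=3)
        _, null_profs = syn.make_profile_cohort(null_cs)
        delta_b = profs["AFD"]["bundle_b"] - null_profs["AFD"]["bundle_b"]
        np.testing.assert_allclose(delta_b[tin][:, 10:30], 3.0 * cs.noise_sd)
        np.testing.assert_allclose(delta_b[~tin], 0.0)
        np.testing.assert_allclose(
            profs["AFD"]["bundle_a"], null_profs["AFD"]["bundle_a"]
        )

    def test_window_bounds_validated(self):
        with pytest.raises(ValueError):
            EffectWindow("b", "AFD", 90, 120, 1.0)


class TestFieldLevelCohort:
    def test_small_cohort_structure(self):
        cs = CohortSpec(n_per_group=2, seed=5)
        specs = [
            BundleSpec("b1", STRAIGHT, n_streamlines=10, radial_dispersion_mm=1.0, seed=1)
        ]
        cohort, subjects = syn.make_cohort(cs, specs, voxel_size_mm=3.0)
        assert len(subjects) == 4
        for sub in subjects:
            assert set(sub.bundle_set) == {"b1"}
            assert sub.fod is not None and sub.tensor is not None
            np.testing.assert_array_equal(sub.fod.affine, sub.tensor.affine)
        # streamlines lie inside the field bounding box
        lo = subjects[0].fod.affine[:3, 3]
        hi = lo + subjects[0].fod.affine[:3, :3] @ np.array(subjects[0].fod.shape)
        pts = np.vstack(subjects[0].bundle_set["b1"].streamlines)
        assert np.all(pts > lo - 1e-9) and np.all(pts < hi + 1e-9)

    def test_effect_localization_in_full_pipeline(self, mesh3):
        """A large injected AFD effect maximizes |t| inside its window."""
        from tractoprofile import group_stats as gs

        w = EffectWindow("b1", "AFD", 40, 60, 8.0)
        specs = [
            BundleSpec("b1", CURVED, n_streamlines=25, radial_dispersion_mm=1.0, seed=1)
        ]
        cs = CohortSpec(n_per_group=4, effect_windows=[w], noise_sd=0.05, seed=6)
        cohort, subjects = syn.make_cohort(cs, specs, voxel_size_mm=2.5,
                                           with_tensors=False)
        cent = tm.centroid(subjects[0].bundle_set["b1"])
        rows = [
            tm.profile(s.bundle_set["b1"], cent, s.fod, "AFD", mesh=mesh3)
            for s in subjects
        ]
        mat = np.vstack(rows)
        tin = (cohort["group"] == "tinnitus").to_numpy()
        t, _ = gs.ttest_segments(mat, tin)
        assert 40 <= int(np.nanargmax(np.abs(t))) < 60
        # effect direction: tinnitus AFD is raised inside the window
        assert t[40:60].mean() > 0
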