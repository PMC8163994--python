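"""Pipeline orchestration: simulate -> profile -> stats -> report.

A :class:`RunConfig` (usually loaded from YAML) drives the whole chain.
Every stage is a pure function of its inputs and the seed, writes its
outputs into a stage subdirectory, and can be re-run idempotently; the run
directory ends with a provenance record.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io, synthetic, tractometry
from .group_stats import (
    CONFOUND_COLUMNS,
    StatsConfig,
    analyze_correlations,
    analyze_group_differences,
    cluster_summary,
)
from .plotting import plot_tract_profile, plot_znormed_metrics
from .sphere import icosphere_mesh
from .synthetic import BundleSpec, CohortSpec, EffectWindow
from .tractometry import METRICS, ProfileMatrix

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass
class RunConfig:
    """Validated configuration of a full run."""

    out_dir: Path
    metrics: tuple[str, ...] = METRICS
    stats: StatsConfig = dc_field(default_factory=StatsConfig)
    cohort_spec: CohortSpec = dc_field(default_factory=CohortSpec)
    bundle_specs: list[BundleSpec] = dc_field(default_factory=list)
    sh_order: int = 8
    voxel_size_mm: float = 1.3
    mesh_subdivisions: int = 4
    seed: int = 0
    correlation_cofactors: tuple[str, ...] = CONFOUND_COLUMNS

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        unknown = set(self.metrics) - set(METRICS)
        if unknown:
            raise ConfigError(f"unknown metrics {sorted(unknown)}; choose from {METRICS}")
        if not self.bundle_specs:
            raise ConfigError("at least one bundle spec is required")

    @staticmethod
    def from_dict(raw: dict, out_dir: str | Path) -> "RunConfig":
        try:
            seed = int(raw.get("seed", 0))
            stats = StatsConfig(**raw.get("stats", {}), seed=seed)
            windows = [EffectWindow(**w) for w in raw.get("effect_windows", [])]
            cspec_kwargs = dict(raw.get("cohort", {}))
            cspec = CohortSpec(**cspec_kwargs, effect_windows=windows, seed=seed)
            bundles = [
                BundleSpec(
                    name=b["name"],
                    centerline_control_points=np.asarray(b["centerline"], dtype=float),
                    n_streamlines=int(b.get("n_streamlines", 500)),
                    radial_dispersion_mm=float(b.get("radial_dispersion_mm", 2.0)),
                    points_per_streamline=int(b.get("points_per_streamline", 100)),
                    seed=seed + i,
                )
                for i, b in enumerate(raw.get("bundles", []))
            ]
            return RunConfig(
                out_dir=Path(out_dir),
                metrics=tuple(raw.get("metrics", METRICS)),
                stats=stats,
                cohort_spec=cspec,
                bundle_specs=bundles,
                sh_order=int(raw.get("sh_order", 8)),
                voxel_size_mm=float(raw.get("voxel_size_mm", 1.3)),
                mesh_subdivisions=int(raw.get("mesh_subdivisions", 4)),
                seed=seed,
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"invalid configuration: {exc}") from exc


def demo_config(
    out_dir: str | Path,
    seed: int = 0,
    n_per_group: int = 19,
    n_streamlines: int = 60,
    n_permutations: int = 1000,
    metrics: tuple[str, ...] = METRICS,
    effect_windows: list[EffectWindow] | None = None,
) -> RunConfig:
    """Small three-bundle configuration used by the worked example and tests."""
    bundles = [
        BundleSpec(
            "arc",
            np.column_stack(
                [
                    30 * np.cos(np.linspace(0.2, 2.9, 7)),
                    30 * np.sin(np.linspace(0.2, 2.9, 7)),
                    np.linspace(-4, 4, 7),
                ]
            ),
            n_streamlines=n_streamlines,
            radial_dispersion_mm=1.5,
            seed=seed + 1,
        ),
        BundleSpec(
            "sigmoid",
            np.column_stack(
                [
                    np.linspace(-30, 30, 7),
                    8 * np.tanh(np.linspace(-2, 2, 7)),
                    np.linspace(18, 26, 7),
                ]
            ),
            n_streamlines=n_streamlines,
            radial_dispersion_mm=1.5,
            seed=seed + 2,
        ),
        BundleSpec(
            "ribbon",
            np.column_stack(
                [
                    np.linspace(-25, 25, 7),
                    np.linspace(-28, -12, 7),
                    6 * np.sin(np.linspace(0, np.pi, 7)) - 20,
                ]
            ),
            n_streamlines=n_streamlines,
            radial_dispersion_mm=1.5,
            seed=seed + 3,
        ),
    ]
    return RunConfig(
        out_dir=Path(out_dir),
        metrics=metrics,
        stats=StatsConfig(n_permutations=n_permutations, seed=seed),
        cohort_spec=CohortSpec(
            n_per_group=n_per_group, effect_windows=effect_windows or [], seed=seed
        ),
        bundle_specs=bundles,
        voxel_size_mm=2.5,
        mesh_subdivisions=3,
        seed=seed,
    )


def simulate_stage(config: RunConfig) -> tuple[pd.DataFrame, list[synthetic.SubjectFields]]:
    """Generate and write the synthetic cohort (TCK + NIfTI + cohort TSV)."""
    out = config.out_dir / "simulated"
    cohort, subjects = synthetic.make_cohort(
        config.cohort_spec,
        config.bundle_specs,
        sh_order=config.sh_order,
        voxel_size_mm=config.voxel_size_mm,
        with_fod=bool({"AFD", "peak_amplitude"} & set(config.metrics)),
        with_tensors="FA" in config.metrics,
    )
    io.write_tsv(cohort, out / "cohort.tsv")
    for sub in subjects:
        sdir = out / sub.subject_id
        if sub.fod is not None:
            io.write_nifti_field(sub.fod, sdir / "fod.nii")
        if sub.tensor is not None:
            io.write_nifti_field(sub.tensor, sdir / "tensor.nii")
        for name, bundle in sub.bundle_set.items():
            io.write_tck(bundle, sdir / f"{name}.tck")
    return cohort, subjects


def profile_stage(
    config: RunConfig,
    cohort: pd.DataFrame,
    subjects: list[synthetic.SubjectFields],
) -> dict[str, dict[str, ProfileMatrix]]:
    """Along-tract profiles per metric and bundle, written as TSV."""
    out = config.out_dir / "profiles"
    mesh = icosphere_mesh(config.mesh_subdivisions)
    # one shared along-tract coordinate system per bundle, from the first subject
    centroids = {
        name: tractometry.centroid(bundle)
        for name, bundle in subjects[0].bundle_set.items()
    }
    result: dict[str, dict[str, ProfileMatrix]] = {m: {} for m in config.metrics}
    subject_ids = [s.subject_id for s in subjects]
    for bundle_name, cent in centroids.items():
        rows = {m: [] for m in config.metrics}
        for sub in subjects:
            bundle = sub.bundle_set[bundle_name]
            for m in config.metrics:
                field = sub.tensor if m == "FA" else sub.fod
                rows[m].append(
                    tractometry.profile(bundle, cent, field, m, mesh=mesh)
                )
        for m in config.metrics:
            pm = ProfileMatrix(bundle_name, m, np.vstack(rows[m]), subject_ids)
            result[m][bundle_name] = pm
            io.write_profile_tsv(pm, out / f"{bundle_name}_{m}.tsv")
    return result


def stats_stage(
    config: RunConfig,
    cohort: pd.DataFrame,
    profiles: dict[str, dict[str, ProfileMatrix]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group differences and cofactor correlations over all metrics."""
    out = config.out_dir / "stats"
    stat_tables, corr_tables = [], []
    for m in config.metrics:
        mats = {b: pm.values for b, pm in profiles[m].items()}
        table = analyze_group_differences(mats, cohort, config.stats, metric_name=m)
        stat_tables.append(table)
        for cofactor in config.correlation_cofactors:
            corr_tables.append(
                analyze_correlations(mats, cohort, cofactor, config.stats, metric_name=m)
            )
    stats = pd.concat(stat_tables, ignore_index=True)
    corrs = pd.concat(corr_tables, ignore_index=True) if corr_tables else pd.DataFrame()
    io.write_tsv(stats, out / "segment_stats.tsv")
    io.write_tsv(cluster_summary(stats), out / "cluster_summary.tsv")
    if len(corrs):
        io.write_tsv(corrs, out / "correlations.tsv")
    return stats, corrs


def report_stage(
    config: RunConfig,
    cohort: pd.DataFrame,
    profiles: dict[str, dict[str, ProfileMatrix]],
    stats: pd.DataFrame,
) -> list[Path]:
    """Tract-profile figures and the z-scored multi-metric comparison."""
    out = config.out_dir / "report"
    written = []
    for m in config.metrics:
        for bundle_name, pm in profiles[m].items():
            p = out / f"{bundle_name}_{m}.png"
            plot_tract_profile(pm, cohort, stats[stats["metric"] == m], p)
            written.append(p)
    first_bundle = next(iter(profiles[config.metrics[0]]))
    p = out / f"{first_bundle}_zscored.png"
    plot_znormed_metrics(
        {m: profiles[m][first_bundle] for m in config.metrics}, cohort, p
    )
    written.append(p)
    return written


def run_pipeline(config: RunConfig) -> Path:
    """Execute simulate -> profile -> stats -> report; returns the run directory."""
    logger.info("pipeline start: %s", config.out_dir)
    cohort, subjects = simulate_stage(config)
    profiles = profile_stage(config, cohort, subjects)
    stats, _ = stats_stage(config, cohort, profiles)
    report_stage(config, cohort, profiles, stats)
    outputs = sorted(p for p in config.out_dir.rglob("*") if p.is_file())
    io.write_provenance(
        config.out_dir,
        {"metrics": list(config.metrics), "seed": config.seed},
        config.seed,
        outputs,
    )
    logger.info("pipeline done: %s", config.out_dir)
    return config.out_dir
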