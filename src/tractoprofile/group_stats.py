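"""Group statistics for along-tract profiles.

The analysis chain mirrors a two-stage multiple-comparison design common in
tractometry group studies:

1. per segment, ordinary least squares removes the confounds (hearing loss,
   THI, tinnitus duration) from the metric; group contrasts then act on the
   confound-adjusted values;
2. per bundle and segment, a pooled-variance two-sample t-test compares the
   groups;
3. family-wise error over *all bundles and segments* of one metric run is
   controlled by maxT permutation: group labels are permuted, the maximum
   |t| over the whole family is recorded, and each observed |t| is compared
   against that null distribution (add-one estimator; exhaustive
   enumeration when the label assignments can all be visited);
4. an additional Bonferroni factor (default 3, one per metric) divides the
   significance level;
5. surviving segments must form contiguous runs of at least
   ``cluster_extent_min`` segments;
6. effect sizes (Cohen's d = 2|t|/sqrt(df), f^2 = r^2/(1-r^2)) and post-hoc
   power (noncentral-t) annotate the findings.

Cofactor correlations are semi-partial: the metric is adjusted by the fitted
contributions of the *other* confounds only, then Pearson-correlated with
the cofactor of interest; the same maxT machinery (permuting the cofactor)
corrects the family of tests.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

CONFOUND_COLUMNS = ("hl_db", "thi", "duration_y")
GROUP_COLUMN = "group"
TINNITUS, CONTROL = "tinnitus", "control"


@dataclass
class StatsConfig:
    """Knobs of the statistical engine (defaults follow the study design)."""

    n_permutations: int = 5000
    alpha: float = 0.05
    n_metrics_bonferroni: int = 3
    cluster_extent_min: int = 5
    seed: int = 0
    power_alpha: float = 0.05
    confound_centering: str = "within_group"  # or "pooled"

    def __post_init__(self) -> None:
        if self.confound_centering not in ("within_group", "pooled"):
            raise ValueError("confound_centering must be 'within_group' or 'pooled'")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.cluster_extent_min < 1:
            raise ValueError("cluster_extent_min must be >= 1")

    @property
    def adjusted_alpha(self) -> float:
        return self.alpha / self.n_metrics_bonferroni


# ---------------------------------------------------------------------------
# Confound regression
# ---------------------------------------------------------------------------

def regress_confounds(
    Y: np.ndarray,
    X: np.ndarray,
    column_names: tuple[str, ...] | None = None,
    center_within: np.ndarray | None = None,
) -> np.ndarray:
    """OLS-residualize each column of ``Y`` on ``[intercept, X]``.

    Returns the residuals with each segment's grand mean re-added, so that
    downstream group contrasts operate on confound-adjusted metric values on
    the original scale.

    When ``center_within`` (an array of group labels) is given, each
    confound column is mean-centered within each group before fitting, so
    the adjustment removes within-group confound variation without spanning
    the between-group contrast.  This is required for covariates such as
    THI or tinnitus duration that exist only in one group (zero-filled in
    the other) and would otherwise act as group proxies and absorb any
    group difference.
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    if center_within is not None:
        labels = np.asarray(center_within)
        X = X.copy()
        for g in np.unique(labels):
            sel = labels == g
            X[sel] -= X[sel].mean(axis=0, keepdims=True)
    design = np.column_stack([np.ones(X.shape[0]), X])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        names = column_names or tuple(f"x{i}" for i in range(X.shape[1]))
        bad = _collinear_columns(design, ("intercept",) + tuple(names))
        raise ValueError(f"rank-deficient confound design; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(design, Y, rcond=None)
    resid = Y - design @ beta
    return resid + Y.mean(axis=0, keepdims=True)


def _collinear_columns(design: np.ndarray, names: tuple[str, ...]) -> list[str]:
    _, r = np.linalg.qr(design)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(design.shape) * np.finfo(float).eps
    return [names[i] for i in np.flatnonzero(diag < tol)]


# ---------------------------------------------------------------------------
# t statistics
# ---------------------------------------------------------------------------

def _pooled_t(values: np.ndarray, masks: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t for many label assignments at once.

    ``values`` is (n_subjects, n_tests); ``masks`` is (B, n_subjects) of
    group-1 membership.  Returns (B, n_tests).  Zero pooled variance gives
    t = 0.
    """
    masks = masks.astype(float)
    n = values.shape[0]
    n1 = masks.sum(axis=1)
    n2 = n - n1
    tot = values.sum(axis=0)
    tot_sq = (values**2).sum(axis=0)
    s1 = masks @ values
    q1 = masks @ values**2
    m1 = s1 / n1[:, None]
    m2 = (tot[None, :] - s1) / n2[:, None]
    ss1 = q1 - n1[:, None] * m1**2
    ss2 = (tot_sq[None, :] - q1) - n2[:, None] * m2**2
    df = n1 + n2 - 2
    sp2 = np.maximum(ss1 + ss2, 0.0) / df[:, None]
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2)[:, None])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / se
    return np.where(se > 0, t, 0.0)


def ttest_segments(
    values: np.ndarray, group1_mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Independent two-sample Student t per column (group1 minus group2).

    Returns (t, two-sided p) with df = n1 + n2 - 2.  Columns with zero
    pooled variance get t = 0, p = 1.
    """
    group1_mask = np.asarray(group1_mask, dtype=bool)
    n1, n2 = int(group1_mask.sum()), int((~group1_mask).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 subjects")
    t = _pooled_t(np.asarray(values, dtype=float), group1_mask[None, :])[0]
    p = 2.0 * sps.t.sf(np.abs(t), n1 + n2 - 2)
    return t, p


# ---------------------------------------------------------------------------
# maxT permutation FWE
# ---------------------------------------------------------------------------

@dataclass
class PermutationResult:
    t_obs: np.ndarray
    p_uncorrected: np.ndarray
    p_fwe: np.ndarray
    max_t_null: np.ndarray
    t_threshold: float
    p_uncorrected_cutoff: float
    exhaustive: bool
    n_permutations_used: int
    df: int

    @property
    def significant(self) -> np.ndarray:
        """Mask at the (metric-Bonferroni-adjusted) threshold used to build this result."""
        return self.p_fwe < self._alpha_adjusted

    _alpha_adjusted: float = field(default=0.05)


def _all_label_masks(n: int, n1: int) -> np.ndarray:
    masks = np.zeros((math.comb(n, n1), n), dtype=bool)
    for i, combo in enumerate(itertools.combinations(range(n), n1)):
        masks[i, list(combo)] = True
    return masks


def _center_within_mask(X: np.ndarray, mask: np.ndarray) -> np.ndarray:
    Xc = X.copy()
    for sel in (mask, ~mask):
        Xc[sel] -= Xc[sel].mean(axis=0, keepdims=True)
    return Xc


def _adjusted_t(
    values: np.ndarray,
    masks: np.ndarray,
    confounds: np.ndarray | None,
    centering: str,
) -> np.ndarray:
    """t statistics with the confound adjustment replayed per label assignment.

    Each permutation re-centers the confounds within its own grouping,
    residualizes, and tests — so the adjustment is part of the permuted
    statistic, keeping the test exact under subject exchangeability
    (residualizing once and permuting residuals deflates the null).
    """
    if confounds is None:
        return _pooled_t(values, masks)
    if centering == "pooled":
        design = np.column_stack([np.ones(values.shape[0]), confounds])
        beta, *_ = np.linalg.lstsq(design, values, rcond=None)
        return _pooled_t(values - design @ beta, masks)
    out = np.empty((masks.shape[0], values.shape[1]))
    for b, mask in enumerate(masks):
        Xc = _center_within_mask(confounds, mask)
        design = np.column_stack([np.ones(values.shape[0]), Xc])
        beta, *_ = np.linalg.lstsq(design, values, rcond=None)
        out[b] = _pooled_t(values - design @ beta, mask[None, :])[0]
    return out


def permutation_fwe(
    values: np.ndarray,
    group1_mask: np.ndarray,
    cfg: StatsConfig,
    rng: np.random.Generator | None = None,
    confounds: np.ndarray | None = None,
) -> PermutationResult:
    """maxT family-wise-error-corrected p-values over all columns.

    For each permutation of the group labels the maximum |t| over every
    column (all bundles x segments of one metric run) is recorded;
    ``p_fwe[j] = (1 + #{max |t| >= |t_obs[j]|}) / (B + 1)`` for sampled
    permutations.  When the number of distinct label assignments does not
    exceed ``cfg.n_permutations`` they are enumerated exactly instead and
    the plain proportion (which includes the identity) is returned.

    When ``confounds`` is given, the nuisance regression (with the
    configured centering) is replayed inside every permutation.
    """
    values = np.asarray(values, dtype=float)
    group1_mask = np.asarray(group1_mask, dtype=bool)
    n = values.shape[0]
    n1 = int(group1_mask.sum())
    rng = rng or np.random.default_rng(cfg.seed)

    t_obs = _adjusted_t(
        values, group1_mask[None, :], confounds, cfg.confound_centering
    )[0]
    df = n - 2
    p_unc = 2.0 * sps.t.sf(np.abs(t_obs), df)

    n_distinct = math.comb(n, n1)
    exhaustive = n_distinct <= cfg.n_permutations
    if exhaustive:
        masks = _all_label_masks(n, n1)
    else:
        masks = np.empty((cfg.n_permutations, n), dtype=bool)
        for b in range(cfg.n_permutations):
            masks[b] = group1_mask[rng.permutation(n)]
    max_null = np.abs(
        _adjusted_t(values, masks, confounds, cfg.confound_centering)
    ).max(axis=1)

    abs_t = np.abs(t_obs)
    exceed = (max_null[:, None] >= abs_t[None, :]).sum(axis=0)
    if exhaustive:
        p_fwe = exceed / n_distinct
    else:
        p_fwe = (exceed + 1.0) / (cfg.n_permutations + 1.0)
    p_fwe = np.maximum(p_fwe, p_unc)

    alpha_adj = cfg.adjusted_alpha
    t_threshold = float(np.quantile(max_null, 1.0 - alpha_adj))
    p_cutoff = float(2.0 * sps.t.sf(t_threshold, df))
    return PermutationResult(
        t_obs=t_obs,
        p_uncorrected=p_unc,
        p_fwe=p_fwe,
        max_t_null=max_null,
        t_threshold=t_threshold,
        p_uncorrected_cutoff=p_cutoff,
        exhaustive=exhaustive,
        n_permutations_used=masks.shape[0],
        df=df,
        _alpha_adjusted=alpha_adj,
    )


# ---------------------------------------------------------------------------
# Clusters
# ---------------------------------------------------------------------------

def cluster_filter(significant_mask: np.ndarray, min_extent: int) -> list[tuple[int, int]]:
    """Maximal runs of contiguous True entries of length >= ``min_extent``.

    Returns half-open (start, stop) index pairs, ascending.
    """
    mask = np.asarray(significant_mask, dtype=bool)
    if min_extent < 1:
        raise ValueError("min_extent must be >= 1")
    padded = np.concatenate([[False], mask, [False]]).astype(int)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return [(int(a), int(b)) for a, b in zip(starts, stops) if b - a >= min_extent]


# ---------------------------------------------------------------------------
# Effect sizes and power
# ---------------------------------------------------------------------------

def cohens_d_from_t(t: float, n1: int, n2: int) -> float:
    """Cohen's d from a two-sample t: ``d = 2|t| / sqrt(n1 + n2 - 2)``.

    This is the conversion used with equal group sizes; the direction of the
    difference is carried by the sign of t, reported separately.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 subjects")
    return 2.0 * abs(float(t)) / math.sqrt(n1 + n2 - 2)


def cohens_f2(r: float) -> float:
    """Cohen's f^2 for a correlation: ``r^2 / (1 - r^2)``."""
    r = float(r)
    if abs(r) >= 1.0:
        warnings.warn("|r| >= 1: f^2 diverges", stacklevel=2)
        return math.inf
    return r * r / (1.0 - r * r)


def posthoc_power(d: float, n1: int, n2: int, alpha: float = 0.05) -> float:
    """Post-hoc power of a two-sided two-sample t-test at effect size ``d``.

    Uses the noncentral t distribution with noncentrality
    ``d * sqrt(n1 n2 / (n1 + n2))`` and df = n1 + n2 - 2.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    df = n1 + n2 - 2
    ncp = abs(float(d)) * math.sqrt(n1 * n2 / (n1 + n2))
    t_crit = sps.t.ppf(1.0 - alpha / 2.0, df)
    upper = sps.nct.sf(t_crit, df, ncp)
    lower = sps.nct.cdf(-t_crit, df, ncp)
    if math.isnan(lower):  # scipy underflows the far tail at large ncp
        lower = 0.0
    return float(min(upper + lower, 1.0))


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------

def correlation_pvalue(r: float, n: int) -> float:
    """Two-sided p of a Pearson correlation via the t transform (df = n - 2)."""
    r = float(r)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if abs(r) >= 1.0:
        return 0.0
    t = abs(r) * math.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * sps.t.sf(t, n - 2))


def _columnwise_pearson(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    xc = x - x.mean()
    Yc = Y - Y.mean(axis=0, keepdims=True)
    denom = np.sqrt((xc**2).sum() * (Yc**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc @ Yc) / denom
    return np.where(denom > 0, r, 0.0)


def semipartial_correlation(
    metric_values: np.ndarray,
    cofactor: np.ndarray,
    other_confounds: np.ndarray,
) -> np.ndarray:
    """Semi-partial Pearson r between a cofactor and adjusted metric columns.

    An OLS model of the metric on *all* confounds (intercept, cofactor, and
    the others, jointly) is fitted per column; the fitted contributions of
    the other confounds are subtracted from the metric, and the Pearson
    correlation of this adjusted metric with the raw cofactor is returned.
    """
    Y = np.asarray(metric_values, dtype=float)
    x = np.asarray(cofactor, dtype=float)
    others = np.asarray(other_confounds, dtype=float)
    if others.ndim == 1:
        others = others[:, None]
    if np.ptp(x) == 0:
        raise ValueError("cofactor is constant")
    design = np.column_stack([np.ones_like(x), x, others])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient design in semi-partial correlation")
    beta, *_ = np.linalg.lstsq(design, Y, rcond=None)
    adjusted = Y - others @ beta[2:]
    return _columnwise_pearson(x, adjusted)


@dataclass
class CorrelationPermutationResult:
    r_obs: np.ndarray
    p_fwe: np.ndarray
    max_r_null: np.ndarray
    exhaustive: bool
    n_permutations_used: int
    _alpha_adjusted: float = 0.05

    @property
    def significant(self) -> np.ndarray:
        return self.p_fwe < self._alpha_adjusted


def correlation_permutation_fwe(
    metric_values: np.ndarray,
    cofactor: np.ndarray,
    other_confounds: np.ndarray,
    cfg: StatsConfig,
    rng: np.random.Generator | None = None,
) -> CorrelationPermutationResult:
    """maxT-style FWE correction for semi-partial correlations.

    The cofactor values are permuted across subjects; for each permutation
    the full semi-partial model is re-fitted and the maximum |r| over all
    columns recorded.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    x = np.asarray(cofactor, dtype=float)
    r_obs = semipartial_correlation(metric_values, x, other_confounds)
    B = cfg.n_permutations
    max_null = np.empty(B)
    for b in range(B):
        xp = x[rng.permutation(x.size)]
        max_null[b] = np.abs(
            semipartial_correlation(metric_values, xp, other_confounds)
        ).max()
    exceed = (max_null[:, None] >= np.abs(r_obs)[None, :]).sum(axis=0)
    p_fwe = (exceed + 1.0) / (B + 1.0)
    return CorrelationPermutationResult(
        r_obs=r_obs,
        p_fwe=p_fwe,
        max_r_null=max_null,
        exhaustive=False,
        n_permutations_used=B,
        _alpha_adjusted=cfg.adjusted_alpha,
    )


# ---------------------------------------------------------------------------
# High-level analyses
# ---------------------------------------------------------------------------

def confound_design(cohort: pd.DataFrame) -> np.ndarray:
    """Confound matrix [hearing loss, THI, duration] in cohort row order.

    THI and tinnitus duration are 0 for controls (no tinnitus), a documented
    limitation of the full-group design.
    """
    X = cohort.loc[:, list(CONFOUND_COLUMNS)].to_numpy(dtype=float)
    return np.nan_to_num(X, nan=0.0)


def _stack_profiles(
    profiles: dict[str, np.ndarray],
) -> tuple[np.ndarray, list[tuple[str, int]], list[tuple[str, int]]]:
    """Stack per-bundle matrices column-wise, dropping incomplete segments.

    Returns (stacked complete-case matrix, kept (bundle, segment) labels,
    dropped (bundle, segment) labels).
    """
    blocks, labels, dropped = [], [], []
    for bundle, mat in profiles.items():
        mat = np.asarray(mat, dtype=float)
        ok = np.all(np.isfinite(mat), axis=0)
        blocks.append(mat[:, ok])
        labels += [(bundle, int(s)) for s in np.flatnonzero(ok)]
        dropped += [(bundle, int(s)) for s in np.flatnonzero(~ok)]
    return np.hstack(blocks), labels, dropped


def analyze_group_differences(
    profiles: dict[str, np.ndarray],
    cohort: pd.DataFrame,
    cfg: StatsConfig,
    metric_name: str = "",
    adjust_confounds: bool = True,
) -> pd.DataFrame:
    """Full between-group analysis of one metric run over several bundles.

    ``profiles`` maps bundle name to a (n_subjects x 100) matrix whose rows
    follow the cohort table order.  Returns one row per (bundle, segment)
    with t, uncorrected and FWE-corrected p, cluster membership after the
    extent filter, Cohen's d, and post-hoc power.
    """
    group1 = (cohort[GROUP_COLUMN] == TINNITUS).to_numpy()
    n1, n2 = int(group1.sum()), int((~group1).sum())
    values, labels, dropped = _stack_profiles(profiles)
    confounds = confound_design(cohort) if adjust_confounds else None
    perm = permutation_fwe(values, group1, cfg, confounds=confounds)

    rows = {
        (b, s): {
            "bundle": b,
            "metric": metric_name,
            "segment": s,
            "t": perm.t_obs[j],
            "p_uncorrected": perm.p_uncorrected[j],
            "p_fwe": perm.p_fwe[j],
            "significant": bool(perm.significant[j]),
            "cluster_id": None,
            "d": cohens_d_from_t(perm.t_obs[j], n1, n2),
            "direction": int(np.sign(perm.t_obs[j])),
            "power": posthoc_power(
                cohens_d_from_t(perm.t_obs[j], n1, n2), n1, n2, cfg.power_alpha
            ),
        }
        for j, (b, s) in enumerate(labels)
    }
    # cluster-extent filter within each bundle; segments significant by
    # p_fwe but outside a surviving cluster are demoted
    for bundle, mat in profiles.items():
        n_seg = mat.shape[1]
        mask = np.array(
            [rows.get((bundle, s), {}).get("significant", False) for s in range(n_seg)]
        )
        clusters = cluster_filter(mask, cfg.cluster_extent_min)
        in_cluster = np.zeros(n_seg, dtype=bool)
        for cid, (a, b_) in enumerate(clusters):
            in_cluster[a:b_] = True
            for s in range(a, b_):
                rows[(bundle, s)]["cluster_id"] = f"{bundle}_c{cid}"
        for s in range(n_seg):
            if (bundle, s) in rows and not in_cluster[s]:
                rows[(bundle, s)]["significant"] = False
    for b, s in dropped:
        rows[(b, s)] = {
            "bundle": b,
            "metric": metric_name,
            "segment": s,
            "t": np.nan,
            "p_uncorrected": np.nan,
            "p_fwe": np.nan,
            "significant": False,
            "cluster_id": None,
            "d": np.nan,
            "direction": 0,
            "power": np.nan,
        }
    table = pd.DataFrame(sorted(rows.values(), key=lambda r: (r["bundle"], r["segment"])))
    table.attrs["t_threshold"] = perm.t_threshold
    table.attrs["p_uncorrected_cutoff"] = perm.p_uncorrected_cutoff
    table.attrs["exhaustive"] = perm.exhaustive
    return table


def cluster_summary(stat_table: pd.DataFrame) -> pd.DataFrame:
    """Per-cluster summary: min uncorrected p and its segment, peak |t|, d, power."""
    sig = stat_table[stat_table["cluster_id"].notna()]
    rows = []
    for cid, grp in sig.groupby("cluster_id"):
        j = grp["p_uncorrected"].idxmin()
        rows.append(
            {
                "cluster_id": cid,
                "bundle": grp.loc[j, "bundle"],
                "metric": grp.loc[j, "metric"],
                "min_p": grp.loc[j, "p_uncorrected"],
                "segment": int(grp.loc[j, "segment"]),
                "t": grp.loc[j, "t"],
                "d": grp.loc[j, "d"],
                "power": grp.loc[j, "power"],
                "extent": len(grp),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cluster_id", "bundle", "metric", "min_p", "segment", "t", "d",
            "power", "extent",
        ],
    )


def analyze_correlations(
    profiles: dict[str, np.ndarray],
    cohort: pd.DataFrame,
    cofactor: str,
    cfg: StatsConfig,
    metric_name: str = "",
) -> pd.DataFrame:
    """Semi-partial correlation of one cofactor with a metric, FWE-corrected.

    Hearing loss is correlated over the whole cohort; THI and tinnitus
    duration only over the tinnitus group.
    """
    if cofactor not in CONFOUND_COLUMNS:
        raise ValueError(f"cofactor must be one of {CONFOUND_COLUMNS}")
    if cofactor == "hl_db":
        sel = np.ones(len(cohort), dtype=bool)
    else:
        sel = (cohort[GROUP_COLUMN] == TINNITUS).to_numpy()
    if sel.sum() < 4:
        raise ValueError("selected sample too small for correlation analysis")
    X = confound_design(cohort)[sel]
    j = CONFOUND_COLUMNS.index(cofactor)
    x = X[:, j]
    others = np.delete(X, j, axis=1)
    values, labels, _ = _stack_profiles({b: m[sel] for b, m in profiles.items()})
    perm = correlation_permutation_fwe(values, x, others, cfg)
    n = int(sel.sum())
    return pd.DataFrame(
        {
            "bundle": [b for b, _ in labels],
            "metric": metric_name,
            "segment": [s for _, s in labels],
            "cofactor": cofactor,
            "r": perm.r_obs,
            "p_uncorrected": [correlation_pvalue(r, n) for r in perm.r_obs],
            "p_fwe": perm.p_fwe,
            "significant": perm.significant,
            "f2": [cohens_f2(r) for r in perm.r_obs],
            "n": n,
        }
    )
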