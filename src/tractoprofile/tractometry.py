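"""Along-tract profiling: from a streamline bundle to a 100-segment profile.

The along-tract coordinate system is the bundle's *centroid fiber*: the
member streamline minimizing the mean flip-invariant corresponding-point
distance to all other members, resampled to 101 points / 100 segments.
Every streamline is resampled the same way; each of its small segments is
assigned the index of the nearest centroid segment (midpoint to midpoint),
the chosen metric is sampled at the segment midpoint with the segment
direction as reference, and per-centroid-segment values are averaged into
the subject's profile row.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import fod_metrics
from .fod_metrics import FODField, TensorField
from .sphere import SphereMesh

logger = logging.getLogger(__name__)

N_SEGMENTS = 100

METRICS = ("AFD", "peak_amplitude", "FA")


@dataclass
class StreamlineBundle:
    """A named set of 3D polylines in world-space millimetres."""

    name: str
    streamlines: list[np.ndarray]

    def __post_init__(self) -> None:
        self.streamlines = [np.asarray(s, dtype=float) for s in self.streamlines]
        for s in self.streamlines:
            if s.ndim != 2 or s.shape[1] != 3 or s.shape[0] < 2:
                raise ValueError("each streamline must be an (n>=2, 3) array")
            if not np.all(np.isfinite(s)):
                raise ValueError("streamline coordinates must be finite")

    def __len__(self) -> int:
        return len(self.streamlines)


@dataclass
class CentroidProfile:
    """The 101-point centroid polyline defining 100 along-tract segments."""

    bundle_name: str
    points: np.ndarray
    segment_count: int = N_SEGMENTS

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.shape != (self.segment_count + 1, 3):
            raise ValueError(
                f"centroid must have {self.segment_count + 1} points, "
                f"got {self.points.shape}"
            )

    @property
    def segment_midpoints(self) -> np.ndarray:
        return 0.5 * (self.points[:-1] + self.points[1:])


@dataclass
class ProfileMatrix:
    """Subjects x 100 segments of one metric in one bundle.

    ``missing`` marks segments that received no streamline points for some
    subject; such entries hold NaN and are excluded from statistics rather
    than imputed.
    """

    bundle_name: str
    metric_name: str
    values: np.ndarray
    subject_ids: list[str]
    missing: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != N_SEGMENTS:
            raise ValueError(f"profile matrix must have {N_SEGMENTS} columns")
        if len(self.subject_ids) != self.values.shape[0]:
            raise ValueError("subject_ids length must match row count")
        if self.missing is None:
            self.missing = np.isnan(self.values)
        self.missing = np.asarray(self.missing, dtype=bool)


def polyline_arclength(polyline: np.ndarray) -> float:
    seg = np.diff(np.asarray(polyline, dtype=float), axis=0)
    return float(np.linalg.norm(seg, axis=1).sum())


def resample(polyline: np.ndarray, n_points: int) -> np.ndarray:
    """Resample a polyline to ``n_points`` equally spaced by arc length.

    Endpoints are preserved exactly.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    p = np.asarray(polyline, dtype=float)
    seg_len = np.linalg.norm(np.diff(p, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = s[-1]
    if total <= 0:
        raise ValueError("cannot resample a zero-length polyline")
    targets = np.linspace(0.0, total, n_points)
    out = np.column_stack([np.interp(targets, s, p[:, k]) for k in range(3)])
    out[0], out[-1] = p[0], p[-1]
    return out


def _corresponding_distances(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """(direct, flipped) mean corresponding-point distances of two resampled lines."""
    direct = float(np.linalg.norm(a - b, axis=1).mean())
    flipped = float(np.linalg.norm(a - b[::-1], axis=1).mean())
    return direct, flipped


def mean_direct_flip_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Flip-invariant mean corresponding-point distance."""
    return min(_corresponding_distances(a, b))


def _resampled_stack(bundle: StreamlineBundle, n_points: int) -> np.ndarray:
    return np.stack([resample(s, n_points) for s in bundle.streamlines])


def centroid(bundle: StreamlineBundle, n_segments: int = N_SEGMENTS) -> CentroidProfile:
    """Centroid fiber: the member minimizing mean distance to all members.

    All streamlines are resampled to ``n_segments + 1`` points; the pairwise
    distance is the flip-invariant mean corresponding-point distance; ties
    are broken by the lowest streamline index.  The winner's resampled form
    is returned.
    """
    if len(bundle) == 0:
        raise ValueError(f"bundle '{bundle.name}' is empty")
    stack = _resampled_stack(bundle, n_segments + 1)
    n = stack.shape[0]
    if n == 1:
        return CentroidProfile(bundle.name, stack[0], n_segments)
    # (n, n) flip-invariant distance matrix, vectorized over pairs
    diff_d = np.linalg.norm(stack[:, None] - stack[None, :], axis=3).mean(axis=2)
    diff_f = np.linalg.norm(stack[:, None] - stack[None, :, ::-1], axis=3).mean(axis=2)
    dist = np.minimum(diff_d, diff_f)
    mean_dist = (dist.sum(axis=1)) / (n - 1)  # diagonal is zero
    winner = int(np.argmin(mean_dist))  # argmin takes the first (lowest index) on ties
    return CentroidProfile(bundle.name, stack[winner], n_segments)


def orient(bundle: StreamlineBundle, centroid_profile: CentroidProfile) -> StreamlineBundle:
    """Flip streamlines so their direct distance to the centroid is minimal.

    After orientation all streamlines traverse the bundle in the centroid's
    direction, so segment indices agree across streamlines.  Idempotent.
    """
    n_pts = centroid_profile.segment_count + 1
    ref = centroid_profile.points
    oriented = []
    for s in bundle.streamlines:
        rs = resample(s, n_pts)
        direct, flipped = _corresponding_distances(rs, ref)
        oriented.append(s[::-1].copy() if flipped < direct else s.copy())
    return StreamlineBundle(bundle.name, oriented)


def assign_segments(
    bundle_oriented: StreamlineBundle, centroid_profile: CentroidProfile
) -> list[np.ndarray]:
    """Nearest-centroid-segment index for each small segment of each streamline.

    Each streamline is resampled to 101 points (100 segments); each segment
    midpoint is assigned the index of the Euclidean-nearest centroid segment
    midpoint.  Returns one int array of length 100 per streamline.
    """
    tree = cKDTree(centroid_profile.segment_midpoints)
    n_pts = centroid_profile.segment_count + 1
    out = []
    for s in bundle_oriented.streamlines:
        rs = resample(s, n_pts)
        mid = 0.5 * (rs[:-1] + rs[1:])
        _, idx = tree.query(mid)
        out.append(idx.astype(np.int64))
    return out


def _segment_midpoints_tangents(
    bundle: StreamlineBundle, n_points: int
) -> tuple[np.ndarray, np.ndarray]:
    stack = _resampled_stack(bundle, n_points)
    mids = 0.5 * (stack[:, :-1] + stack[:, 1:])
    tangents = stack[:, 1:] - stack[:, :-1]
    norms = np.linalg.norm(tangents, axis=2, keepdims=True)
    tangents = np.divide(tangents, norms, out=np.zeros_like(tangents), where=norms > 0)
    return mids.reshape(-1, 3), tangents.reshape(-1, 3)


def profile(
    bundle: StreamlineBundle,
    centroid_profile: CentroidProfile,
    field: FODField | TensorField,
    metric_name: str,
    mesh: SphereMesh | None = None,
    amplitude_floor_frac: float = fod_metrics.DEFAULT_AMPLITUDE_FLOOR,
) -> np.ndarray:
    """One subject's 100-segment profile of a metric along a bundle.

    Metric values are sampled at every streamline-segment midpoint (with the
    segment direction as the reference axis for AFD and peak amplitude) and
    averaged per assigned centroid segment.  Segments with no assigned
    points are NaN; >20% missing raises a logged warning, all missing is an
    error.
    """
    if metric_name not in METRICS:
        raise ValueError(f"unknown metric '{metric_name}', expected one of {METRICS}")
    oriented = orient(bundle, centroid_profile)
    assignments = np.concatenate(assign_segments(oriented, centroid_profile))
    mids, tangents = _segment_midpoints_tangents(oriented, centroid_profile.segment_count + 1)

    if metric_name == "FA":
        if not isinstance(field, TensorField):
            raise TypeError("FA requires a TensorField")
        values = fod_metrics.fa_batch(field, mids)
    else:
        if not isinstance(field, FODField):
            raise TypeError(f"{metric_name} requires an FODField")
        afd, peak = fod_metrics.afd_and_peak_batch(
            field, mids, tangents, mesh=mesh, amplitude_floor_frac=amplitude_floor_frac
        )
        values = afd if metric_name == "AFD" else peak

    n_seg = centroid_profile.segment_count
    counts = np.bincount(assignments, minlength=n_seg).astype(float)
    sums = np.bincount(assignments, weights=values, minlength=n_seg)
    out = np.full(n_seg, np.nan)
    nz = counts > 0
    out[nz] = sums[nz] / counts[nz]
    n_missing = int((~nz).sum())
    if n_missing == n_seg:
        raise ValueError(f"no segment of '{bundle.name}' received any points")
    if n_missing > 0.2 * n_seg:
        logger.warning(
            "bundle '%s': %d/%d segments have no assigned points",
            bundle.name,
            n_missing,
            n_seg,
        )
    return out


def znorm(profile_matrix: ProfileMatrix) -> ProfileMatrix:
    """Z-score a profile matrix over all subjects and segments of its bundle.

    Enables cross-metric comparison of profiles on one dimensionless scale.
    A constant matrix (sd = 0) maps to all zeros with a warning.
    """
    vals = profile_matrix.values
    finite = np.isfinite(vals)
    mu = vals[finite].mean()
    sd = vals[finite].std(ddof=0)
    if sd <= 1e-12 * max(1.0, abs(mu)):  # constant up to rounding
        warnings.warn(
            f"bundle '{profile_matrix.bundle_name}' metric "
            f"'{profile_matrix.metric_name}' is constant; z-scores set to 0",
            stacklevel=2,
        )
        z = np.where(finite, 0.0, np.nan)
    else:
        z = np.where(finite, (vals - mu) / sd, np.nan)
    return ProfileMatrix(
        profile_matrix.bundle_name,
        profile_matrix.metric_name,
        z,
        list(profile_matrix.subject_ids),
    )
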