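"""Curvature metrics on trimmed stent centerlines.

Two complementary readings of stent tortuosity:

* **Segment vector angles** — the centerline is divided into ``k`` contiguous
  segments (default 100); each segment gets the unit direction vector of its
  total-least-squares line fit, and angles between vectors are measured.  In
  ``consecutive`` mode the angle is between adjacent segments of one image; in
  ``cross_timepoint`` mode it is between the same segment's direction at the
  two imaging timepoints.  The per-image summary is the mean angle in degrees.

* **Pointwise slope** — the gradient d(lateral)/d(axial) between consecutive
  centerline points, summarized as the sum of absolute gradients and as their
  mean (the *normalized mean slope*).  A perfectly straight vertical stent
  scores 0; the score grows with lateral excursion per unit length, so a
  straightening stent scores lower at follow-up.

The axial coordinate is the independent variable throughout: the stent runs
roughly head-to-foot, so axial position is strictly increasing along the curve
and the gradient is finite, whereas differentiating against the lateral
coordinate would blow up on a straight stent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .centerline import Centerline

__all__ = [
    "SegmentVector",
    "AngleProfile",
    "SlopeProfile",
    "split_segments",
    "fit_segment_vector",
    "angle_between",
    "algorithm1_profile",
    "algorithm1_change",
    "algorithm2_slope",
]


@dataclass(frozen=True)
class SegmentVector:
    """Unit direction of a fitted segment line.

    ``vx`` is the lateral component and ``vy`` the axial component.  The fit
    direction is a line direction, not a heading, so the sign is normalized to
    ``vy >= 0`` (and ``vx >= 0`` when exactly horizontal); without that, two
    nearly identical segments can report an angle near 180 degrees purely
    because the fits picked opposite signs.
    """

    vx: float
    vy: float
    segment_index: int = 0

    def __post_init__(self) -> None:
        norm = self.vx * self.vx + self.vy * self.vy
        if not math.isclose(norm, 1.0, abs_tol=1e-9):
            raise ValueError(f"segment vector must be unit length, |v|^2 = {norm}")
        if self.vy < 0 or (self.vy == 0 and self.vx < 0):
            raise ValueError("segment vector must be normalized to vy >= 0")


@dataclass(frozen=True)
class AngleProfile:
    """Per-comparison inter-vector angles in degrees.

    ``mode`` is ``"consecutive"`` (adjacent segments of one centerline, k-1
    angles) or ``"cross_timepoint"`` (same segment index across two
    centerlines, k angles).
    """

    angles_deg: np.ndarray = field(repr=False)
    mode: str = "consecutive"
    k: int = 0

    def __post_init__(self) -> None:
        angles = np.asarray(self.angles_deg, dtype=float)
        if self.mode not in ("consecutive", "cross_timepoint"):
            raise ValueError(f"unknown mode {self.mode!r}")
        expected = self.k - 1 if self.mode == "consecutive" else self.k
        if angles.size != expected:
            raise ValueError(f"expected {expected} angles for mode {self.mode!r}, got {angles.size}")
        object.__setattr__(self, "angles_deg", angles)

    @property
    def mean_deg(self) -> float:
        return float(np.mean(self.angles_deg))


@dataclass(frozen=True)
class SlopeProfile:
    """Per-step centerline gradients with their absolute-value summaries."""

    gradients: np.ndarray = field(repr=False)
    abs_sum: float = 0.0
    mean_abs: float = 0.0

    @property
    def n_steps(self) -> int:
        return int(np.asarray(self.gradients).size)


def split_segments(cl: Centerline, k: int = 100) -> list[np.ndarray]:
    """Partition the centerline into ``k`` contiguous ordered segments.

    Segment sizes differ by at most one; when ``n`` is not divisible by ``k``
    the remainder is spread over the leading segments.  Every segment needs at
    least two points for a line fit, hence the ``n >= 2k`` requirement.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    n = len(cl)
    if n < 2 * k:
        raise ValueError(f"centerline has {n} points; k={k} segments require at least {2 * k}")
    points = cl.as_points()
    base, rem = divmod(n, k)
    sizes = np.full(k, base, dtype=int)
    sizes[:rem] += 1
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    return [points[bounds[i] : bounds[i + 1]] for i in range(k)]


def fit_segment_vector(points: np.ndarray, segment_index: int = 0) -> SegmentVector:
    """Unit direction of the orthogonal-distance (total-least-squares) line.

    The direction is the principal axis of the centered point cloud, i.e. the
    leading right singular vector of the centered coordinates — identical to
    the dominant eigenvector of the 2x2 scatter matrix.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("need an (m >= 2, 2) array of (axial, lateral) points")
    centered = pts - pts.mean(axis=0)
    if not centered.any():
        raise ValueError("degenerate segment")
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    d_axial, d_lateral = vt[0]
    if d_axial < 0 or (d_axial == 0 and d_lateral < 0):
        d_axial, d_lateral = -d_axial, -d_lateral
    return SegmentVector(vx=float(d_lateral), vy=float(d_axial), segment_index=segment_index)


def angle_between(a: SegmentVector, b: SegmentVector, pi_value: float = math.pi) -> float:
    """Angle between two unit segment vectors, in degrees.

    Computed as acos of the dot product.  If floating-point accumulation
    pushes the dot product outside [-1, 1] the angle is returned as exactly 0;
    with both vectors normalized to vy >= 0 the only reachable overshoot is
    just past +1, i.e. two effectively identical directions.

    ``pi_value`` is the constant used in the radian-to-degree conversion
    (180 / pi); pass 3.14 to reproduce output of software that hard-codes the
    two-decimal approximation.
    """
    dot = a.vx * b.vx + a.vy * b.vy
    if dot < -1.0 or dot > 1.0:
        return 0.0
    return math.acos(dot) * 180.0 / pi_value


def _segment_vectors(cl: Centerline, k: int) -> list[SegmentVector]:
    return [fit_segment_vector(seg, i) for i, seg in enumerate(split_segments(cl, k))]


def algorithm1_profile(cl: Centerline, k: int = 100, pi_value: float = math.pi) -> AngleProfile:
    """Consecutive-segment vector angles of a single centerline.

    Fits a direction to each of the ``k`` segments and measures the angle
    between each adjacent pair, giving ``k - 1`` angles; ``mean_deg`` is the
    per-image tortuosity summary.
    """
    vecs = _segment_vectors(cl, k)
    angles = [angle_between(vecs[i], vecs[i + 1], pi_value) for i in range(k - 1)]
    return AngleProfile(angles_deg=np.asarray(angles), mode="consecutive", k=k)


def algorithm1_change(
    pre_cl: Centerline, post_cl: Centerline, k: int = 100, pi_value: float = math.pi
) -> AngleProfile:
    """Segment-wise direction change between two timepoints of one patient.

    Segment ``i`` of the pre centerline is compared with segment ``i`` of the
    post centerline, giving ``k`` angles; ``mean_deg`` summarizes how much the
    stent's local directions rotated between acquisitions.  Meaningful only to
    the extent the two ROIs are axially aligned.
    """
    pre_vecs = _segment_vectors(pre_cl, k)
    post_vecs = _segment_vectors(post_cl, k)
    angles = [angle_between(pre_vecs[i], post_vecs[i], pi_value) for i in range(k)]
    return AngleProfile(angles_deg=np.asarray(angles), mode="cross_timepoint", k=k)


def algorithm2_slope(cl: Centerline) -> SlopeProfile:
    """Pointwise gradient profile of a centerline.

    gradient_i = (lateral_{i+1} - lateral_i) / (axial_{i+1} - axial_i).

    ``abs_sum`` totals the absolute gradients (total lateral excursion per
    unit axial length); ``mean_abs`` divides by the step count and is the
    normalized mean slope, the headline per-image statistic.  Magnitudes are
    used because signed slopes of a laterally symmetric curve cancel to zero
    regardless of how tortuous it is.
    """
    if len(cl) < 2:
        raise ValueError("need at least 2 centerline points")
    d_axial = np.diff(cl.axial)
    if (d_axial == 0).any():  # impossible for a valid Centerline, but guarded
        raise ValueError("duplicate axial coordinates")
    gradients = np.diff(cl.lateral) / d_axial
    abs_sum = float(np.abs(gradients).sum())
    return SlopeProfile(gradients=gradients, abs_sum=abs_sum, mean_abs=abs_sum / gradients.size)
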