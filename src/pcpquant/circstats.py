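"""Circular and axial statistics for planar-polarity data.

Polarity axes, cell-elongation axes and microtubule orientations are all
*axial* quantities: an orientation of 10 deg is the same axis as 190 deg, so
every statistic here doubles angles (psi -> 2 psi) before treating them as
points on the circle, and halves the result on the way back.  This is the
standard nematic-order construction and is used consistently by every module
in the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats

__all__ = [
    "wrap_axial",
    "wrap_axial_signed",
    "axial_difference",
    "axial_mean",
    "circular_summary",
    "CircularSummary",
    "polar_histogram",
    "PolarHistogram",
    "quadrant_split",
    "polarity_vectors",
    "hotelling_t2",
    "HotellingResult",
]


def wrap_axial(angles_deg):
    """Wrap axial angles (period 180 deg) into [0, 180)."""
    return np.asarray(angles_deg, dtype=float) % 180.0


def wrap_axial_signed(angles_deg):
    """Wrap axial angles into (-90, 90]."""
    w = np.asarray(angles_deg, dtype=float) % 180.0
    out = np.where(w > 90.0, w - 180.0, w)
    return out if out.ndim else float(out)


def axial_difference(a_deg, b_deg):
    """Signed axial difference a - b, wrapped to (-90, 90]."""
    return wrap_axial_signed(np.asarray(a_deg, float) - np.asarray(b_deg, float))


def axial_mean(angles_deg, weights=None):
    """Weighted axial mean direction and mean resultant length.

    Returns ``(mean_deg, rbar)`` where the mean is in [0, 180) and ``rbar``
    is the mean resultant length of the doubled angles (1 = perfectly
    aligned, 0 = no preferred axis).  The mean is NaN when ``rbar`` vanishes.
    """
    a = np.radians(2.0 * np.asarray(angles_deg, dtype=float))
    if weights is None:
        weights = np.ones_like(a)
    w = np.asarray(weights, dtype=float)
    tot = w.sum()
    if tot <= 0:
        raise ValueError("total weight must be positive")
    c = float(np.sum(w * np.cos(a)) / tot)
    s = float(np.sum(w * np.sin(a)) / tot)
    rbar = math.hypot(c, s)
    if rbar < 1e-12:
        return float("nan"), rbar
    mean = math.degrees(math.atan2(s, c)) / 2.0
    return float(mean % 180.0), rbar


@dataclass(frozen=True)
class CircularSummary:
    mean_deg: float          # axial mean in [0, 180); NaN when undefined
    rbar: float              # mean resultant length of doubled angles
    circular_sd_deg: float   # (180/pi) * sqrt(-2 ln rbar) / 2
    n: int

    @property
    def mean_defined(self) -> bool:
        return not math.isnan(self.mean_deg)


def circular_summary(angles_deg, weights=None) -> CircularSummary:
    """Axial mean, mean resultant length and circular SD of a sample.

    The circular SD is computed on doubled angles and halved, so it is
    directly comparable to the MTSD reported for microtubule textures.
    """
    angles_deg = np.atleast_1d(np.asarray(angles_deg, dtype=float))
    if angles_deg.size == 0:
        raise ValueError("empty sample")
    mean, rbar = axial_mean(angles_deg, weights)
    if rbar < 1e-12:
        sd = float("inf")
    else:
        sd = math.degrees(math.sqrt(-2.0 * math.log(rbar))) / 2.0
    return CircularSummary(mean, rbar, sd, int(angles_deg.size))


@dataclass(frozen=True)
class PolarHistogram:
    bin_edges_deg: np.ndarray      # length bins+1, spanning [0, 180]
    counts: np.ndarray             # per-bin counts (or weight sums)
    mirrored_edges_deg: np.ndarray = field(repr=False, default=None)
    mirrored_counts: np.ndarray = field(repr=False, default=None)


def polar_histogram(angles_deg, bins: int = 9, mirrored: bool = True,
                    weights=None) -> PolarHistogram:
    """Histogram of axial angles over [0, 180) with equal-width bins.

    With the default 9 bins the bin width is 20 deg.  ``mirrored=True``
    additionally returns the display form in which every count is duplicated
    at angle + 180 deg (full-circle rose plots of axial data); the
    pre-mirroring counts always sum to the sample size.
    """
    if bins < 1:
        raise ValueError("bins must be >= 1")
    a = wrap_axial(np.atleast_1d(angles_deg))
    edges = np.linspace(0.0, 180.0, bins + 1)
    counts, _ = np.histogram(a, bins=edges, weights=weights)
    if not mirrored:
        return PolarHistogram(edges, counts)
    m_edges = np.concatenate([edges[:-1], edges + 180.0])
    m_counts = np.concatenate([counts, counts])
    return PolarHistogram(edges, counts, m_edges, m_counts)


def quadrant_split(normalized_angles_deg):
    """Split reference-normalised axial angles into two quadrants.

    Angles are wrapped to (-45, 135] and counted in (-45, 45] (axis near the
    reference) versus (45, 135] (axis near the perpendicular).  Intervals are
    left-open/right-closed, so an angle at exactly 45 deg falls in the first
    quadrant.
    """
    a = np.atleast_1d(np.asarray(normalized_angles_deg, dtype=float))
    w = (a + 45.0) % 180.0 - 45.0
    first = int(np.count_nonzero(w <= 45.0))
    return first, int(w.size - first)


def polarity_vectors(magnitudes, angles_deg):
    """Map per-wing (M, psi) pairs to doubled-angle Cartesian vectors.

    Each axial measurement becomes ``(M cos 2psi, M sin 2psi)``; these are
    the 2-D vectors compared by :func:`hotelling_t2`.
    """
    m = np.asarray(magnitudes, dtype=float)
    a = np.radians(2.0 * np.asarray(angles_deg, dtype=float))
    return np.column_stack([m * np.cos(a), m * np.sin(a)])


@dataclass(frozen=True)
class HotellingResult:
    t2: float
    f_stat: float
    df: tuple
    p_value: float
    mean_a: np.ndarray
    mean_b: np.ndarray | None


def _inv_pooled(cov: np.ndarray) -> np.ndarray:
    evals, evecs = np.linalg.eigh(cov)
    if evals.min() <= 1e-12 * max(evals.max(), 1e-300):
        direction = evecs[:, int(np.argmin(evals))]
        raise np.linalg.LinAlgError(
            "singular covariance: no variation along direction "
            f"({direction[0]:+.3f}, {direction[1]:+.3f})"
        )
    return evecs @ np.diag(1.0 / evals) @ evecs.T


def hotelling_t2(group_a, group_b=None, mu0=(0.0, 0.0)) -> HotellingResult:
    """Hotelling's T-squared test on 2-D polarity vectors.

    Two-sample form (``group_b`` given): pooled-covariance T2 comparing the
    mean polarity vectors of two sets of wings; the F transform has
    (2, nA + nB - 3) degrees of freedom.  One-sample form (``group_b`` is
    None): tests the group mean against the fixed point ``mu0`` with
    (2, n - 2) degrees of freedom.  Each row of a group is one wing's
    doubled-angle vector (M cos 2psi, M sin 2psi).
    """
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    p = a.shape[1]
    if p != 2:
        raise ValueError("expected 2-D polarity vectors")
    na = a.shape[0]
    mean_a = a.mean(axis=0)

    if group_b is None:
        if na < 3:
            raise ValueError("need at least 3 observations")
        s = np.cov(a, rowvar=False)
        d = mean_a - np.asarray(mu0, dtype=float)
        t2 = float(na * d @ _inv_pooled(s) @ d)
        f_stat = (na - p) / (p * (na - 1)) * t2
        df = (p, na - p)
        pval = float(sstats.f.sf(f_stat, *df))
        return HotellingResult(t2, f_stat, df, min(max(pval, 0.0), 1.0),
                               mean_a, None)

    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    nb = b.shape[0]
    if na < 3 or nb < 3:
        raise ValueError("need at least 3 observations per group")
    mean_b = b.mean(axis=0)
    pooled = ((na - 1) * np.cov(a, rowvar=False)
              + (nb - 1) * np.cov(b, rowvar=False)) / (na + nb - 2)
    d = mean_a - mean_b
    t2 = float(na * nb / (na + nb) * d @ _inv_pooled(pooled) @ d)
    f_stat = (na + nb - p - 1) / (p * (na + nb - 2)) * t2
    df = (p, na + nb - p - 1)
    pval = float(sstats.f.sf(f_stat, *df))
    return HotellingResult(t2, f_stat, df, min(max(pval, 0.0), 1.0),
                           mean_a, mean_b)
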