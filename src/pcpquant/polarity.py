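"""Per-cell PCA polarity, wing aggregates and timer stable fractions.

The polarity statistic treats each cell's membrane fluorescence as a set of
intensity-weighted pseudo-points on a circle.  The cell is first mapped
onto the unit circle using its best-fit ellipse (rotate by -phi, scale the
axes by 1/a and 1/b), which makes the readout insensitive to cell shape.
Membrane pixels are pooled into equal-angle sectors around the centroid
(their mean intensity per sector, so the estimate does not depend on how
densely the rasterised membrane samples each direction), sector intensities
are normalised by their mean, each sector becomes the pseudo-point
``q_k = I_k_hat (cos th_k, sin th_k)`` at its angular position ``th_k``,
and the second-moment matrix of the pseudo-points about the origin is
diagonalised.  The principal-eigenvector orientation is the polarity angle
(the axis of largest variance of the normalised intensities) and the
eigenvalue asymmetry

    M = (l1 - l2) / (l1 + l2)

is the polarity magnitude: 0 for a uniform membrane ring, 1 for intensity
concentrated on a single axis.  Moments are taken about the origin rather
than the pseudo-point mean, so unipolar (crescent) and bipolar
distributions both register on the correct axis and a uniform ring gives
exactly M = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .circstats import wrap_axial_signed
from .geometry import CellGeometry, TissueGraph

__all__ = [
    "PolarityMeasurement",
    "WingPolarity",
    "StableFraction",
    "membrane_pseudo_points",
    "compute_cell_polarity",
    "normalize_angles",
    "aggregate_wing",
    "stable_fraction",
    "estimate_background",
    "measure_tissue_polarity",
]

MIN_MEMBRANE_PIXELS = 8
# coefficient of variation of normalised intensities below which the
# membrane is treated as uniform: angle undefined, M = 0
UNIFORM_CV_TOL = 1e-3
# angular sectors used to pool membrane pixels into pseudo-points
N_SECTORS = 72
# a measurement needs membrane signal over at least this many sectors
MIN_SECTORS = 8


@dataclass(frozen=True)
class PolarityMeasurement:
    cell: int
    angle_deg: float       # psi, axial, (-90, 90]; NaN when undefined
    magnitude: float       # M = (l1 - l2)/(l1 + l2) in [0, 1]
    lambda1: float
    lambda2: float
    valid: bool

    @property
    def angle_defined(self) -> bool:
        return not math.isnan(self.angle_deg)


@dataclass(frozen=True)
class WingPolarity:
    magnitude: float
    angle_deg: float
    n_cells: int


@dataclass(frozen=True)
class StableFraction:
    cell: int
    ratio: float           # NaN when the denominator is not positive
    valid: bool


def membrane_pseudo_points(coords_rc, intensities,
                           geometry: CellGeometry,
                           n_sectors: int = N_SECTORS):
    """Shape-normalised pseudo-points of a cell's membrane fluorescence.

    Pixel positions are mapped onto the unit circle (translate to the
    centroid, rotate by -phi, scale the axes by 1/a and 1/b), pooled into
    ``n_sectors`` equal angular sectors, and each non-empty sector becomes
    a point at its bisector angle with radius equal to its mean intensity
    normalised by the mean over sectors.  Pooling by angle, not by pixel,
    keeps the statistic independent of how densely the rasterised membrane
    samples each direction.  Returns ``(theta_rad, ihat)`` arrays.
    """
    coords = np.asarray(coords_rc, dtype=float)
    inten = np.asarray(intensities, dtype=float)
    if coords.shape[0] != inten.shape[0]:
        raise ValueError("coords and intensities must have equal length")
    cr, cc = geometry.centroid_rc
    x = coords[:, 1] - cc
    y = -(coords[:, 0] - cr)              # math convention
    if geometry.orientation_defined:
        phi = math.radians(geometry.orientation_deg)
        a, b = geometry.semi_major, geometry.semi_minor
    else:
        phi, a = 0.0, geometry.semi_major
        b = a if a > 0 else 1.0
    cph, sph = math.cos(-phi), math.sin(-phi)
    u = (x * cph - y * sph) / max(a, 1e-9)
    v = (x * sph + y * cph) / max(b, 1e-9)
    theta = np.arctan2(v, u)

    idx = np.floor((theta + math.pi) / (2.0 * math.pi) * n_sectors)
    idx = np.clip(idx.astype(int), 0, n_sectors - 1)
    sums = np.bincount(idx, weights=inten, minlength=n_sectors)
    counts = np.bincount(idx, minlength=n_sectors)
    occupied = counts > 0
    means = sums[occupied] / counts[occupied]
    centers = (np.arange(n_sectors)[occupied] + 0.5) \
        * (2.0 * math.pi / n_sectors) - math.pi
    grand = means.mean()
    ihat = means / grand if grand > 0 else means
    return centers, ihat


def compute_cell_polarity(coords_rc, intensities,
                          geometry: CellGeometry,
                          n_sectors: int = N_SECTORS
                          ) -> PolarityMeasurement:
    """PCA polarity angle and magnitude of one cell's membrane pixels.

    ``coords_rc`` are (row, col) membrane-band pixel coordinates and
    ``intensities`` their fluorescence values; ``geometry`` supplies the
    centroid and best-fit ellipse used for shape normalisation.  The
    returned angle is mapped back to the image frame by undoing the
    normalising rotation, so a polarity axis along the image horizontal
    reports 0 deg regardless of cell orientation.
    """
    coords = np.asarray(coords_rc, dtype=float)
    inten = np.asarray(intensities, dtype=float)
    if coords.shape[0] < MIN_MEMBRANE_PIXELS or not np.all(
            np.isfinite(inten)) or np.any(inten < 0):
        return PolarityMeasurement(geometry.label, float("nan"), 0.0,
                                   0.0, 0.0, False)
    if inten.mean() <= 0:
        return PolarityMeasurement(geometry.label, float("nan"), 0.0,
                                   0.0, 0.0, False)
    theta, ihat = membrane_pseudo_points(coords, inten, geometry, n_sectors)
    if theta.size < MIN_SECTORS:
        return PolarityMeasurement(geometry.label, float("nan"), 0.0,
                                   0.0, 0.0, False)

    if np.std(ihat) < UNIFORM_CV_TOL:
        return PolarityMeasurement(geometry.label, float("nan"), 0.0,
                                   0.5, 0.5, True)

    qx = ihat * np.cos(theta)
    qy = ihat * np.sin(theta)
    n = qx.size
    cxx = float(qx @ qx) / n
    cyy = float(qy @ qy) / n
    cxy = float(qx @ qy) / n
    tr = cxx + cyy
    disc = math.sqrt(max((cxx - cyy) ** 2 / 4.0 + cxy * cxy, 0.0))
    l1, l2 = tr / 2.0 + disc, max(tr / 2.0 - disc, 0.0)
    mag = (l1 - l2) / (l1 + l2) if l1 + l2 > 0 else 0.0
    psi_norm = math.degrees(0.5 * math.atan2(2.0 * cxy, cxx - cyy))
    phi_deg = geometry.orientation_deg if geometry.orientation_defined \
        else 0.0
    psi = float(wrap_axial_signed(psi_norm + phi_deg))
    return PolarityMeasurement(geometry.label, psi, float(mag),
                               float(l1), float(l2), True)


def normalize_angles(angles_deg, reference_deg):
    """Subtract a reference axis and wrap to (-90, 90].

    The reference is typically the mean cell-elongation axis of the image
    or the overexpression-boundary axis.
    """
    if reference_deg is None or (isinstance(reference_deg, float)
                                 and math.isnan(reference_deg)):
        raise ValueError("reference angle is undefined")
    return wrap_axial_signed(np.asarray(angles_deg, float)
                             - float(reference_deg))


def aggregate_wing(measurements) -> WingPolarity:
    """Average polarity over the cells of one wing.

    Each valid cell with a defined angle contributes the doubled-angle
    vector ``(M cos 2psi, M sin 2psi)``; the wing polarity is the
    component-wise mean, reported as (magnitude, half-argument).  Cells on
    orthogonal axes therefore cancel, as axial data require.
    """
    vx = vy = 0.0
    n = 0
    for m in measurements:
        if not m.valid:
            continue
        n += 1
        if m.angle_defined:
            t = math.radians(2.0 * m.angle_deg)
            vx += m.magnitude * math.cos(t)
            vy += m.magnitude * math.sin(t)
        # undefined-angle cells have M = 0 and contribute a zero vector
    if n == 0:
        raise ValueError("no valid cells to aggregate")
    vx /= n
    vy /= n
    mag = math.hypot(vx, vy)
    ang = float("nan") if mag < 1e-12 else \
        float(wrap_axial_signed(math.degrees(math.atan2(vy, vx)) / 2.0))
    return WingPolarity(float(mag), ang, n)


def stable_fraction(coords_rc, mkate2, sfgfp, background=(0.0, 0.0),
                    cell: int = 0) -> StableFraction:
    """Timer ratio r = mean(mKate2 - bg) / mean(sfGFP - bg) on a membrane
    pixel set; proxies the stable (old) protein fraction."""
    coords = np.asarray(coords_rc, dtype=int)
    bk, bg_ = float(background[0]), float(background[1])
    num = float(mkate2[coords[:, 0], coords[:, 1]].mean()) - bk
    den = float(sfgfp[coords[:, 0], coords[:, 1]].mean()) - bg_
    if den <= 0:
        return StableFraction(cell, float("nan"), False)
    return StableFraction(cell, max(num, 0.0) / den, True)


def estimate_background(graph: TissueGraph, channel,
                        erosion: int = 2) -> float:
    """Per-image autofluorescence estimate: mean intensity of cell-interior
    pixels (each cell eroded to stay clear of the membrane band)."""
    from scipy import ndimage as ndi
    interior = graph.labels > 0
    interior = ndi.binary_erosion(interior, iterations=max(erosion, 1))
    if not interior.any():
        raise ValueError("no interior pixels available")
    return float(np.asarray(channel, float)[interior].mean())


def measure_tissue_polarity(graph: TissueGraph, channel,
                            background: float = 0.0,
                            timer=None, timer_background=(0.0, 0.0)):
    """Per-cell polarity (and optional timer ratio) for a whole tissue.

    Returns a list of (PolarityMeasurement, StableFraction-or-None) in cell
    order; cells without membrane-band pixels yield invalid measurements.
    ``timer`` is an optional (mKate2, sfGFP) image pair.
    """
    out = []
    ch = np.asarray(channel, dtype=float)
    for lab in graph.cells:
        band = graph.cell_membrane_band(lab)
        geom = graph.cell_geometry(lab)
        if band.shape[0] == 0:
            out.append((PolarityMeasurement(lab, float("nan"), 0.0, 0.0,
                                            0.0, False), None))
            continue
        inten = ch[band[:, 0], band[:, 1]] - background
        inten = np.clip(inten, 0.0, None)
        pm = compute_cell_polarity(band, inten, geom)
        sf = None
        if timer is not None:
            sf = stable_fraction(band, timer[0], timer[1],
                                 timer_background, cell=lab)
        out.append((pm, sf))
    return out
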