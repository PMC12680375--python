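"""Texture (microtubule) orientation analysis per cell.

The apical microtubule network of each cell is summarised from the tubulin
channel in four steps: (1) per-image contrast normalisation by percentile
clipping; (2) per-cell orientation distributions from the gradient of the
signal, computed with two 5 x 5 Sobel operators and weighted by gradient
magnitude (a filament's gradient is normal to it, so the texture
orientation is the gradient direction + 90 deg); (3) a weighted Von Mises
fit on doubled angles whose mean is the main microtubule direction and
whose circular standard deviation is the MTSD, the per-cell measure of
microtubule co-alignment (small MTSD = well aligned); (4) average
orientation profiles aligned to their maxima, grouped by cell-eccentricity
bin, for population-level comparisons.

Cells whose orientation distribution cannot be fitted (near-uniform
gradients) or whose MTSD is not below 90 deg are excluded from MTSD
summaries.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.optimize import brentq, least_squares
from scipy.special import i0e, i1e

from .circstats import wrap_axial

__all__ = [
    "SOBEL5_X",
    "SOBEL5_Y",
    "OrientationDistribution",
    "OrientationFit",
    "percentile_clip",
    "sobel_gradients",
    "gradient_orientation_distribution",
    "fit_von_mises",
    "mtsd_from_kappa",
    "aligned_average_profile",
    "DEFAULT_ECC_BINS",
]

# separable 5x5 Sobel pair: binomial smoothing x central derivative
_SMOOTH5 = np.array([1.0, 4.0, 6.0, 4.0, 1.0])
_DERIV5 = np.array([-1.0, -2.0, 0.0, 2.0, 1.0])
SOBEL5_X = np.outer(_SMOOTH5, _DERIV5)      # d/dx (columns)
SOBEL5_Y = np.outer(_DERIV5, _SMOOTH5)      # d/dy (rows)

MIN_CELL_PIXELS = 25
_RBAR_TOL = 1e-9

# eccentricity bins used for aligned average profiles: (centre, half-width)
DEFAULT_ECC_BINS = ((0.750, 0.025), (0.800, 0.025))


def percentile_clip(image, lower: float = 0.5, upper: float = 99.5):
    """Saturate the darkest/brightest pixel tails and rescale to [0, 1].

    Values below the ``lower`` percentile map to 0, above the ``upper``
    percentile to 1, linearly in between; this normalises signal
    variability between images and increases contrast before gradient
    analysis.  A constant image is returned unchanged with a warning.
    """
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    lo, hi = np.percentile(img, [lower, upper])
    if hi <= lo:
        warnings.warn("constant (or degenerate) image: clip is a no-op",
                      stacklevel=2)
        return img.copy()
    return np.clip((img - lo) / (hi - lo), 0.0, 1.0)


def sobel_gradients(image):
    """(gx, gy) from the two 5x5 Sobel operators (reflect boundary)."""
    img = np.asarray(image, dtype=float)
    gx = ndi.convolve(img, SOBEL5_X, mode="reflect")
    gy = ndi.convolve(img, SOBEL5_Y, mode="reflect")
    return gx, gy


@dataclass(frozen=True)
class OrientationDistribution:
    cell: int
    bin_edges_deg: np.ndarray       # partition of [0, 180]
    weights: np.ndarray             # gradient-magnitude sums per bin
    total_weight: float
    excluded: bool = False
    reason: str = ""

    @property
    def bin_centers_deg(self) -> np.ndarray:
        e = self.bin_edges_deg
        return (e[:-1] + e[1:]) / 2.0


def gradient_orientation_distribution(image_or_gradients, cell_coords_rc,
                                      bin_width_deg: float = 1.0,
                                      cell: int = 0
                                      ) -> OrientationDistribution:
    """Magnitude-weighted texture-orientation histogram of one cell.

    The cell mask is eroded by one pixel so membrane-edge gradients do not
    contribute.  ``image_or_gradients`` is either the (clipped) tubulin
    image or a precomputed ``(gx, gy)`` pair from :func:`sobel_gradients`
    (pass the image ``shape`` explicitly only with bare coordinate input on
    a gradient pair).  Cells smaller than 25 px after erosion are excluded.
    """
    if 180.0 % bin_width_deg:
        raise ValueError("bin width must divide 180")
    if isinstance(image_or_gradients, tuple):
        gx, gy = image_or_gradients
    else:
        gx, gy = sobel_gradients(image_or_gradients)
    coords = np.asarray(cell_coords_rc, dtype=int)
    h, w = gx.shape

    mask = np.zeros((h, w), dtype=bool)
    mask[coords[:, 0], coords[:, 1]] = True
    mask = ndi.binary_erosion(mask, structure=np.ones((3, 3)))
    nbins = int(round(180.0 / bin_width_deg))
    edges = np.linspace(0.0, 180.0, nbins + 1)
    if mask.sum() < MIN_CELL_PIXELS:
        return OrientationDistribution(cell, edges, np.zeros(nbins), 0.0,
                                       True, "cell too small after erosion")
    gxm = gx[mask]
    gym = gy[mask]
    magnitude = np.hypot(gxm, gym)
    # gradient direction in math convention; texture axis is normal to it
    orient = wrap_axial(np.degrees(np.arctan2(-gym, gxm)) + 90.0)
    weights, _ = np.histogram(orient, bins=edges, weights=magnitude)
    total = float(weights.sum())
    if total <= 0:
        return OrientationDistribution(cell, edges, weights, 0.0, True,
                                       "no gradient signal")
    return OrientationDistribution(cell, edges, weights, total)


@dataclass(frozen=True)
class OrientationFit:
    cell: int
    mu_deg: float           # main MT direction, axial, [0, 180)
    kappa: float            # fitted Von Mises concentration (doubled angles)
    mtsd_deg: float         # circular SD of the fitted curve
    mtsd_moment_deg: float  # circular SD from the raw weighted resultant
    rbar: float             # raw weighted mean resultant length
    amplitude: float        # weight fraction carried by the VM component
    r_squared: float        # structure explained by the fit (vs uniform)
    valid: bool
    reason: str = ""


def _kappa_from_rbar(rbar: float) -> float:
    """Invert the Bessel ratio A(kappa) = I1/I0 = rbar (ML estimate)."""
    if rbar >= 1.0 - 1e-12:
        return float("inf")
    f = lambda k: i1e(k) / i0e(k) - rbar
    hi = 2.0
    while f(hi) < 0 and hi < 1e8:
        hi *= 2.0
    return float(brentq(f, 1e-12, hi, xtol=1e-10))


def mtsd_from_kappa(kappa: float) -> float:
    """Analytic MTSD (deg) of an axial Von Mises with concentration kappa:
    circular SD of the doubled-angle distribution, halved."""
    if kappa <= 0:
        return float("inf")
    rbar = i1e(kappa) / i0e(kappa)
    if rbar <= 0:
        return float("inf")
    return math.degrees(math.sqrt(-2.0 * math.log(rbar))) / 2.0


# minimum share of histogram structure the Von Mises component must explain
# for a fit to count; below this the distribution is deemed unfittable
R2_THRESHOLD = 0.5
_KAPPA_BOUNDS = (1e-3, 1e4)


def _mixture_model(centers_deg, width_deg, mu_deg, kappa, lam):
    """Per-bin probability of a uniform + axial Von Mises mixture.

    The Von Mises lives on doubled angles (mean 2 mu, concentration kappa);
    bin probabilities use 3-point averaging so narrow peaks are resolved.
    """
    nb = centers_deg.size
    offsets = np.array([-width_deg / 3.0, 0.0, width_deg / 3.0])
    th = centers_deg[:, None] + offsets[None, :]
    dens = np.exp(kappa * (np.cos(np.radians(2.0 * (th - mu_deg))) - 1.0))
    dens = dens.mean(axis=1) / (2.0 * math.pi * i0e(kappa))
    vm_bin = dens * 2.0 * math.radians(width_deg)
    return lam / nb + (1.0 - lam) * vm_bin


def fit_von_mises(dist: OrientationDistribution,
                  r2_threshold: float = R2_THRESHOLD) -> OrientationFit:
    """Fit a Von Mises curve to one cell's orientation distribution.

    The normalised histogram is fitted (weighted least squares) with a
    mixture of a uniform floor and an axial Von Mises on doubled angles;
    the uniform component absorbs unoriented signal (filament ends,
    crossings, noise) so the Von Mises parameters describe the oriented
    texture itself.  The fitted mean (halved) is the main microtubule
    direction and the MTSD is the circular standard deviation of the
    fitted curve, ``(180/pi) sqrt(-2 ln A(kappa)) / 2`` with A the Bessel
    ratio I1/I0.

    A cell is excluded (``valid=False``) when the distribution is
    unfittable — the optimiser fails, the raw resultant vanishes, or the
    fitted curve explains less than ``r2_threshold`` of the histogram's
    squared deviation from uniformity — or when MTSD >= 90 deg.  The
    moment-based circular SD of the raw distribution is also reported
    (``mtsd_moment_deg``); it is defined for every non-empty distribution
    but mixes oriented and unoriented signal.
    """
    nanfit = lambda reason, rbar=0.0, mt_m=float("nan"): OrientationFit(
        dist.cell, float("nan"), float("nan"), float("nan"), mt_m, rbar,
        0.0, 0.0, False, reason)
    if dist.excluded or dist.total_weight <= 0:
        return nanfit(dist.reason or "empty distribution")
    centers = dist.bin_centers_deg
    width = float(dist.bin_edges_deg[1] - dist.bin_edges_deg[0])
    w = dist.weights / dist.total_weight
    th2 = np.radians(2.0 * centers)
    c = float(np.sum(w * np.cos(th2)))
    s = float(np.sum(w * np.sin(th2)))
    rbar = math.hypot(c, s)
    mtsd_moment = math.degrees(math.sqrt(-2.0 * math.log(rbar))) / 2.0 \
        if rbar >= _RBAR_TOL else float("inf")
    if rbar < _RBAR_TOL:
        return nanfit("unfittable: no preferred axis", rbar, mtsd_moment)

    mu0 = (math.degrees(math.atan2(s, c)) / 2.0) % 180.0
    k0 = _kappa_from_rbar(min(rbar * 1.3, 0.95))
    lo, hi = _KAPPA_BOUNDS
    x0 = [mu0, math.log(max(min(k0, hi), lo)), 0.3]

    def residual(p):
        return _mixture_model(centers, width, p[0], math.exp(p[1]),
                              p[2]) - w

    try:
        res = least_squares(residual, x0=x0,
                            bounds=([mu0 - 90.0, math.log(lo), 0.0],
                                    [mu0 + 90.0, math.log(hi), 1.0]))
    except Exception:   # noqa: BLE001 - optimiser failure = unfittable
        return nanfit("unfittable: fit failed", rbar, mtsd_moment)
    if not res.success:
        return nanfit("unfittable: fit did not converge", rbar, mtsd_moment)
    mu, kappa, lam = res.x[0] % 180.0, math.exp(res.x[1]), res.x[2]
    fitted = _mixture_model(centers, width, mu, kappa, lam)
    ss_res = float(np.sum((w - fitted) ** 2))
    ss_tot = float(np.sum((w - 1.0 / w.size) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    mtsd = mtsd_from_kappa(kappa)
    amplitude = 1.0 - lam
    if r2 < r2_threshold:
        return OrientationFit(dist.cell, float(mu), float(kappa),
                              float(mtsd), mtsd_moment, rbar,
                              float(amplitude), float(r2), False,
                              "unfittable: poor fit")
    if not mtsd < 90.0:
        return OrientationFit(dist.cell, float(mu), float(kappa),
                              float(mtsd), mtsd_moment, rbar,
                              float(amplitude), float(r2), False,
                              "MTSD >= 90")
    return OrientationFit(dist.cell, float(mu), float(kappa), float(mtsd),
                          mtsd_moment, rbar, float(amplitude), float(r2),
                          True)


def aligned_average_profile(distributions, geometries,
                            ecc_bins=DEFAULT_ECC_BINS):
    """Average orientation profiles aligned to their maxima, by
    eccentricity bin.

    Each cell's binned distribution is circularly shifted so its modal bin
    sits at 0 deg, normalised to unit sum, and averaged over the cells
    whose eccentricity falls in each requested bin (centre +- half-width).
    Returns ``{centre: (offsets_deg, profile, n_cells)}``; empty bins are
    omitted with a warning.
    """
    geo_by_cell = {g.label: g for g in geometries}
    out = {}
    for centre, half in ecc_bins:
        profiles = []
        offsets = None
        for d in distributions:
            if d.excluded or d.total_weight <= 0:
                continue
            g = geo_by_cell.get(d.cell)
            if g is None or abs(g.eccentricity - centre) > half:
                continue
            k = int(np.argmax(d.weights))
            prof = np.roll(d.weights, -k) / d.total_weight
            profiles.append(prof)
            if offsets is None:
                offsets = d.bin_centers_deg - d.bin_centers_deg[0]
        if not profiles:
            warnings.warn(f"no cells in eccentricity bin {centre} +- {half}",
                          stacklevel=2)
            continue
        out[centre] = (offsets, np.mean(profiles, axis=0), len(profiles))
    return out
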