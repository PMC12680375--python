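"""Seeded synthetic epithelium generator with ground truth.

Produces label masks, junctional fluorescence channels (a two-channel
sfGFP/mKate2 fluorescent timer) and per-cell filament textures that emulate
the measured features of a pupal-wing epithelium: polygonal cells of
controllable eccentricity, membrane intensities set by a per-cell nematic
polarity axis, a stable protein fraction read out as a channel ratio, and
Von Mises-distributed microtubule-like filaments.  Every stage of the
analysis pipeline can therefore be tested by parameter recovery against the
returned ground-truth tables.

Tissue model
------------
Cells are the nearest-seed (Voronoi) regions of a jittered hexagonal (or
square) lattice.  Anisotropy is an affine stretch of the whole tessellation
along x: distances are computed in a virtual isotropic frame, so a stretch
factor ``s = a/b`` yields cells of eccentricity ``sqrt(1 - 1/s^2)`` oriented
at 0 deg, exactly.

Junction intensity model
------------------------
A junction at orientation ``alpha`` between cells whose (axial) polarity
axes average to ``psi`` receives the noiseless intensity

    I = B + A * sin^2(alpha - psi)

so junctions perpendicular to the polarity axis are brightest: for a
proximo-distal axis this puts the signal on medio-lateral membranes, the
pattern the pipeline must detect.  The sin^2 profile is a modelling choice
(the measured profile of a polarised cell is not itself specified by the
quantities the pipeline reports); its two parameters B (baseline) and A
(asymmetry amplitude) are the natural dials for polarity strength.

The timer is a single stable-fraction scalar ``f`` per dataset: the mKate2
channel is ``f`` times the sfGFP channel before background and noise, which
is sufficient to exercise the ratio estimator without a maturation ODE.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from skimage.draw import line_aa

from . import geometry as geo
from .circstats import axial_difference, axial_mean, wrap_axial

__all__ = [
    "TissueSpec",
    "PolarityField",
    "FilamentSpec",
    "SyntheticTissue",
    "ChannelRender",
    "generate_tissue",
    "render_channels",
    "render_filaments",
]

_SQRT3_2 = math.sqrt(3.0) / 2.0
_MIN_SPACING_PX = 6.0


@dataclass(frozen=True)
class TissueSpec:
    """Geometry of a synthetic tissue.

    ``anisotropy`` is the target long/short axis ratio a/b (>= 1), applied
    as a global x-stretch; ``jitter`` displaces each lattice seed uniformly
    by up to that fraction of the lattice spacing in each direction.  When
    ``image_shape`` is None the image is sized so hexagonal cells are
    regular before stretching.
    """

    n_cols: int = 15
    n_rows: int = 14
    cell_spacing: float = 28.0          # px, seed spacing along x (virtual)
    image_shape: tuple | None = None    # (H, W); None -> derived from grid
    anisotropy: float = 1.0             # a/b >= 1
    jitter: float = 0.12                # fraction of spacing
    seed: int = 0
    lattice: str = "hex"                # "hex" | "square"

    def __post_init__(self):
        if self.n_cols < 2 or self.n_rows < 2:
            raise ValueError("grid must be at least 2 x 2")
        if self.anisotropy < 1.0:
            raise ValueError("anisotropy must be >= 1 (stretch along x)")
        if self.jitter < 0 or self.jitter > 0.45:
            raise ValueError("jitter must be in [0, 0.45]")
        if self.lattice not in ("hex", "square"):
            raise ValueError("lattice must be 'hex' or 'square'")

    @property
    def true_eccentricity(self) -> float:
        return math.sqrt(1.0 - 1.0 / self.anisotropy**2)


@dataclass(frozen=True)
class SyntheticTissue:
    labels: np.ndarray        # integer label image, 0 = membrane skeleton
    cells: pd.DataFrame       # per-cell ground-truth geometry
    spec: TissueSpec


def generate_tissue(spec: TissueSpec) -> SyntheticTissue:
    """Rasterise a jittered, optionally stretched polygonal tissue.

    Returns the label image (contiguous labels >= 1, one-pixel membrane
    skeleton at 0 between adjacent cells) and a ground-truth table with the
    seed position, true orientation (0 deg, NaN when isotropic), true
    eccentricity and an ``on_border`` flag per cell.  Identical spec and
    seed give bit-identical output.
    """
    s = spec.anisotropy
    if spec.image_shape is None:
        if spec.lattice == "hex":
            dx, dy = spec.cell_spacing, spec.cell_spacing * _SQRT3_2
        else:
            dx = dy = spec.cell_spacing
        height = int(round(spec.n_rows * dy))
        width = int(round(spec.n_cols * dx * s))
    else:
        height, width = spec.image_shape
        if height < 1 or width < 1:
            raise ValueError("image size must be positive")
        dy = height / spec.n_rows
        dx = (width / s) / spec.n_cols
    if min(dx * s, dy) < _MIN_SPACING_PX:
        raise ValueError(
            f"image too small for requested grid: cell spacing would be "
            f"{min(dx * s, dy):.1f} px (need >= {_MIN_SPACING_PX:.0f})")

    rng = np.random.default_rng(spec.seed)
    ii, jj = np.meshgrid(np.arange(spec.n_rows), np.arange(spec.n_cols),
                         indexing="ij")
    yv = (ii + 0.5) * dy
    xv = (jj + 0.5) * dx
    if spec.lattice == "hex":
        xv = xv + (ii % 2) * 0.5 * dx
    seeds = np.column_stack([xv.ravel(), yv.ravel()]).astype(float)
    seeds += rng.uniform(-spec.jitter, spec.jitter, seeds.shape) * \
        min(dx, dy)
    # wrap seeds into the virtual domain so every cell exists
    wv = width / s
    seeds[:, 0] = np.clip(seeds[:, 0], 0.0, wv - 1e-9)
    seeds[:, 1] = np.clip(seeds[:, 1], 0.0, height - 1e-9)

    tree = cKDTree(seeds)
    rr, cc = np.meshgrid(np.arange(height), np.arange(width), indexing="ij")
    pts = np.column_stack([((cc.ravel() + 0.5) / s), rr.ravel() + 0.5])
    _, idx = tree.query(pts, workers=1)
    labels = (idx + 1).reshape(height, width).astype(np.int32)

    # one-pixel membrane skeleton: zero pixels whose right or down
    # neighbour belongs to a different cell
    membrane = np.zeros_like(labels, dtype=bool)
    membrane[:, :-1] |= labels[:, :-1] != labels[:, 1:]
    membrane[:-1, :] |= labels[:-1, :] != labels[1:, :]
    labels[membrane] = 0

    # relabel contiguously in case a seed produced no surviving pixels
    present = np.unique(labels)
    present = present[present > 0]
    remap = np.zeros(int(present.max()) + 1, dtype=np.int32)
    remap[present] = np.arange(1, present.size + 1)
    old_of_new = {int(remap[p]): int(p) for p in present}
    labels = remap[labels]

    border = set(np.unique(np.concatenate([
        labels[0], labels[-1], labels[:, 0], labels[:, -1]])))
    ecc = spec.true_eccentricity
    rows = []
    for new in range(1, present.size + 1):
        old = old_of_new[new] - 1
        rows.append({
            "cell": new,
            "seed_row": seeds[old, 1],
            "seed_col": seeds[old, 0] * s,
            "orientation_deg": 0.0 if s > 1.0 else float("nan"),
            "eccentricity": ecc,
            "on_border": new in border,
        })
    cells = pd.DataFrame(rows)
    return SyntheticTissue(labels, cells, spec)


@dataclass(frozen=True)
class PolarityField:
    """Parameters of the junctional polarity pattern.

    ``mode`` is one of ``uniform`` (every cell has axis ``psi0_deg``),
    ``swirl`` (axes tangent to circles about ``vortex_rc``) or
    ``boundary`` (repolarisation from an overexpression boundary: cells in
    row r <= ``propagation_rows`` have their axis rotated toward the
    boundary-parallel direction by the fraction 1 - r/(L+1), deeper rows
    keep ``psi0_deg``).  ``stable_fraction`` scales the mKate2 channel
    relative to sfGFP; ``noise_sigma`` is the per-pixel Gaussian sigma in
    the same intensity units as ``baseline``.
    """

    mode: str = "uniform"
    psi0_deg: float = 0.0
    amplitude: float = 1.0            # A, asymmetry amplitude
    baseline: float = 1.0             # B, junction baseline intensity
    stable_fraction: float = 1.0      # f in [0, 1]
    propagation_rows: int = 1         # L, boundary mode only
    background: float = 0.0
    noise_sigma: float = 0.0
    vortex_rc: tuple | None = None    # swirl centre, default image centre
    boundary_axis_deg: float | None = None  # default: from boundary-0 junctions

    def __post_init__(self):
        if self.mode not in ("uniform", "swirl", "boundary"):
            raise ValueError("mode must be uniform, swirl or boundary")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.baseline <= 0:
            raise ValueError("baseline must be > 0")
        if not 0.0 <= self.stable_fraction <= 1.0:
            raise ValueError("stable_fraction must be in [0, 1]")
        if self.propagation_rows < 0:
            raise ValueError("propagation_rows must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass(frozen=True)
class ChannelRender:
    channels: dict            # name -> float image ("sfGFP", "mKate2")
    junction_truth: pd.DataFrame
    cell_truth: pd.DataFrame
    graph: "geo.TissueGraph"
    row_assignment: dict | None = None


def _cell_axes(graph: geo.TissueGraph, fld: PolarityField,
               source_cells=None):
    """Ground-truth polarity axis per cell; NaN marks unpolarised source
    cells.  Returns (axes dict, row assignment dict or None, boundary axis)."""
    axes: dict = {}
    assignment = None
    boundary_axis = None
    if fld.mode == "uniform":
        for lab in graph.cells:
            axes[lab] = float(wrap_axial(fld.psi0_deg))
    elif fld.mode == "swirl":
        h, w = graph.labels.shape
        r0, c0 = fld.vortex_rc if fld.vortex_rc is not None else \
            ((h - 1) / 2.0, (w - 1) / 2.0)
        for lab in graph.cells:
            r, c = graph.cell_geometry(lab).centroid_rc
            pos = math.degrees(math.atan2(-(r - r0), c - c0))
            axes[lab] = float(wrap_axial(pos + 90.0))
    else:  # boundary repolarisation
        if not source_cells:
            raise ValueError(
                "boundary mode requires a non-empty source cell set")
        from .rows import assign_rows, SOURCE_ROW
        assignment = assign_rows(graph, source_cells, max_row=None)
        if fld.boundary_axis_deg is not None:
            boundary_axis = float(wrap_axial(fld.boundary_axis_deg))
        else:
            angs, wts = [], []
            for (a, b), j in graph.junctions.items():
                ra, rb = assignment.get(a), assignment.get(b)
                if {ra, rb} == {SOURCE_ROW, 0} and \
                        not math.isnan(j.orientation_deg):
                    angs.append(j.orientation_deg)
                    wts.append(j.n_pixels)
            if not angs:
                raise ValueError("no boundary-0 junctions found")
            boundary_axis, _ = axial_mean(angs, wts)
        delta = float(axial_difference(boundary_axis, fld.psi0_deg))
        lmax = fld.propagation_rows
        for lab in graph.cells:
            r = assignment.get(lab)
            if r == SOURCE_ROW:
                axes[lab] = float("nan")
            elif r is not None and r <= lmax:
                w = 1.0 - r / (lmax + 1.0)
                axes[lab] = float(wrap_axial(fld.psi0_deg + w * delta))
            else:
                axes[lab] = float(wrap_axial(fld.psi0_deg))
    return axes, assignment, boundary_axis


def render_channels(labels_or_tissue, fld: PolarityField, *,
                    graph: geo.TissueGraph | None = None,
                    source_cells=None, band_width: int = 3,
                    seed: int = 0) -> ChannelRender:
    """Render sfGFP and mKate2 channels from a polarity field.

    Paints ``I = B + A sin^2(alpha - psi)`` on each junction's membrane
    band (mean where bands overlap near vertices), adds the constant
    autofluorescent background and i.i.d. Gaussian noise per channel, and
    scales mKate2 by the stable fraction.  Returns the channel images along
    with noiseless per-junction and per-cell ground-truth tables.
    """
    if isinstance(labels_or_tissue, SyntheticTissue):
        labels = labels_or_tissue.labels
    else:
        labels = np.asarray(labels_or_tissue)
    if graph is None:
        graph = geo.parse_tissue(labels, band_width=band_width)
    axes, assignment, boundary_axis = _cell_axes(graph, fld, source_cells)
    source = set(source_cells) if source_cells else set()

    shape = labels.shape
    acc = np.zeros(shape, dtype=float)
    cnt = np.zeros(shape, dtype=np.int32)
    jrows = []
    for (a, b), j in sorted(graph.junctions.items()):
        alpha = j.orientation_deg
        flank = [axes[c] for c in (a, b) if not math.isnan(axes[c])]
        if not flank:                       # both cells unpolarised source
            inten = fld.baseline + fld.amplitude
            psi_bar = float("nan")
        else:
            psi_bar, rbar = axial_mean(flank)
            if math.isnan(psi_bar) or rbar < 1e-9:
                inten = fld.baseline + fld.amplitude / 2.0
            elif math.isnan(alpha):
                inten = fld.baseline + fld.amplitude / 2.0
            else:
                inten = fld.baseline + fld.amplitude * \
                    math.sin(math.radians(alpha - psi_bar)) ** 2
        band = j.band_rc
        acc[band[:, 0], band[:, 1]] += inten
        cnt[band[:, 0], band[:, 1]] += 1
        jrows.append({"cell_a": a, "cell_b": b, "alpha_deg": alpha,
                      "psi_bar_deg": psi_bar, "intensity": inten,
                      "n_band_pixels": j.band_rc.shape[0]})

    fieldimg = np.where(cnt > 0, acc / np.maximum(cnt, 1), 0.0)
    rng = np.random.default_rng(seed)
    channels = {}
    for name, scale in (("sfGFP", 1.0), ("mKate2", fld.stable_fraction)):
        img = scale * fieldimg + fld.background
        if fld.noise_sigma > 0:
            img = img + rng.normal(0.0, fld.noise_sigma, shape)
        channels[name] = img

    crows = []
    for lab in graph.cells:
        row = assignment.get(lab) if assignment is not None else None
        crows.append({"cell": lab, "psi_true_deg": axes[lab],
                      "row": row if row is not None else float("nan"),
                      "is_source": lab in source})
    cell_truth = pd.DataFrame(crows)
    if boundary_axis is not None:
        cell_truth.attrs["boundary_axis_deg"] = boundary_axis
    return ChannelRender(channels, pd.DataFrame(jrows), cell_truth, graph,
                         assignment)


@dataclass(frozen=True)
class FilamentSpec:
    """Per-cell filament texture parameters.

    ``mu_deg`` may be a scalar (same true orientation for every cell) or a
    mapping label -> orientation.  Orientations are axial; segments are
    drawn with angles sampled from a Von Mises on doubled angles with mean
    ``2 mu`` and concentration ``kappa`` (kappa = 0 gives uniform axes).
    """

    mu_deg: float | dict = 30.0
    kappa: float = 4.0
    n_filaments: int = 120
    length: float = 30.0              # px
    amplitude: float = 100.0          # peak added intensity per segment

    def __post_init__(self):
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.n_filaments < 1 or self.length <= 0:
            raise ValueError("need n_filaments >= 1 and positive length")


def render_filaments(labels_or_tissue, fspec: FilamentSpec,
                     seed: int = 0) -> tuple:
    """Render a tubulin-like channel of oriented filaments per cell.

    Each cell receives ``n_filaments`` anti-aliased line segments centred
    at random pixels of the cell, clipped to the cell's own mask so
    orientations do not bleed across membranes.  Returns ``(image,
    angles)`` where ``angles`` is a table of every drawn segment's cell and
    true axial angle — the sampling ground truth for orientation recovery.
    """
    if isinstance(labels_or_tissue, SyntheticTissue):
        labels = labels_or_tissue.labels
    else:
        labels = np.asarray(labels_or_tissue)
    rng = np.random.default_rng(seed)
    h, w = labels.shape
    img = np.zeros((h, w), dtype=float)
    recs = []
    cells = [int(v) for v in np.unique(labels) if v > 0]
    half = fspec.length / 2.0
    for lab in cells:
        mask = labels == lab
        coords = np.column_stack(np.nonzero(mask))
        if isinstance(fspec.mu_deg, dict):
            mu = float(fspec.mu_deg[lab])
        else:
            mu = float(fspec.mu_deg)
        mu2 = math.radians(2.0 * mu)
        for _ in range(fspec.n_filaments):
            centre = coords[rng.integers(coords.shape[0])]
            if fspec.kappa == 0:
                theta = rng.uniform(0.0, 180.0)
            else:
                theta = math.degrees(rng.vonmises(mu2, fspec.kappa)) / 2.0
            theta = float(theta % 180.0)
            t = math.radians(theta)
            dr, dc = -math.sin(t) * half, math.cos(t) * half
            r0 = int(round(centre[0] - dr))
            c0 = int(round(centre[1] - dc))
            r1 = int(round(centre[0] + dr))
            c1 = int(round(centre[1] + dc))
            rr, cc, val = line_aa(r0, c0, r1, c1)
            ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
            rr, cc, val = rr[ok], cc[ok], val[ok]
            ok = mask[rr, cc]
            img[rr[ok], cc[ok]] += fspec.amplitude * val[ok]
            recs.append({"cell": lab, "angle_deg": theta})
    return img, pd.DataFrame(recs)
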