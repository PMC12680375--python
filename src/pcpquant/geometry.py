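"""Parsing label masks into a tissue graph and per-cell ellipse geometry.

Input is an integer label image as produced by membrane-segmentation tools
(one positive label per cell, 0 on the membrane skeleton and background).
The parser extracts cell regions, cell-cell adjacency, junction segments
(membrane skeleton pixels shared by exactly two cells), vertex pixels
(shared by three or more), and a membrane band of configurable width around
each junction over which fluorescence is measured.

Coordinate and angle conventions
--------------------------------
Pixel coordinates are (row, col) with the origin at the top-left; all
*reported* angles use the mathematical convention, counter-clockwise from
the image horizontal (so the proximo-distal reference axis of an oriented
wing image is 0 deg).  Angles of axes are axial, period 180 deg.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .circstats import wrap_axial_signed

__all__ = [
    "CellGeometry",
    "Junction",
    "TissueGraph",
    "parse_tissue",
    "fit_cell_ellipse",
    "junction_orientation",
]

# eccentricity below which the long-axis direction is not meaningful
_ORIENTATION_ECC_TOL = 0.05


@dataclass(frozen=True)
class CellGeometry:
    """Second-moment (best-fit) ellipse of a cell's pixel region."""

    label: int
    centroid_rc: tuple          # (row, col), pixel-centre coordinates
    orientation_deg: float      # long-axis angle, (-90, 90], math convention
    semi_major: float           # a, pixels
    semi_minor: float           # b <= a, pixels
    eccentricity: float         # sqrt(1 - (b/a)^2)
    orientation_defined: bool   # False when a ~ b (or degenerate region)
    n_pixels: int


def fit_cell_ellipse(coords_rc, label: int = 0) -> CellGeometry:
    """Fit the inertia-equivalent ellipse to a pixel region.

    ``coords_rc`` is an (n, 2) array of (row, col) pixel coordinates.  The
    ellipse has the same second moments as the region (semi-axes
    ``a = 2 sqrt(lambda1)``, ``b = 2 sqrt(lambda2)`` from the coordinate
    covariance, which is exact for a filled ellipse).  The orientation is
    reported counter-clockwise from the image horizontal in (-90, 90] and is
    flagged undefined for near-isotropic or degenerate (collinear) regions.
    """
    coords = np.asarray(coords_rc, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2 or coords.shape[0] < 5:
        raise ValueError("need at least 5 (row, col) pixel coordinates")
    x = coords[:, 1]
    y = -coords[:, 0]  # math convention: y grows upward
    cx, cy = x.mean(), y.mean()
    dx, dy = x - cx, y - cy
    cxx = float(np.mean(dx * dx))
    cyy = float(np.mean(dy * dy))
    cxy = float(np.mean(dx * dy))
    tr = cxx + cyy
    det = cxx * cyy - cxy * cxy
    disc = max(tr * tr / 4.0 - det, 0.0)
    lam1 = tr / 2.0 + math.sqrt(disc)
    lam2 = tr / 2.0 - math.sqrt(disc)
    a = 2.0 * math.sqrt(max(lam1, 0.0))
    b = 2.0 * math.sqrt(max(lam2, 0.0))
    centroid_rc = (float(-cy), float(cx))
    if lam1 <= 0:
        return CellGeometry(label, centroid_rc, float("nan"), 0.0, 0.0, 0.0,
                            False, coords.shape[0])
    ecc = math.sqrt(max(1.0 - lam2 / lam1, 0.0))
    degenerate = lam2 <= 0
    if ecc < _ORIENTATION_ECC_TOL:
        phi, defined = float("nan"), False
    else:
        phi = math.degrees(0.5 * math.atan2(2.0 * cxy, cxx - cyy))
        phi = float(wrap_axial_signed(phi))
        defined = not degenerate
    if degenerate:
        defined = False
    return CellGeometry(label, centroid_rc, phi, a, b, min(ecc, 1.0 - 1e-12),
                        defined, coords.shape[0])


@dataclass
class Junction:
    """Membrane skeleton segment shared by exactly two cells."""

    cells: tuple                 # (label_a, label_b), a < b
    pixels_rc: np.ndarray        # (n, 2) skeleton pixel coordinates
    endpoints_rc: np.ndarray     # (2, 2) endpoint pixel coordinates
    band_rc: np.ndarray = None   # (m, 2) membrane-band pixel coordinates
    orientation_deg: float = float("nan")   # [0, 180)
    low_confidence: bool = False

    @property
    def n_pixels(self) -> int:
        return int(self.pixels_rc.shape[0])

    @property
    def length(self) -> float:
        e = self.endpoints_rc
        return float(np.hypot(*(e[1].astype(float) - e[0])))


@dataclass
class TissueGraph:
    """Cells, adjacency, junctions and membrane bands parsed from a mask."""

    labels: np.ndarray                       # the input label image
    cells: list                              # sorted positive labels
    regions: dict                            # label -> (n, 2) pixel coords
    adjacency: set                           # {(a, b), a < b}
    junctions: dict                          # (a, b) -> Junction
    vertices_rc: np.ndarray                  # (k, 2) vertex pixel coords
    geometry: dict = field(default_factory=dict)   # label -> CellGeometry

    def neighbors(self, label: int) -> list:
        out = []
        for a, b in self.adjacency:
            if a == label:
                out.append(b)
            elif b == label:
                out.append(a)
        return sorted(out)

    def cell_junctions(self, label: int) -> list:
        return [j for pair, j in self.junctions.items() if label in pair]

    def cell_membrane_band(self, label: int) -> np.ndarray:
        """Union of the membrane bands of all junctions of one cell."""
        parts = [j.band_rc for j in self.cell_junctions(label)
                 if j.band_rc is not None and j.band_rc.size]
        if not parts:
            return np.empty((0, 2), dtype=int)
        return np.unique(np.concatenate(parts, axis=0), axis=0)

    def cell_geometry(self, label: int) -> CellGeometry:
        if label not in self.geometry:
            self.geometry[label] = fit_cell_ellipse(self.regions[label], label)
        return self.geometry[label]

    def fit_all_geometry(self) -> dict:
        for lab in self.cells:
            self.cell_geometry(lab)
        return self.geometry


_EIGHT_SHIFTS = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
                 (0, 1), (1, -1), (1, 0), (1, 1)]


def _neighbor_label_stack(labels: np.ndarray) -> np.ndarray:
    """(8, H, W) array of 8-neighbour labels, 0-padded at the border."""
    h, w = labels.shape
    out = np.zeros((8, h, w), dtype=labels.dtype)
    for k, (dr, dc) in enumerate(_EIGHT_SHIFTS):
        src = labels[max(dr, 0) or None: h + min(dr, 0) or None,
                     max(dc, 0) or None: w + min(dc, 0) or None]
        out[k,
            max(-dr, 0): h - max(dr, 0),
            max(-dc, 0): w - max(dc, 0)] = src
    return out


def _trace_endpoints(pixels_rc: np.ndarray) -> np.ndarray:
    """Endpoints of a skeleton segment: pixels with <= 1 neighbour in the
    segment (8-connectivity); falls back to the most distant pixel pair for
    loops or blobs."""
    pts = pixels_rc
    n = pts.shape[0]
    if n == 1:
        return np.vstack([pts[0], pts[0]])
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
    neigh = (d2 > 0) & (d2 <= 2)          # 8-connected neighbours
    deg = neigh.sum(axis=1)
    ends = np.flatnonzero(deg <= 1)
    if ends.size >= 2:
        # most-separated pair among the degree-<=1 pixels
        sub = d2[np.ix_(ends, ends)]
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        return np.vstack([pts[ends[i]], pts[ends[j]]])
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    return np.vstack([pts[i], pts[j]])


def junction_orientation(junction: Junction,
                         flank_centroids=None) -> tuple:
    """Axial orientation of a junction in [0, 180), math convention.

    Uses the chord between the two endpoint pixels, so a curved junction is
    summarised by its end-to-end axis.  When the endpoints coincide (single
    pixel), the orientation falls back to the normal of the line joining the
    flanking cell centroids and is flagged low-confidence; with no centroids
    available the result is NaN.
    """
    e = junction.endpoints_rc.astype(float)
    dr, dc = e[1] - e[0]
    if dr == 0.0 and dc == 0.0:
        if flank_centroids is not None:
            (r1, c1), (r2, c2) = flank_centroids
            if (r1, c1) != (r2, c2):
                ang = math.degrees(math.atan2(-(r2 - r1), c2 - c1)) + 90.0
                return float(ang % 180.0), True
        return float("nan"), True
    return float(math.degrees(math.atan2(-dr, dc)) % 180.0), False


def parse_tissue(labels: np.ndarray, band_width: int = 3) -> TissueGraph:
    """Parse an integer label mask into a :class:`TissueGraph`.

    Membrane skeleton pixels (value 0) adjacent to exactly two distinct
    cell labels in their 8-neighbourhood form the junction of that cell
    pair; pixels adjacent to three or more labels are vertices and belong to
    no junction.  Each junction's membrane band is its skeleton dilated by
    ``band_width`` (a band_width x band_width square), clipped to the two
    flanking cells plus the skeleton itself.
    """
    labels = np.asarray(labels)
    if not np.issubdtype(labels.dtype, np.integer):
        raise TypeError("label image must have an integer dtype")
    if labels.ndim != 2:
        raise ValueError("label image must be 2-D")
    if band_width < 1:
        raise ValueError("band_width must be >= 1")
    if labels.min() < 0:
        raise ValueError("labels must be non-negative")

    cells = [int(v) for v in np.unique(labels) if v > 0]
    # pixel regions per cell
    regions: dict = {}
    if cells:
        objs = ndi.find_objects(labels, max_label=max(cells))
        for lab in cells:
            sl = objs[lab - 1]
            rr, cc = np.nonzero(labels[sl] == lab)
            regions[lab] = np.column_stack([rr + sl[0].start,
                                            cc + sl[1].start])

    neigh = _neighbor_label_stack(labels)
    bg = labels == 0
    # distinct positive neighbour labels per background pixel
    sorted_neigh = np.sort(np.where(neigh > 0, neigh, 0), axis=0)
    distinct = ((sorted_neigh[1:] != sorted_neigh[:-1])
                & (sorted_neigh[1:] > 0)).sum(axis=0)
    distinct += (sorted_neigh[0] > 0).astype(int)  # counts 0 if no labels

    junction_mask = bg & (distinct == 2)
    vertex_mask = bg & (distinct >= 3)
    vertices_rc = np.column_stack(np.nonzero(vertex_mask))

    jr, jc = np.nonzero(junction_mask)
    # the two flanking labels of each junction pixel = (min>0, max)
    col = sorted_neigh[:, jr, jc]
    hi = col[-1]
    lo = np.where(col > 0, col, np.iinfo(labels.dtype).max
                  if labels.dtype.kind in "iu" else 2**31).min(axis=0)
    pair_lo = np.minimum(lo, hi).astype(int)
    pair_hi = np.maximum(lo, hi).astype(int)

    junctions: dict = {}
    order = np.lexsort((pair_hi, pair_lo))
    jr, jc = jr[order], jc[order]
    pl, ph = pair_lo[order], pair_hi[order]
    if jr.size:
        breaks = np.flatnonzero((np.diff(pl) != 0) | (np.diff(ph) != 0)) + 1
        starts = np.concatenate([[0], breaks])
        stops = np.concatenate([breaks, [jr.size]])
        for s, t in zip(starts, stops):
            pair = (int(pl[s]), int(ph[s]))
            pix = np.column_stack([jr[s:t], jc[s:t]])
            junctions[pair] = Junction(pair, pix, _trace_endpoints(pix))

    adjacency = set(junctions)
    if len(cells) == 1:
        warnings.warn("single-cell image: adjacency is empty", stacklevel=2)

    # membrane bands and orientations
    pad = band_width // 2
    h, w = labels.shape
    for pair, j in junctions.items():
        rmin, cmin = j.pixels_rc.min(axis=0) - pad
        rmax, cmax = j.pixels_rc.max(axis=0) + pad + 1
        rmin, cmin = max(rmin, 0), max(cmin, 0)
        rmax, cmax = min(rmax, h), min(cmax, w)
        local = np.zeros((rmax - rmin, cmax - cmin), dtype=bool)
        local[j.pixels_rc[:, 0] - rmin, j.pixels_rc[:, 1] - cmin] = True
        dil = ndi.binary_dilation(local, structure=np.ones((band_width,
                                                            band_width)))
        sub = labels[rmin:rmax, cmin:cmax]
        keep = dil & (local | (sub == pair[0]) | (sub == pair[1]))
        br, bc = np.nonzero(keep)
        j.band_rc = np.column_stack([br + rmin, bc + cmin])

    graph = TissueGraph(labels, cells, regions, adjacency, junctions,
                        vertices_rc)
    for pair, j in junctions.items():
        cents = None
        try:
            ca = graph.cell_geometry(pair[0]).centroid_rc
            cb = graph.cell_geometry(pair[1]).centroid_rc
            cents = (ca, cb)
        except ValueError:
            pass
        j.orientation_deg, j.low_confidence = junction_orientation(j, cents)
    return graph
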