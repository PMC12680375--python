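"""Row assignment and junction-class intensity analysis at an
overexpression boundary.

Cells are layered by breadth-first search over the junction-adjacency
graph, starting from a user-supplied set of "source" cells (the
overexpression domain): row 0 is the first row of non-source cells sharing
a junction with the source, row k the cells sharing a junction with row
k-1 and no lower row.  Boundary k is the set of junctions between row k-1
and row k (boundary 0 between source and row 0).

Junctions are classified by their acute angle to the boundary axis:
"horizontal" (parallel to the boundary, 0-45 deg inclusive) versus
"medio-lateral" (45-90 deg); a tie at exactly 45 deg is horizontal.  Per
row, per class and per named boundary, the summary statistic is the mean
over junctions of each junction's background-subtracted mean membrane-band
intensity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from collections import deque

import numpy as np
import pandas as pd

from .circstats import axial_difference, axial_mean
from .geometry import TissueGraph

__all__ = [
    "SOURCE_ROW",
    "assign_rows",
    "boundary_junctions",
    "default_boundary_axis",
    "classify_junctions",
    "junction_intensity_table",
    "summarize_junction_intensity",
]

SOURCE_ROW = -1   # sentinel row index for source (overexpressing) cells

HORIZONTAL = "horizontal"
MEDIO_LATERAL = "medio-lateral"
UNCLASSIFIED = "unclassified"


def assign_rows(graph: TissueGraph, source_cells, max_row=3) -> dict:
    """Breadth-first row layering from the source set.

    Returns ``{cell: row}`` with source cells at ``SOURCE_ROW`` (-1);
    cells beyond ``max_row`` are omitted (unassigned).  ``max_row=None``
    assigns every reachable cell.  Row adjacency requires a shared
    junction, so diagonal (vertex-only) contact does not propagate.
    """
    source = {int(c) for c in source_cells}
    if not source:
        raise ValueError("source cell set is empty")
    unknown = source - set(graph.cells)
    if unknown:
        raise ValueError(f"source cells not in tissue: {sorted(unknown)}")
    if source == set(graph.cells):
        raise ValueError("source set covers every cell: no rows to assign")

    neigh: dict = {c: [] for c in graph.cells}
    for a, b in graph.adjacency:
        neigh[a].append(b)
        neigh[b].append(a)

    assignment = {c: SOURCE_ROW for c in source}
    frontier = deque(sorted(source))
    while frontier:
        c = frontier.popleft()
        r = assignment[c]
        if max_row is not None and r >= max_row:
            continue
        for nb in neigh[c]:
            if nb not in assignment:
                assignment[nb] = r + 1
                frontier.append(nb)
    return assignment


def boundary_junctions(graph: TissueGraph, assignment: dict, k: int):
    """Junction keys forming boundary ``k`` (between row k-1 and row k)."""
    inner = k - 1 if k > 0 else SOURCE_ROW
    out = []
    for (a, b) in graph.junctions:
        ra, rb = assignment.get(a), assignment.get(b)
        if ra is None or rb is None:
            continue
        if {ra, rb} == {inner, k}:
            out.append((a, b))
    return out


def default_boundary_axis(graph: TissueGraph, assignment: dict) -> float:
    """Length-weighted circular mean orientation of boundary-0 junctions;
    robust to gently curved boundaries."""
    angs, wts = [], []
    for a, b in boundary_junctions(graph, assignment, 0):
        j = graph.junctions[(a, b)]
        if not math.isnan(j.orientation_deg):
            angs.append(j.orientation_deg)
            wts.append(j.n_pixels)
    if not angs:
        raise ValueError("no boundary-0 junctions with defined orientation")
    mean, _ = axial_mean(angs, wts)
    if math.isnan(mean):
        raise ValueError("boundary-0 junction orientations cancel")
    return mean


def classify_junctions(graph: TissueGraph, assignment: dict,
                       boundary_axis_deg: float | None = None
                       ) -> pd.DataFrame:
    """Classify junctions among assigned cells relative to the boundary.

    Returns one record per junction whose two cells are both assigned
    (source counts as assigned): cell pair, acute angle to the boundary
    axis in [0, 90], class (horizontal iff angle <= 45 deg), and boundary
    index when the junction separates consecutive rows.  Junctions with
    undefined orientation are kept but marked unclassified.
    """
    if boundary_axis_deg is None:
        boundary_axis_deg = default_boundary_axis(graph, assignment)
    recs = []
    for (a, b), j in sorted(graph.junctions.items()):
        ra, rb = assignment.get(a), assignment.get(b)
        if ra is None or rb is None:
            continue
        if math.isnan(j.orientation_deg):
            angle, cls = float("nan"), UNCLASSIFIED
        else:
            angle = abs(float(axial_difference(j.orientation_deg,
                                               boundary_axis_deg)))
            cls = HORIZONTAL if angle <= 45.0 else MEDIO_LATERAL
        lo, hi = min(ra, rb), max(ra, rb)
        boundary = hi if hi - lo == 1 else None
        # junction row: the row it belongs to (row of both cells, or the
        # outer row for a between-rows junction)
        row = hi if hi >= 0 else None
        recs.append({"cell_a": a, "cell_b": b,
                     "row_a": ra, "row_b": rb, "row": row,
                     "angle_to_boundary_deg": angle, "junction_class": cls,
                     "boundary": boundary})
    df = pd.DataFrame(recs)
    df.attrs["boundary_axis_deg"] = float(boundary_axis_deg)
    return df


def junction_intensity_table(graph: TissueGraph, classes: pd.DataFrame,
                             channels: dict, background=None
                             ) -> pd.DataFrame:
    """Per-junction mean membrane-band intensity per channel.

    ``background`` maps channel name to the per-image constant to
    subtract (default 0).  Adds one ``mean_<channel>`` column per channel
    to a copy of the junction-class table.
    """
    background = background or {}
    df = classes.copy()
    for name, img in channels.items():
        img = np.asarray(img, dtype=float)
        bg = float(background.get(name, 0.0))
        vals = []
        for a, b in zip(df["cell_a"], df["cell_b"]):
            band = graph.junctions[(a, b)].band_rc
            vals.append(float(img[band[:, 0], band[:, 1]].mean()) - bg)
        df[f"mean_{name}"] = vals
    return df


def summarize_junction_intensity(graph: TissueGraph, classes: pd.DataFrame,
                                 channels: dict, background=None,
                                 max_row: int = 3) -> pd.DataFrame:
    """Mean of per-junction mean intensities, by row and junction class.

    One record per (channel, row 0..max_row, class) plus per named
    boundary; combinations with no junctions are absent from the table
    rather than reported as zero.
    """
    table = junction_intensity_table(graph, classes, channels, background)
    recs = []
    for name in channels:
        col = f"mean_{name}"
        for row in range(0, max_row + 1):
            sub = table[table["row"] == row]
            for cls in (HORIZONTAL, MEDIO_LATERAL):
                vals = sub.loc[sub["junction_class"] == cls, col]
                if len(vals):
                    recs.append({"channel": name, "row": row,
                                 "junction_class": cls,
                                 "boundary": None,
                                 "mean_intensity": float(vals.mean()),
                                 "n_junctions": int(len(vals))})
        for k in sorted(x for x in table["boundary"].dropna().unique()):
            vals = table.loc[table["boundary"] == k, col]
            recs.append({"channel": name, "row": None,
                         "junction_class": "boundary",
                         "boundary": int(k),
                         "mean_intensity": float(vals.mean()),
                         "n_junctions": int(len(vals))})
    return pd.DataFrame(recs)
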