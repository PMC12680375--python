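"""Row layering from an overexpression boundary and junction classes."""

import numpy as np
import pandas as pd
import pytest

from pcpquant import geometry as geo
from pcpquant import rows as rw
from pcpquant import synthetic as syn


def _square_grid(n=4, cell=8):
    """n x n square cells separated by one-pixel membranes."""
    size = n * cell + (n - 1)
    lab = np.zeros((size, size), dtype=np.int32)
    for i in range(n):
        for j in range(n):
            r0 = i * (cell + 1)
            c0 = j * (cell + 1)
            lab[r0:r0 + cell, c0:c0 + cell] = i * n + j + 1
    return lab


class TestAssignRows:
    def test_grid_layering_from_bottom_row(self):
        g = geo.parse_tissue(_square_grid(4))
        source = [13, 14, 15, 16]               # bottom row of the grid
        asg = rw.assign_rows(g, source, max_row=3)
        for c in source:
            assert asg[c] == rw.SOURCE_ROW
        for c in (9, 10, 11, 12):
            assert asg[c] == 0
        for c in (5, 6, 7, 8):
            assert asg[c] == 1
        for c in (1, 2, 3, 4):
            assert asg[c] == 2

    def test_max_row_truncates(self):
        g = geo.parse_tissue(_square_grid(4))
        asg = rw.assign_rows(g, [13, 14, 15, 16], max_row=1)
        assert 1 not in asg and 4 not in asg     # row-2 cells unassigned

    def test_diagonal_contact_does_not_propagate(self):
        """A cell touching the source only at a vertex is not row 0."""
        g = geo.parse_tissue(_square_grid(2))
        asg = rw.assign_rows(g, [3], max_row=3)  # bottom-left cell
        assert asg[1] == 0 and asg[4] == 0       # junction neighbours
        assert asg[2] == 1                       # diagonal: one row later

    def test_source_covering_all_cells_rejected(self):
        g = geo.parse_tissue(_square_grid(2))
        with pytest.raises(ValueError, match="every cell"):
            rw.assign_rows(g, [1, 2, 3, 4])

    def test_empty_or_unknown_source_rejected(self):
        g = geo.parse_tissue(_square_grid(2))
        with pytest.raises(ValueError):
            rw.assign_rows(g, [])
        with pytest.raises(ValueError, match="not in tissue"):
            rw.assign_rows(g, [99])

    def test_matches_networkx_bfs_oracle_on_jittered_mesh(self):
        """500-cell jittered tissue: layering equals an independent
        shortest-path computation on the junction-adjacency graph."""
        import networkx as nx
        tissue = syn.generate_tissue(syn.TissueSpec(n_cols=23, n_rows=22,
                                                    seed=19))
        g = geo.parse_tissue(tissue.labels)
        assert len(g.cells) >= 500
        width = tissue.labels.shape[1]
        source = tissue.cells.loc[tissue.cells["seed_col"]
                                  < width / 8, "cell"].tolist()
        asg = rw.assign_rows(g, source, max_row=None)
        G = nx.Graph(list(g.adjacency))
        G.add_nodes_from(g.cells)
        virtual = "SRC"
        G.add_edges_from((virtual, s) for s in source)
        dist = nx.single_source_shortest_path_length(G, virtual)
        for cell in g.cells:
            expected = dist.get(cell)
            if cell in set(source):
                assert asg[cell] == rw.SOURCE_ROW
            elif expected is None:
                assert cell not in asg
            else:
                # virtual -> source is one edge, so row k sits at
                # shortest-path distance k + 2 from the virtual node
                assert asg[cell] == expected - 2

    def test_rows_are_nested_shells(self):
        g = geo.parse_tissue(_square_grid(5))
        source = [21, 22, 23, 24, 25]
        asg = rw.assign_rows(g, source, max_row=3)
        rows_of = lambda k: {c for c, r in asg.items() if r == k}
        for k in (1, 2, 3):
            for c in rows_of(k):
                neigh_rows = {asg.get(n) for n in g.neighbors(c)}
                assert (k - 1) in neigh_rows
                assert all(r is None or r >= k - 1 for r in neigh_rows)


def _mini_graph_with_angles(angles_deg):
    """Hand-built graph: one source cell (1) and one row-0 cell per angle,
    each junction's orientation set directly."""
    labels = np.zeros((2, 2), dtype=np.int32)
    cells = [1] + [i + 2 for i in range(len(angles_deg))]
    junctions = {}
    for i, ang in enumerate(angles_deg):
        pix = np.array([[0, 0]])
        j = geo.Junction((1, i + 2), pix, np.vstack([pix[0], pix[0]]))
        j.orientation_deg = ang
        j.band_rc = pix
        junctions[(1, i + 2)] = j
    return geo.TissueGraph(labels, cells, {c: np.array([[0, 0]])
                                           for c in cells},
                           set(junctions), junctions,
                           np.empty((0, 2), int))


class TestClassifyJunctions:
    def test_forty_five_degree_rule(self):
        """30 deg from the boundary -> horizontal, 60 deg ->
        medio-lateral, exactly 45 deg -> horizontal (documented
        tie-break)."""
        g = _mini_graph_with_angles([30.0, 60.0, 45.0, 44.9, 45.1])
        asg = {1: rw.SOURCE_ROW, 2: 0, 3: 0, 4: 0, 5: 0, 6: 0}
        df = rw.classify_junctions(g, asg, boundary_axis_deg=0.0)
        by_angle = dict(zip(df["cell_b"], df["junction_class"]))
        assert by_angle[2] == rw.HORIZONTAL          # 30 deg
        assert by_angle[3] == rw.MEDIO_LATERAL       # 60 deg
        assert by_angle[4] == rw.HORIZONTAL          # tie at 45
        assert by_angle[5] == rw.HORIZONTAL          # 44.9
        assert by_angle[6] == rw.MEDIO_LATERAL       # 45.1

    def test_angle_is_acute_and_axial(self):
        g = _mini_graph_with_angles([170.0])
        asg = {1: rw.SOURCE_ROW, 2: 0}
        df = rw.classify_junctions(g, asg, boundary_axis_deg=0.0)
        assert df["angle_to_boundary_deg"].iloc[0] == pytest.approx(10.0)

    def test_default_axis_from_boundary_junctions(self):
        """Without an explicit axis the boundary-0 junction mean is used."""
        g = _mini_graph_with_angles([80.0, 100.0])
        asg = {1: rw.SOURCE_ROW, 2: 0, 3: 0}
        df = rw.classify_junctions(g, asg)
        assert df.attrs["boundary_axis_deg"] == pytest.approx(90.0)

    def test_class_counts_partition_junctions(self, hex_tissue, hex_graph):
        width = hex_tissue.labels.shape[1]
        source = hex_tissue.cells.loc[hex_tissue.cells["seed_col"]
                                      < width / 6, "cell"].tolist()
        asg = rw.assign_rows(hex_graph, source, max_row=None)
        df = rw.classify_junctions(hex_graph, asg, boundary_axis_deg=90.0)
        n_assigned_junctions = sum(
            1 for (a, b) in hex_graph.junctions
            if a in asg and b in asg)
        assert len(df) == n_assigned_junctions
        assert (df["junction_class"].isin(
            [rw.HORIZONTAL, rw.MEDIO_LATERAL, rw.UNCLASSIFIED])).all()


@pytest.fixture(scope="module")
def boundary_setup():
    """Square-lattice tissue, overexpression domain at the bottom.

    The physical boundary runs horizontally (axis ~ 0 deg) and the
    uniform polarity axis is also 0 deg — the wing configuration, where
    the overexpression boundary and normal proximo-distal polarity are
    parallel.
    """
    tissue = syn.generate_tissue(syn.TissueSpec(seed=23,
                                                lattice="square",
                                                jitter=0.0))
    height = tissue.labels.shape[0]
    source = tissue.cells.loc[tissue.cells["seed_row"]
                              > height * 12 / 14, "cell"].tolist()
    fld = syn.PolarityField(psi0_deg=0.0, amplitude=100.0,
                            baseline=100.0)
    rend = syn.render_channels(tissue, fld, source_cells=source, seed=24)
    asg = rw.assign_rows(rend.graph, source, max_row=3)
    classes = rw.classify_junctions(rend.graph, asg)
    return rend, asg, classes


class TestIntensitySummaries:
    def test_inferred_boundary_axis_is_horizontal(self, boundary_setup):
        _, _, classes = boundary_setup
        axis = classes.attrs["boundary_axis_deg"]
        assert min(axis, 180.0 - axis) <= 2.0

    def test_uniform_field_class_ratio_near_two(self, boundary_setup):
        """Medio-lateral junctions (perpendicular to the polarity axis)
        read B + A = 2B; horizontal ones read B: class-mean ratio 2."""
        rend, asg, classes = boundary_setup
        table = rw.junction_intensity_table(
            rend.graph, classes, {"sfGFP": rend.channels["sfGFP"]})
        table = table[table["row"].notna()]   # drop source-internal ones
        ml = table.loc[table["junction_class"] == rw.MEDIO_LATERAL,
                       "mean_sfGFP"]
        hz = table.loc[table["junction_class"] == rw.HORIZONTAL,
                       "mean_sfGFP"]
        assert len(ml) and len(hz)
        assert ml.mean() / hz.mean() == pytest.approx(2.0, rel=0.10)

    def test_empty_class_reported_missing_not_zero(self, boundary_setup):
        rend, asg, classes = boundary_setup
        # square lattice has junctions only at 0/90: relative to axis 0,
        # every junction is exactly horizontal (0) or medio-lateral (90)
        summary = rw.summarize_junction_intensity(
            rend.graph, classes, {"sfGFP": rend.channels["sfGFP"]})
        assert not (summary["mean_intensity"] == 0.0).any()
        assert (summary["n_junctions"] > 0).all()

    def test_summary_invariant_under_relabelling(self):
        tissue = syn.generate_tissue(syn.TissueSpec(n_cols=6, n_rows=6,
                                                    seed=29))
        fld = syn.PolarityField(psi0_deg=0.0, amplitude=50.0,
                                baseline=100.0)
        rend = syn.render_channels(tissue, fld, seed=30)
        labels = tissue.labels
        n = int(labels.max())
        rng = np.random.default_rng(31)
        perm = np.concatenate([[0], rng.permutation(np.arange(1, n + 1))])
        relabeled = perm[labels]
        width = labels.shape[1]
        source = tissue.cells.loc[tissue.cells["seed_col"] < width / 6,
                                  "cell"].tolist()
        img = rend.channels["sfGFP"]

        def summarise(lab, src):
            g = geo.parse_tissue(lab)
            asg = rw.assign_rows(g, src, max_row=3)
            cls = rw.classify_junctions(g, asg, boundary_axis_deg=90.0)
            return rw.summarize_junction_intensity(g, cls, {"ch": img})

        s1 = summarise(labels, source)
        s2 = summarise(relabeled.astype(np.int32),
                       [int(perm[s]) for s in source])
        key = ["channel", "row", "junction_class", "boundary"]
        s1 = s1.sort_values(key).reset_index(drop=True)
        s2 = s2.sort_values(key).reset_index(drop=True)
        pd.testing.assert_frame_equal(s1, s2)

    def test_all_zero_channel_reads_minus_background(self, boundary_setup):
        rend, asg, classes = boundary_setup
        zero = np.zeros_like(rend.channels["sfGFP"])
        table = rw.junction_intensity_table(rend.graph, classes,
                                            {"z": zero},
                                            background={"z": 10.0})
        assert np.allclose(table["mean_z"], -10.0)
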