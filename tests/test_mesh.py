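"""Mesh construction, periodic geometry and the topological operators."""
import numpy as np
import pytest

from neurovertex import mesh as M


HEX_SIDE = np.sqrt(1.0 / (1.5 * np.sqrt(3.0)))  # side of the unit-area regular hexagon


class TestBuild:
    @pytest.mark.parametrize(
        "rows,cols,n_c,n_v,n_e",
        [(10, 10, 100, 200, 300), (15, 15, 225, 450, 675), (2, 2, 4, 8, 12), (3, 4, 12, 24, 36)],
    )
    def test_counts_and_defect_free(self, rows, cols, n_c, n_v, n_e):
        m = M.build_hexagonal_tissue(rows, cols)
        assert (m.n_cells, m.n_vertices, m.n_edges) == (n_c, n_v, n_e)
        assert all(len(c) == 6 for c in m.cells)
        assert M.topology_audit(m) == []

    def test_mean_side_count_exactly_six(self):
        for rows, cols in [(2, 3), (5, 7), (10, 10)]:
            m = M.build_hexagonal_tissue(rows, cols)
            assert np.mean([len(c) for c in m.cells]) == 6.0

    @pytest.mark.parametrize("rows,cols", [(1, 5), (5, 1), (0, 0)])
    def test_too_small_grids_rejected(self, rows, cols):
        with pytest.raises(M.MeshError):
            M.build_hexagonal_tissue(rows, cols)

    def test_tiling_covers_box(self):
        m = M.build_hexagonal_tissue(6, 5, cell_area=2.0)
        assert np.isclose(m.areas().sum(), m.box.prod(), rtol=1e-9)
        assert np.allclose(m.areas(), 2.0)


class TestGeometry:
    def test_unit_square(self, unit_square_mesh):
        assert M.cell_area(unit_square_mesh, 0) == pytest.approx(1.0)
        assert M.cell_perimeter(unit_square_mesh, 0) == pytest.approx(4.0)

    def test_regular_hexagon_closed_form(self, hex44):
        # side s: area (3 sqrt3 / 2) s^2, perimeter 6 s
        assert M.cell_area(hex44, 0) == pytest.approx(1.0)
        assert M.cell_perimeter(hex44, 0) == pytest.approx(6 * HEX_SIDE)

    def test_seam_straddling_cell_translation_invariant(self, hex44):
        areas0 = [M.cell_area(hex44, c) for c in range(hex44.n_cells)]
        perims0 = [M.cell_perimeter(hex44, c) for c in range(hex44.n_cells)]
        # shift so that several cells straddle both seams
        hex44.vertices += np.array([0.37 * hex44.box[0], 0.61 * hex44.box[1]])
        hex44.wrap()
        hex44.invalidate()
        areas1 = [M.cell_area(hex44, c) for c in range(hex44.n_cells)]
        perims1 = [M.cell_perimeter(hex44, c) for c in range(hex44.n_cells)]
        assert np.allclose(areas0, areas1)
        assert np.allclose(perims0, perims1)

    def test_degenerate_loop_raises(self, unit_square_mesh):
        unit_square_mesh.cells[0] = unit_square_mesh.cells[0][::-1]  # clockwise
        unit_square_mesh.invalidate()
        with pytest.raises(M.MeshError):
            M.cell_area(unit_square_mesh, 0)


class TestShortEdges:
    def test_uniform_tissue_has_none(self, hex44):
        assert M.detect_short_edges(hex44, M.TopologyParams()) == []

    def test_threshold_is_strict_less_than(self):
        # rectangle with binary-exact side lengths: h = 0.125, w = 0.875,
        # mean edge = 0.5, so with a 25% threshold the cutoff is exactly h
        def rect_mesh(h):
            w = 0.875
            verts = np.array([[0.0, 0.0], [w, 0.0], [w, h], [0.0, h]])
            return M.Mesh(verts, [[0, 1, 2, 3]], box=(10.0, 10.0))

        tp = M.TopologyParams(t1_threshold_fraction=0.25, l_new=1.0)
        assert M.detect_short_edges(rect_mesh(0.125), tp) == []  # exactly at: excluded
        shorts = M.detect_short_edges(rect_mesh(0.0625), tp)  # strictly below
        assert sorted(shorts) == [(0, 3), (1, 2)]

    def test_one_percent_edge_detected_and_ordered(self, hex44):
        tp = M.TopologyParams(t1_threshold_fraction=0.03, l_new=1.0)
        mean0 = hex44.mean_edge_length()
        edge = next(iter(hex44.edges()))
        M.t1_transition(hex44, edge, M.TopologyParams(l_new=0.01 * mean0))
        shorts = M.detect_short_edges(hex44, tp)
        assert len(shorts) == 1


class TestT1:
    def test_neighbour_count_pattern(self, hex44):
        edge = next(iter(hex44.edges()))
        before = [len(c) for c in hex44.cells]
        info = M.t1_transition(hex44, edge, M.TopologyParams(l_new=0.05))
        after = [len(c) for c in hex44.cells]
        a, b, c, d = info["cells"]
        assert before[a] == before[b] == before[c] == before[d] == 6
        assert (after[a], after[b], after[c], after[d]) == (5, 5, 7, 7)
        assert M.topology_audit(hex44) == []

    def test_new_edge_length_and_perpendicularity(self, hex44):
        edge = next(iter(hex44.edges()))
        i, j = edge
        old_vec = hex44.minimum_image(hex44.vertices[j] - hex44.vertices[i])
        info = M.t1_transition(hex44, edge, M.TopologyParams(l_new=0.07))
        new_vec = hex44.minimum_image(hex44.vertices[j] - hex44.vertices[i])
        assert np.hypot(*new_vec) == pytest.approx(0.07)
        assert abs(float(old_vec @ new_vec)) < 1e-12
        assert abs(info["new_angle"] - info["old_angle"]) == pytest.approx(np.pi / 2)

    def test_conserves_counts(self, hex44):
        counts = (hex44.n_vertices, hex44.n_cells, hex44.n_edges)
        M.t1_transition(hex44, next(iter(hex44.edges())), M.TopologyParams(l_new=0.05))
        assert (hex44.n_vertices, hex44.n_cells, hex44.n_edges) == counts

    def test_missing_junction_raises(self, hex44):
        with pytest.raises(M.MeshError):
            M.t1_transition(hex44, (0, 9999), M.TopologyParams(l_new=0.05))

    def test_triangle_protected_unless_collapse_allowed(self):
        m, tri = _mesh_with_triangle()
        loop = m.cells[tri]
        edge = tuple(sorted((loop[0], loop[1])))
        with pytest.raises(M.MeshError):
            M.t1_transition(m, edge, M.TopologyParams(l_new=0.05), allow_collapse=False)

    def test_collapse_to_two_sided_removes_cell(self):
        m, tri = _mesh_with_triangle()
        n_before = (m.n_vertices, m.n_cells, m.n_edges)
        loop = m.cells[tri]
        edge = tuple(sorted((loop[0], loop[1])))
        info = M.t1_transition(m, edge, M.TopologyParams(l_new=0.02), allow_collapse=True)
        assert info["removed"] is not None
        assert (m.n_vertices, m.n_cells, m.n_edges) == (
            n_before[0] - 2, n_before[1] - 1, n_before[2] - 3,
        )
        assert M.topology_audit(m) == []
        assert np.isclose(m.areas().sum(), m.box.prod(), rtol=1e-9)


def _mesh_with_triangle():
    """5x5 tissue with one cell reduced to a triangle by repeated T1s."""
    m = M.build_hexagonal_tissue(5, 5)
    target = 7
    tp = M.TopologyParams(l_new=0.05)
    while len(m.cells[target]) > 3:
        loop = m.cells[target]
        pts = m.unwrapped_loop(target)
        ev = np.roll(pts, -1, axis=0) - pts
        lens = np.hypot(ev[:, 0], ev[:, 1])
        k = int(np.argmin(lens))
        e = tuple(sorted((loop[k], loop[(k + 1) % len(loop)])))
        M.t1_transition(m, e, tp)
    assert M.topology_audit(m) == []
    return m, target


class TestDivision:
    def test_hexagon_gives_two_pentagons(self, hex44, rng):
        counts = (hex44.n_vertices, hex44.n_cells, hex44.n_edges)
        a, b, info = M.divide_cell(hex44, 5, rng)
        assert len(hex44.cells[a]) == 5 and len(hex44.cells[b]) == 5
        assert (hex44.n_vertices, hex44.n_cells, hex44.n_edges) == (
            counts[0] + 2, counts[1] + 1, counts[2] + 3,
        )
        assert M.topology_audit(hex44) == []

    def test_odd_sided_cell_divides_cleanly(self, hex44, rng):
        M.t1_transition(hex44, next(iter(hex44.edges())), M.TopologyParams(l_new=0.05))
        heptagon = next(c for c in range(hex44.n_cells) if len(hex44.cells[c]) == 7)
        a, b, _ = M.divide_cell(hex44, heptagon, rng)
        assert {len(hex44.cells[a]), len(hex44.cells[b])} == {5, 6}
        assert M.topology_audit(hex44) == []

    def test_too_few_sides_rejected(self):
        m, tri = _mesh_with_triangle()
        with pytest.raises(M.MeshError):
            M.divide_cell(m, tri, np.random.default_rng(0))

    def test_edge_selection_weighted_by_length(self, rng):
        from scipy.stats import chisquare

        base = M.build_hexagonal_tissue(4, 4)
        base.vertices += 0.08 * rng.standard_normal(base.vertices.shape)
        base.wrap()
        base.invalidate()
        pts = base.unwrapped_loop(5)
        lens = np.hypot(*(np.roll(pts, -1, axis=0) - pts).T)
        n_draws = 400
        picks = np.zeros(len(lens))
        for _ in range(n_draws):
            m = base.copy()
            _, _, info = M.divide_cell(m, 5, rng)
            picks[info["edge_pair"][0]] += 1
        expected = n_draws * lens / lens.sum()
        assert chisquare(picks, expected).pvalue > 1e-3


class TestRemoval:
    def test_requires_two_sided(self, hex44):
        with pytest.raises(M.MeshError):
            M.remove_cell(hex44, 0)

    def test_area_conservation_through_event_sequence(self, hex44, rng):
        box_area = hex44.box.prod()
        for cell in [3, 7]:
            M.divide_cell(hex44, cell, rng)
        M.t1_transition(hex44, next(iter(hex44.edges())), M.TopologyParams(l_new=0.05))
        assert np.isclose(hex44.areas().sum(), box_area, rtol=1e-9)
        assert M.topology_audit(hex44) == []


class TestAudit:
    def test_fresh_tissue_clean(self, hex44):
        assert M.topology_audit(hex44) == []

    def test_corrupted_orientation_detected(self, hex44):
        hex44.cells[3] = hex44.cells[3][::-1]
        hex44.invalidate()
        issues = M.topology_audit(hex44)
        assert any("area" in s or "sides" in s for s in issues)

    def test_long_run_with_events_stays_clean(self, rng):
        """Regression: many interleaved divisions and T1s keep all invariants."""
        m = M.build_hexagonal_tissue(4, 4)
        m.vertices += 0.05 * rng.standard_normal(m.vertices.shape)
        m.wrap()
        m.invalidate()
        tp = M.TopologyParams(l_new=None)
        for k in range(60):
            alpha = int(rng.integers(m.n_cells))
            if len(m.cells[alpha]) >= 4:
                M.divide_cell(m, alpha, rng)
            for e in M.detect_short_edges(m, tp)[:1]:
                try:
                    M.t1_transition(m, e, tp)
                except M.MeshError:
                    pass
        assert M.topology_audit(m) == []
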