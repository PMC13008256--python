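import numpy as np
import pytest

from bivtwin.anatomy import solve_laplace
from bivtwin.conduction import (FractalTreeParams, PMJCoupling, PurkinjeTree,
                                apply_variant, build_his_bundle, couple_pmjs,
                                grow_fractal_tree, pmj_metrics,
                                project_tree_depth, surface_geodesic)
from bivtwin.mesh import make_slab_mesh


@pytest.fixture(scope="module")
def wide_slab():
    return make_slab_mesh((2.0, 2.0, 0.5), 1000.0)


@pytest.fixture(scope="module")
def wide_coords(wide_slab):
    tm = solve_laplace(wide_slab, {"endo": 0.0, "epi": 1.0})
    ab = solve_laplace(wide_slab, {"apex": 0.0, "base": 1.0})
    return tm, ab


class TestGeodesics:
    def test_straight_on_flat_surface(self, wide_slab):
        """On a plane the geodesic hugs the chord between its endpoints."""
        surf = wide_slab.surface_tags["endo"]
        path = surface_geodesic(wide_slab, surf, (0.2, 0.2, 0.0), (1.8, 1.6, 0.0))
        pts = wide_slab.nodes[path]
        a, b = pts[0], pts[-1]
        chord = b - a
        chord /= np.linalg.norm(chord)
        # every vertex within about one edge length of the chord
        dev = np.linalg.norm((pts - a) - np.outer((pts - a) @ chord, chord), axis=1)
        h = wide_slab.edge_length_stats()["mean"] * 1e-4
        assert dev.max() <= 1.2 * h

    def test_length_at_least_euclidean(self, wide_slab):
        surf = wide_slab.surface_tags["endo"]
        path = surface_geodesic(wide_slab, surf, (0.1, 0.3, 0.0), (1.9, 1.7, 0.0))
        pts = wide_slab.nodes[path]
        length = np.linalg.norm(np.diff(pts, axis=0), axis=1).sum()
        assert length >= np.linalg.norm(pts[-1] - pts[0]) - 1e-12

    def test_off_surface_landmark_rejected(self, wide_slab):
        with pytest.raises(ValueError):
            surface_geodesic(wide_slab, wide_slab.surface_tags["endo"],
                             (0.2, 0.2, 5.0), (1.8, 1.6, 0.0), tol_cm=0.5)


class TestHisBundle:
    def test_three_branch_terminals(self, wide_slab):
        lm = dict(av_node=(0.1, 1.0, 0.0), bifurcation=(0.4, 1.0, 0.0),
                  lv_anterior=(1.8, 0.3, 0.0), lv_posterior=(1.8, 1.7, 0.0),
                  rv=(1.0, 1.9, 0.0))
        his = build_his_bundle(wide_slab, lm)
        assert len(his.terminals) == 3
        assert his.is_tree()

    def test_missing_landmark_rejected(self, wide_slab):
        with pytest.raises(ValueError):
            build_his_bundle(wide_slab, {"av_node": (0, 0, 0)})


class TestFractalTree:
    def test_zero_generations_returns_seeds(self, wide_slab):
        t = grow_fractal_tree(wide_slab, wide_slab.surface_tags["endo"],
                              np.array([[1.0, 1.0, 0.0]]),
                              FractalTreeParams(generations=0))
        assert t.n_nodes == 1
        assert len(t.segments) == 0
        assert np.array_equal(t.terminals, [0])

    def test_exclusion_region_has_no_terminals(self, wide_slab):
        excl = wide_slab.surface_tags["endo"][
            wide_slab.nodes[wide_slab.surface_tags["endo"], 0] > 1.2]
        t = grow_fractal_tree(wide_slab, wide_slab.surface_tags["endo"],
                              np.array([[0.5, 1.0, 0.0]]),
                              FractalTreeParams(initial_length_cm=0.6,
                                                generations=4),
                              exclusions=excl, rng_seed=1)
        assert np.all(t.nodes[t.terminals, 0] <= 1.2 + 1e-9)

    def test_segment_count_matches_growth_rule_enumeration(self, wide_slab):
        """Unobstructed growth yields steps * (2^G - 1) segments."""
        p = FractalTreeParams(initial_length_cm=0.4, generations=3,
                              steps_per_branch=3, length_jitter=0.1)
        t = grow_fractal_tree(wide_slab, wide_slab.surface_tags["endo"],
                              np.array([[1.0, 1.0, 0.0]]), p, rng_seed=5)
        assert len(t.segments) == p.steps_per_branch * (2 ** p.generations - 1)
        assert len(t.terminals) == 2 ** (p.generations - 1)
        assert t.is_tree()

    def test_deterministic_per_seed(self, wide_slab):
        p = FractalTreeParams(generations=3)
        a = grow_fractal_tree(wide_slab, wide_slab.surface_tags["endo"],
                              np.array([[1.0, 1.0, 0.0]]), p, rng_seed=9)
        b = grow_fractal_tree(wide_slab, wide_slab.surface_tags["endo"],
                              np.array([[1.0, 1.0, 0.0]]), p, rng_seed=9)
        assert np.array_equal(a.nodes, b.nodes)
        assert np.array_equal(a.segments, b.segments)


@pytest.fixture(scope="module")
def surface_tree(wide_slab):
    return grow_fractal_tree(wide_slab, wide_slab.surface_tags["endo"],
                             np.array([[1.0, 1.0, 0.0]]),
                             FractalTreeParams(initial_length_cm=0.5,
                                               generations=4), rng_seed=3)


class TestDepthProjection:
    def test_zero_fraction_all_subendocardial(self, wide_slab, wide_coords,
                                              surface_tree):
        tm, _ = wide_coords
        proj = project_tree_depth(surface_tree, wide_slab, tm, 0.0)
        assert np.all(proj.depth_label[proj.terminals] == 1)
        assert proj.is_tree()

    def test_seventyfive_percent_intramyocardial(self, wide_slab, wide_coords,
                                                 surface_tree):
        tm, _ = wide_coords
        proj = project_tree_depth(surface_tree, wide_slab, tm, 75.0)
        n_intra = int((proj.depth_label[proj.terminals] == 2).sum())
        expect = 0.75 * len(proj.terminals)
        assert abs(n_intra - expect) <= 1.0

    def test_full_fraction_lands_in_mid_third(self):
        """All relocated terminals sit inside the midmyocardial middle third."""
        from scipy.spatial import cKDTree

        # seven transmural layers so the mid-third band holds mesh nodes
        mesh = make_slab_mesh((1.5, 1.5, 0.5), 900.0)
        tm = solve_laplace(mesh, {"endo": 0.0, "epi": 1.0})
        tree = grow_fractal_tree(mesh, mesh.surface_tags["endo"],
                                 np.array([[0.75, 0.75, 0.0]]),
                                 FractalTreeParams(initial_length_cm=0.4,
                                                   generations=4), rng_seed=3)
        proj = project_tree_depth(tree, mesh, tm, 100.0)
        kd = cKDTree(mesh.nodes)
        _, near = kd.query(proj.nodes[proj.terminals])
        coord = tm.values[near]
        lo = 0.40 + 0.35 / 3.0
        hi = 0.40 + 2 * 0.35 / 3.0
        assert np.all((coord >= lo - 1e-9) & (coord <= hi + 1e-9))


class TestVariants:
    def test_be_is_identity(self, wide_slab, surface_tree):
        out = apply_variant(surface_tree, "be", wide_slab)
        assert out is surface_tree

    def test_unknown_variant_rejected(self, wide_slab, surface_tree):
        with pytest.raises(ValueError):
            apply_variant(surface_tree, "xx", wide_slab)

    def _projected(self, wide_slab, wide_coords, surface_tree):
        tm, _ = wide_coords
        return project_tree_depth(surface_tree, wide_slab, tm, 75.0, rng_seed=2)

    def test_mi_retention_and_depth_proportions(self, wide_slab, wide_coords):
        """42 % of affected-zone junctions retained, spread 51:36:13."""
        tm, _ = wide_coords
        # a dense synthetic tree whose terminals all sit in the affected zone
        rng = np.random.default_rng(0)
        n_term = 100
        pts = np.column_stack([rng.uniform(0.2, 1.8, n_term),
                               rng.uniform(0.2, 1.8, n_term),
                               np.zeros(n_term)])
        nodes = [np.array([1.0, 1.0, 0.0])]
        segs, terms = [], []
        for p in pts:
            nodes.append(p)
            segs.append((0, len(nodes) - 1))
            terms.append(len(nodes) - 1)
        tree = PurkinjeTree(np.array(nodes), np.array(segs), root=0,
                            terminals=np.array(terms),
                            depth_label=np.ones(n_term + 1, dtype=np.int64))
        az = np.arange(wide_slab.n_nodes)  # whole mesh affected
        out = apply_variant(tree, "mi", wide_slab, transmural_coord=tm,
                            az_mask=az, rng_seed=7)
        assert len(out.terminals) == 42
        hist = [int((out.depth_label[out.terminals] == code).sum())
                for code in (1, 2, 3)]
        expect = [round(0.51 * 42), round(0.36 * 42), round(0.13 * 42)]
        assert all(abs(h - e) <= 1 for h, e in zip(hist, expect))
        assert out.is_tree()

    def test_ap_e_flattens_to_endocardium(self, wide_slab, wide_coords,
                                          surface_tree):
        proj = self._projected(wide_slab, wide_coords, surface_tree)
        out = apply_variant(proj, "ap-e", wide_slab)
        assert np.all(out.depth_label == 0)
        assert np.abs(out.nodes[:, 2]).max() < 1e-9  # back on the z=0 face
        assert out.is_tree()


class TestPMJCoupling:
    def test_radius_below_clearance_connects_nothing(self, wide_slab):
        # tree hovering 2.5 mm above the slab's top face (z = 0.5)
        tree = PurkinjeTree(np.array([[1.0, 1.0, 0.8], [1.0, 1.0, 0.75]]),
                            np.array([[0, 1]]), root=0,
                            terminals=np.array([1]))
        c = couple_pmjs(tree, wide_slab, 0.5)  # 0.5 mm << 2.5 mm clearance
        assert not c.connected_mask().any()

    def test_matches_brute_force_distance_search(self, wide_slab, surface_tree):
        radius_mm = 1.5
        c = couple_pmjs(surface_tree, wide_slab, radius_mm)
        for term, found in zip(c.terminals, c.node_sets):
            d = np.linalg.norm(wide_slab.nodes - surface_tree.nodes[term], axis=1)
            brute = np.flatnonzero(d <= radius_mm / 10.0)
            assert np.array_equal(found, brute)

    def test_negative_radius_rejected(self, wide_slab, surface_tree):
        with pytest.raises(ValueError):
            couple_pmjs(surface_tree, wide_slab, -1.0)


class TestPMJMetrics:
    def toy(self):
        nodes = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0],
                          [1.0, 1.0, 0], [2.0, 1.0, 0]])
        segs = np.array([[0, 1], [1, 2], [0, 3], [3, 4]])
        return PurkinjeTree(nodes, segs, root=0, terminals=np.array([2, 4]))

    def test_retrograde_only_gives_zero(self):
        tree = self.toy()
        coupling = PMJCoupling(tree.terminals, [np.array([0]), np.array([1])], 0.5)
        cs_at = np.array([0.0, 1.0, 2.0, 1.0, 2.0])
        myo_at = np.array([-5.0, -5.0])  # myocardium fired long before
        m = pmj_metrics(coupling, tree, cs_at, myo_at)
        assert m.aPMJ == 0.0 and m.ncPMJ == 100.0

    def test_unit_lag_all_anterograde(self):
        tree = self.toy()
        coupling = PMJCoupling(tree.terminals, [np.array([0]), np.array([1])], 0.5)
        cs_at = np.array([0.0, 1.0, 2.0, 1.0, 2.0])
        myo_at = np.array([2.0, 2.0])  # 1 ms after each penultimate node
        m = pmj_metrics(coupling, tree, cs_at, myo_at)
        assert (m.ncPMJ, m.aPMJ, m.cpPMJ) == (100.0, 100.0, 1.0)

    def test_randomized_instance_matches_brute_force(self):
        rng = np.random.default_rng(8)
        tree = self.toy()
        n_myo = 30
        sets = [np.sort(rng.choice(n_myo, size=rng.integers(0, 5), replace=False))
                for _ in tree.terminals]
        coupling = PMJCoupling(tree.terminals, sets, 1.0)
        cs_at = rng.uniform(0, 10, size=tree.n_nodes)
        myo_at = rng.uniform(0, 12, size=n_myo)
        m = pmj_metrics(coupling, tree, cs_at, myo_at, window_ms=1.5)
        parent = tree.parent_map()
        n_conn = sum(len(s) > 0 for s in sets)
        exp_nc = 100.0 * n_conn / len(sets)
        exp_cp = np.mean([len(s) for s in sets if len(s)]) if n_conn else 0.0
        n_ant = 0
        for t, s in zip(tree.terminals, sets):
            if len(s) == 0:
                continue
            lag = myo_at[s] - cs_at[parent[t]]
            if np.any((lag >= 0) & (lag <= 1.5)):
                n_ant += 1
        assert m.ncPMJ == pytest.approx(exp_nc)
        assert m.cpPMJ == pytest.approx(exp_cp)
        assert m.aPMJ == pytest.approx(100.0 * n_ant / len(sets))
        assert m.aPMJ <= m.ncPMJ

    def test_negative_window_rejected(self):
        tree = self.toy()
        coupling = PMJCoupling(tree.terminals, [np.array([0]), np.array([1])], 0.5)
        with pytest.raises(ValueError):
            pmj_metrics(coupling, tree, np.zeros(5), np.zeros(2), window_ms=-1.0)
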