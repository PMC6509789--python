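"""Normalized Normal Constraint solver: geometry, lattice, fronts, filtering."""

from math import comb

import numpy as np
import pytest

from paretoflux import (
    FluxObjective,
    MofaProblem,
    compute_anchor_points,
    export_front,
    generate_utopia_lattice,
    load_front,
    make_toy,
    pareto_filter,
    run_mofa,
    solve_lattice_point,
)
from paretoflux.nnc import ParetoPoint

from .oracles import brute_force_pareto, epsilon_constraint_front


def two_objective_problem(toy, spacing=10, co2_objective=False):
    objs = [
        FluxObjective.for_reaction("EX_biomass", label="growth"),
        FluxObjective.for_reaction("EX_h2", label="h2"),
    ]
    return MofaProblem(toy, objs, spacing=spacing)


def three_objective_problem(toy, spacing=5):
    objs = [
        FluxObjective.for_reaction("EX_biomass", label="growth"),
        FluxObjective.for_reaction("EX_co2", label="co2"),
        FluxObjective.for_reaction("EX_h2", label="h2"),
    ]
    return MofaProblem(toy, objs, spacing=spacing)


class TestLattice:
    @pytest.mark.parametrize(
        "n, m, count",
        [(2, 10, 11), (3, 5, 21), (8, 10, 19448), (2, 1, 2), (4, 3, 20)],
    )
    def test_counts_match_closed_form(self, n, m, count):
        lattice = generate_utopia_lattice(n, m)
        assert len(lattice) == count == comb(m + n - 1, n - 1)

    def test_weights_sum_to_one_on_grid(self):
        for w in generate_utopia_lattice(3, 4):
            assert w.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.allclose(np.round(w * 4), w * 4)

    def test_deterministic_lexicographic_order(self):
        a = generate_utopia_lattice(3, 3)
        b = generate_utopia_lattice(3, 3)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))
        assert len({tuple(w) for w in a}) == len(a)


class TestAnchors:
    def test_anchor_equals_plain_fba_optimum(self, toy, growth_objective):
        from paretoflux import fba

        geometry = compute_anchor_points(two_objective_problem(toy))
        assert geometry.anchor_points[0, 0] == pytest.approx(
            fba(toy, growth_objective).objective_value, abs=1e-9
        )

    def test_h2_anchor_has_zero_growth(self, toy):
        geometry = compute_anchor_points(two_objective_problem(toy))
        assert geometry.anchor_points[1, 0] == pytest.approx(0.0, abs=1e-9)
        assert geometry.anchor_points[1, 1] == pytest.approx(20.0, abs=1e-9)

    def test_normalized_anchor_attains_one_in_own_coordinate(self, toy):
        geometry = compute_anchor_points(three_objective_problem(toy))
        ebar = geometry.normalized_anchors
        for k in range(3):
            assert ebar[k, k] == pytest.approx(1.0, abs=1e-9)
            assert np.all(ebar >= -1e-9) and np.all(ebar <= 1 + 1e-9)

    def test_unbounded_objective_names_culprit(self, toy):
        # genuinely infinite acetate, light and capacity leave the growth
        # archetype unbounded (the fixture's finite big-M caps are removed)
        loose = toy.copy()
        for rxn in loose.reactions:
            if rxn.upper_bound > 0:
                rxn.upper_bound = np.inf
        loose.reaction("EX_ac").lower_bound = -np.inf
        loose.reaction("EX_photon").lower_bound = -np.inf
        problem = two_objective_problem(loose)
        with pytest.raises(ValueError, match="growth"):
            compute_anchor_points(problem)


class TestLatticePointSolves:
    def test_corner_weights_recover_anchors(self, toy):
        problem = three_objective_problem(toy)
        geometry = compute_anchor_points(problem)
        for k in range(3):
            w = np.zeros(3)
            w[k] = 1.0
            pt = solve_lattice_point(problem, geometry, w)
            assert pt is not None
            assert np.allclose(pt.normalized, geometry.normalized_anchors[k], atol=1e-6)

    def test_front_matches_epsilon_constraint_sweep(self, toy):
        """Each NNC point's H2 optimum agrees with an epsilon-constraint
        oracle (cobra/GLPK) at the same growth level, to 1e-6."""
        front = run_mofa(two_objective_problem(toy, spacing=10))
        growth_levels = [pt.objective_values[0] for pt in front.solutions]
        oracle = epsilon_constraint_front(toy, "EX_biomass", "EX_h2", growth_levels)
        assert len(oracle) == len(front.solutions)
        paired = sorted(front.solutions, key=lambda p: p.objective_values[0])
        oracle = sorted(oracle)
        for pt, (g, h) in zip(paired, oracle):
            assert pt.objective_values[0] == pytest.approx(g, abs=1e-6)
            assert pt.objective_values[1] == pytest.approx(h, abs=1e-6)

    def test_three_objective_points_nondominated_vs_dense_oracle(self, toy):
        """No dense epsilon/weighted-sum sample dominates any returned point."""
        rng = np.random.default_rng(0)
        front = run_mofa(three_objective_problem(toy, spacing=4))
        from .oracles import to_cobra

        cm = to_cobra(toy)
        samples = []
        for _ in range(150):
            w = rng.dirichlet(np.ones(3))
            cm.objective = {
                cm.reactions.EX_biomass: w[0],
                cm.reactions.EX_co2: w[1],
                cm.reactions.EX_h2: w[2],
            }
            sol = cm.optimize()
            samples.append(
                [sol.fluxes["EX_biomass"], sol.fluxes["EX_co2"], sol.fluxes["EX_h2"]]
            )
        samples = np.array(samples)
        for pt in front.solutions:
            raw = pt.objective_values
            dominating = np.all(samples >= raw - 1e-6, axis=1) & np.any(
                samples > raw + 1e-6, axis=1
            )
            assert not dominating.any()


class TestParetoFilter:
    def _points(self, vectors):
        return [
            ParetoPoint(np.zeros(len(v)), np.asarray(v, float), np.asarray(v, float), None)
            for v in vectors
        ]

    def test_strict_domination_removed(self):
        pts = self._points([(1, 0), (0, 1), (0.5, 0.5), (0.4, 0.4)])
        kept = pareto_filter(pts)
        assert [tuple(p.normalized) for p in kept] == [(1, 0), (0, 1), (0.5, 0.5)]

    def test_single_point_unchanged(self):
        pts = self._points([(0.3, 0.7)])
        assert pareto_filter(pts) == pts

    def test_500_random_vectors_match_quadratic_oracle(self):
        rng = np.random.default_rng(42)
        vectors = rng.random((500, 4))
        keep_idx = brute_force_pareto(vectors)
        kept = pareto_filter(self._points(vectors))
        got = {tuple(np.round(p.normalized, 9)) for p in kept}
        want = {tuple(np.round(vectors[i], 9)) for i in keep_idx}
        assert got == want

    def test_duplicates_collapse(self):
        pts = self._points([(0.5, 0.5), (0.5, 0.5), (0.5 + 1e-9, 0.5)])
        assert len(pareto_filter(pts)) == 1


class TestRunMofa:
    def test_two_objective_front_is_monotone_tradeoff(self, toy):
        front = run_mofa(two_objective_problem(toy))
        pts = sorted(front.solutions, key=lambda p: p.objective_values[0])
        h2 = [p.objective_values[1] for p in pts]
        assert all(b <= a + 1e-9 for a, b in zip(h2, h2[1:]))

    def test_h2_beyond_growth_anchor_costs_growth(self, toy):
        """Pushing H2 above the growth archetype's level strictly lowers
        growth; the H2 archetype stops growth entirely."""
        front = run_mofa(two_objective_problem(toy))
        growth_anchor = front.geometry.anchor_points[0]
        for pt in front.solutions:
            if pt.objective_values[1] > growth_anchor[1] + 1e-6:
                assert pt.objective_values[0] < growth_anchor[0] - 1e-9
        h2_max = max(pt.objective_values[1] for pt in front.solutions)
        (h2_pt,) = [p for p in front.solutions if p.objective_values[1] == h2_max]
        assert h2_pt.objective_values[0] == pytest.approx(0.0, abs=1e-9)

    def test_front_internally_nondominated(self, toy):
        front = run_mofa(three_objective_problem(toy, spacing=3))
        vecs = np.array([p.normalized for p in front.solutions])
        assert len(brute_force_pareto(vecs)) == len(vecs)

    def test_scale_invariance_of_normalized_front(self, toy):
        base = run_mofa(two_objective_problem(toy))
        scaled_objs = [
            FluxObjective({"EX_biomass": 1000.0}, label="growth"),
            FluxObjective.for_reaction("EX_h2", label="h2"),
        ]
        scaled = run_mofa(MofaProblem(toy, scaled_objs, spacing=10))
        a = sorted(tuple(p.normalized) for p in base.solutions)
        b = sorted(tuple(p.normalized) for p in scaled.solutions)
        assert np.allclose(a, b, atol=1e-6)

    def test_rerun_deterministic(self, toy):
        f1 = run_mofa(three_objective_problem(toy, spacing=5))
        f2 = run_mofa(three_objective_problem(toy, spacing=5))
        assert f1.n_unique == f2.n_unique
        for p1, p2 in zip(f1.solutions, f2.solutions):
            assert np.allclose(p1.objective_values, p2.objective_values, atol=1e-9)
            assert p1.flux.fluxes == pytest.approx(p2.flux.fluxes, abs=1e-9)

    def test_provenance_recorded(self, toy):
        front = run_mofa(two_objective_problem(toy, spacing=2))
        assert front.provenance["spacing"] == 2
        assert front.provenance["n_lattice"] == 3
        assert "solver" in front.provenance


class TestExport:
    def test_tsv_round_trip(self, toy, tmp_path):
        front = run_mofa(two_objective_problem(toy))
        path = tmp_path / "front.tsv"
        export_front(front, path)
        frame = load_front(path)
        assert len(frame) == front.n_unique
        assert list(frame.columns) == [
            "w_growth", "w_h2", "norm_growth", "norm_h2", "raw_growth", "raw_h2",
        ]
        norm = frame[["norm_growth", "norm_h2"]].to_numpy()
        assert (norm >= -1e-9).all() and (norm <= 1 + 1e-9).all()

    def test_empty_front_refused(self, toy):
        front = run_mofa(two_objective_problem(toy, spacing=2))
        front.solutions = []
        with pytest.raises(ValueError):
            export_front(front, "/tmp/should_not_exist.tsv")

    def test_heatmap_renders(self, toy, tmp_path):
        from paretoflux.nnc import render_front

        front = run_mofa(two_objective_problem(toy, spacing=3))
        png = tmp_path / "front.png"
        render_front(front, png)
        assert png.stat().st_size > 0
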