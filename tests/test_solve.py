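import itertools
import math

import numpy as np
import pytest

from domctx.bench import InstanceParams, generate_instance
from domctx.conflicts import ConflictGraph, build_conflict_graph, greedy_clique_cover
from domctx.context import estimate_scores
from domctx.scoring import objective
from domctx.solve import (
    Solution,
    brute_force,
    build_ilp,
    is_trivial,
    positive_elimination,
    predict,
    solve_ilp,
)

TOL = 1e-6


@pytest.fixture
def plain_meta(make_meta_map):
    return make_meta_map({f: {"t_dom": 0.0} for f in "AB"})


def _two_candidate_instance(make_cand, plain_meta, s_ab):
    """Two non-conflicting candidates with gains 3 and 2 and S(A,B)=s_ab."""
    # engineer the exact pair score with n=2, alpha=1:
    # S = log2((c+1)*4 / (c+4)); invert for c, or use a penalty-only model
    if s_ab == 1.0:
        model = estimate_scores({("A", "B"): 2}, ["A", "B"], alpha=1.0)
    else:
        raise NotImplementedError
    cands = [
        make_cand("A", 1, 50, bitscore=3.0),
        make_cand("B", 200, 250, bitscore=2.0),
    ]
    return cands, model


class TestPositiveElimination:
    def test_lone_negative_domain_eliminated(self, make_cand, plain_meta, zero_context_model):
        model = zero_context_model(["A", "B"])
        cands = [make_cand("A", 1, 50, bitscore=-1.0)]
        assert positive_elimination(cands, plain_meta, model) == []

    def test_positive_context_rescues(self, make_cand, plain_meta, ab_model):
        # gain -1, partner context log2(3) ~ +1.58 => S+ > 0, kept
        cands = [
            make_cand("A", 1, 50, bitscore=-1.0),
            make_cand("B", 200, 250, bitscore=5.0),
        ]
        surv = positive_elimination(cands, plain_meta, ab_model)
        assert len(surv) == 2

    def test_conflict_zeroes_pair_contribution(self, make_cand, make_meta_map):
        # big positive S but the pair conflicts, so it cannot rescue anyone
        meta = make_meta_map({"A": {"t_dom": 0.0}, "B": {"t_dom": 0.0}})
        model = estimate_scores({("A", "B"): 1000}, ["A", "B"], alpha=1.0)
        assert model.score("A", "B") > 1.9
        cands = [
            make_cand("A", 1, 100, bitscore=-1.0),
            make_cand("B", 10, 110, bitscore=-1.0),
        ]
        assert positive_elimination(cands, meta, model) == []

    def test_iterates_to_fixpoint(self, make_cand, plain_meta, ab_model):
        # B's only support is A; once A falls (gain too negative), B falls too
        s = ab_model.score("A", "B")
        cands = [
            make_cand("A", 1, 50, bitscore=-(s + 1.0)),
            make_cand("B", 200, 250, bitscore=-(s - 0.1)),
        ]
        assert positive_elimination(cands, plain_meta, ab_model) == []

    def test_family_surplus_elimination(self, make_cand, make_meta_map, zero_context_model):
        # gain 1.5 < t_tilde 2.0: whole family eliminated
        meta = make_meta_map({"A": {"t_dom": 10.0, "t_seq": 12.0}})
        model = zero_context_model(["A"])
        cands = [make_cand("A", 1, 50, bitscore=11.5)]
        assert positive_elimination(cands, meta, model) == []

    def test_soundness_on_random_instances(self):
        for seed in range(60):
            inst = generate_instance(
                InstanceParams(k=2 + seed % 9, conflict_rate=0.4, frac_ttilde_positive=0.3),
                seed=seed,
            )
            surv = positive_elimination(inst.candidates, inst.meta, inst.model)
            full = brute_force(inst.candidates, inst.meta, inst.model)
            pruned = brute_force(surv, inst.meta, inst.model)
            assert pruned.objective == pytest.approx(full.objective, abs=TOL)

    def test_quadratic_iteration_cost(self, make_cand, make_meta_map, zero_context_model):
        fams = {f"F{i}": {"t_dom": 0.0} for i in range(12)}
        meta = make_meta_map(fams)
        model = zero_context_model(sorted(fams))
        cands = [
            make_cand(f"F{i}", 1 + 300 * i, 100 + 300 * i, bitscore=float(i) - 5.0)
            for i in range(12)
        ]
        stats = {}
        positive_elimination(cands, meta, model, stats=stats)
        assert stats["pair_evals"] <= stats["iterations"] * len(cands) ** 2


class TestIsTrivial:
    def test_clean_survivors_trivial_and_optimal(self, make_cand, plain_meta, ab_model):
        cands = [
            make_cand("A", 1, 50, bitscore=3.0),
            make_cand("B", 200, 250, bitscore=2.0),
        ]
        assert is_trivial(cands, plain_meta, ab_model)
        bf = brute_force(cands, plain_meta, ab_model)
        assert objective(cands, plain_meta, ab_model) == pytest.approx(bf.objective)

    def test_conflicting_pair_not_trivial(self, make_cand, plain_meta, ab_model):
        cands = [
            make_cand("A", 1, 100, bitscore=3.0),
            make_cand("B", 10, 110, bitscore=2.0),
        ]
        assert not is_trivial(cands, plain_meta, ab_model)

    def test_negative_context_not_trivial(self, make_cand, plain_meta, ab_model):
        # B before A hits the unobserved-pair penalty
        cands = [
            make_cand("B", 1, 50, bitscore=3.0),
            make_cand("A", 200, 250, bitscore=2.0),
        ]
        assert not is_trivial(cands, plain_meta, ab_model)

    def test_single_survivor_trivial(self, make_cand, plain_meta, ab_model):
        assert is_trivial([make_cand("A", 1, 50, bitscore=3.0)], plain_meta, ab_model)

    def test_shared_context_pool_not_trivial(self, make_cand, make_meta_map):
        # Two negative-gain domains jointly propped up by one big shared pair
        # score: each survives elimination and every ordered pair score is
        # positive, yet including both is worse than dropping both. A trivial
        # test based on "no conflicts + no negative context" alone would
        # wrongly return the full set here; ours must decline.
        meta = make_meta_map({f: {"t_dom": 0.0} for f in "ABC"})
        model = estimate_scores(
            {("B", "C"): 500, ("A", "B"): 90, ("A", "C"): 90}, ["A", "B", "C"], alpha=1e-3
        )
        s = model.score("B", "C")
        assert model.score("A", "B") > 0 and model.score("A", "C") > 0
        cands = [
            make_cand("A", 1, 50, bitscore=1.0),
            make_cand("B", 200, 250, bitscore=-(s - 1.0)),
            make_cand("C", 400, 450, bitscore=-(s - 1.0)),
        ]
        surv = positive_elimination(cands, meta, model)
        assert len(surv) == 3  # nothing individually eliminable
        bf = brute_force(cands, meta, model)
        assert bf.objective > objective(surv, meta, model) + 0.1  # full set suboptimal
        assert not is_trivial(surv, meta, model)
        sol = predict(cands, meta, model)
        assert sol.objective == pytest.approx(bf.objective, abs=TOL)

    def test_trivial_soundness_random(self):
        fired = 0
        for seed in range(150):
            inst = generate_instance(
                InstanceParams(k=2 + seed % 7, conflict_rate=0.1, frac_negative_context=0.2),
                seed=seed,
            )
            surv = positive_elimination(inst.candidates, inst.meta, inst.model)
            if surv and is_trivial(surv, inst.meta, inst.model):
                fired += 1
                bf = brute_force(inst.candidates, inst.meta, inst.model)
                assert objective(surv, inst.meta, inst.model) == pytest.approx(
                    bf.objective, abs=TOL
                )
        assert fired > 0  # the shortcut must actually trigger sometimes


class TestBuildILP:
    def test_two_clean_candidates(self, make_cand, plain_meta, ab_model):
        cands = [
            make_cand("A", 1, 50, bitscore=3.0),
            make_cand("B", 200, 250, bitscore=2.0),
        ]
        inst = build_ilp(cands, plain_meta, ab_model)
        assert inst.n_variables == 3  # x_0, x_1, p_0_1
        c, A, lbs, ubs = inst.to_matrix()
        assert A.shape[0] == 3  # the three AND rows
        assert len(inst.cliques) == 0

    def test_conflicting_pair_constraint(self, make_cand, plain_meta, ab_model):
        cands = [
            make_cand("A", 1, 100, bitscore=3.0),
            make_cand("B", 10, 110, bitscore=2.0),
        ]
        inst = build_ilp(cands, plain_meta, ab_model)
        # no pair variable (they can never co-occur); one at-most-one clique
        assert inst.n_variables == 2
        assert inst.cliques == (frozenset({0, 1}),)
        c, A, lbs, ubs = inst.to_matrix()
        assert A.shape[0] == 1
        np.testing.assert_allclose(A[0], [1.0, 1.0])
        assert ubs[0] == 1.0

    def test_family_variable_constraints(self, make_cand, make_meta_map, zero_context_model):
        meta = make_meta_map({"A": {"t_dom": 10.0, "t_seq": 13.0}})
        model = zero_context_model(["A"])
        cands = [
            make_cand("A", 1, 50, bitscore=14.0),
            make_cand("A", 200, 250, bitscore=14.0),
        ]
        inst = build_ilp(cands, meta, model)
        assert inst.n_variables == 3  # x_0, x_1, f_A (no pair var: S(A,A)=0)
        assert inst.family_surplus == {"A": pytest.approx(3.0)}
        c, A, lbs, ubs = inst.to_matrix()
        assert A.shape[0] == 3  # x_F >= x_0, x_F >= x_1, x_F <= x_0 + x_1

    def test_zero_score_pairs_omitted(self, make_cand, plain_meta, zero_context_model):
        model = zero_context_model(["A", "B"])
        cands = [
            make_cand("A", 1, 50, bitscore=3.0),
            make_cand("B", 200, 250, bitscore=2.0),
        ]
        inst = build_ilp(cands, plain_meta, model)
        assert inst.n_variables == 2
        assert inst.pair_scores == {}

    def test_empty_survivors_error(self, plain_meta, ab_model):
        with pytest.raises(ValueError):
            build_ilp([], plain_meta, ab_model)


@pytest.mark.parametrize("backend", ["highs", "bnb"])
class TestSolveILP:
    def test_negative_pair_picks_single(self, make_cand, make_meta_map, backend):
        # gains 3 and 2, S = penalty ~ -6.97: take only the 3-bit domain
        meta = make_meta_map({"A": {"t_dom": 0.0}, "B": {"t_dom": 0.0}})
        model = estimate_scores({("B", "A"): 500}, ["A", "B"], alpha=1e-3)
        assert model.penalty < -6.0
        cands = [
            make_cand("A", 1, 50, bitscore=3.0),
            make_cand("B", 200, 250, bitscore=2.0),
        ]
        inst = build_ilp(cands, meta, model)
        selected, obj = solve_ilp(inst, backend=backend)
        assert selected == [0]
        assert obj == pytest.approx(3.0, abs=TOL)

    def test_positive_pair_takes_both(self, make_cand, plain_meta, backend):
        cands, model = _two_candidate_instance(make_cand, plain_meta, 1.0)
        inst = build_ilp(cands, plain_meta, model)
        selected, obj = solve_ilp(inst, backend=backend)
        assert selected == [0, 1]
        assert obj == pytest.approx(6.0, abs=TOL)

    def test_all_negative_yields_empty(self, make_cand, plain_meta, zero_context_model, backend):
        model = zero_context_model(["A", "B"])
        cands = [
            make_cand("A", 1, 50, bitscore=-3.0),
            make_cand("B", 200, 250, bitscore=-2.0),
        ]
        inst = build_ilp(cands, plain_meta, model)
        selected, obj = solve_ilp(inst, backend=backend)
        assert selected == []
        assert obj == pytest.approx(0.0, abs=TOL)

    def test_matches_objective_recomputation(self, backend):
        for seed in range(20):
            inst_data = generate_instance(
                InstanceParams(k=7, conflict_rate=0.4, frac_ttilde_positive=0.3), seed=seed
            )
            surv = positive_elimination(inst_data.candidates, inst_data.meta, inst_data.model)
            if not surv:
                continue
            ilp = build_ilp(surv, inst_data.meta, inst_data.model)
            selected, obj = solve_ilp(ilp, backend=backend)
            chosen = [ilp.candidates[i] for i in selected]
            assert obj == pytest.approx(
                objective(chosen, inst_data.meta, inst_data.model), abs=TOL
            )

    def test_unknown_backend(self, make_cand, plain_meta, ab_model, backend):
        inst = build_ilp([make_cand("A", 1, 50)], plain_meta, ab_model)
        with pytest.raises(ValueError, match="unknown backend"):
            solve_ilp(inst, backend="nope")


class TestBruteForce:
    def test_empty(self, make_meta_map, ab_model):
        sol = brute_force([], make_meta_map({}), ab_model)
        assert sol.selected == () and sol.objective == 0.0 and sol.status == "empty"

    def test_conflict_triangle(self, make_cand, make_meta_map, zero_context_model):
        meta = make_meta_map({f: {"t_dom": 0.0} for f in "ABC"})
        model = zero_context_model(["A", "B", "C"])
        cands = [
            make_cand("A", 1, 100, bitscore=3.0),
            make_cand("B", 10, 110, bitscore=2.0),
            make_cand("C", 20, 120, bitscore=1.0),
        ]
        sol = brute_force(cands, meta, model)
        assert [c.family_id for c in sol.selected] == ["A"]
        assert sol.objective == pytest.approx(3.0)

    def test_limit_enforced(self, make_cand, make_meta_map, zero_context_model):
        meta = make_meta_map({"A": {"t_dom": 0.0}})
        model = zero_context_model(["A"])
        cands = [make_cand("A", 1 + 300 * i, 100 + 300 * i) for i in range(21)]
        with pytest.raises(ValueError, match="limited"):
            brute_force(cands, meta, model)


class TestPredict:
    def test_empty_candidates(self, make_meta_map, ab_model):
        sol = predict([], make_meta_map({}), ab_model)
        assert sol.status == "empty" and sol.objective == 0.0

    def test_trivial_shortcut_skips_ilp(self, make_cand, plain_meta, ab_model):
        cands = [
            make_cand("A", 1, 50, bitscore=3.0),
            make_cand("B", 200, 250, bitscore=2.0),
        ]
        sol = predict(cands, plain_meta, ab_model)
        assert sol.status == "trivial"
        assert not sol.diagnostics["used_ilp"]

    @pytest.mark.parametrize("backend", ["highs", "bnb"])
    def test_oracle_equivalence(self, backend):
        for seed in range(80):
            k = 2 + seed % 11
            inst = generate_instance(
                InstanceParams(k=k, conflict_rate=0.35, frac_ttilde_positive=0.3),
                seed=1000 + seed,
            )
            sol = predict(inst.candidates, inst.meta, inst.model, backend=backend)
            bf = brute_force(inst.candidates, inst.meta, inst.model)
            assert sol.objective == pytest.approx(bf.objective, abs=TOL), seed

    def test_solution_invariants(self):
        for seed in range(40):
            inst = generate_instance(InstanceParams(k=8, conflict_rate=0.5), seed=seed)
            sol = predict(inst.candidates, inst.meta, inst.model)
            graph = build_conflict_graph(sol.selected, inst.meta)
            assert not graph.edges  # conflict-free
            assert sol.objective >= 0.0

    def test_cover_vs_single_edge_constraints(self):
        # any valid cover gives the same optimum as one constraint per edge
        for seed in range(30):
            inst = generate_instance(InstanceParams(k=8, conflict_rate=0.5), seed=seed)
            surv = positive_elimination(inst.candidates, inst.meta, inst.model)
            if len(surv) < 2:
                continue
            graph = build_conflict_graph(surv, inst.meta)
            if not graph.edges:
                continue
            edge_cliques = [frozenset(e) for e in sorted(graph.edges)]
            ilp_edges = build_ilp(surv, inst.meta, inst.model, cliques=edge_cliques)
            ilp_cover = build_ilp(
                surv, inst.meta, inst.model, cliques=greedy_clique_cover(graph)
            )
            _, obj_e = solve_ilp(ilp_edges)
            _, obj_c = solve_ilp(ilp_cover)
            assert obj_e == pytest.approx(obj_c, abs=TOL)

    def test_zero_context_limit_threshold_consistency(self, make_meta_map):
        # with all S = 0 and t_tilde = 0, every selected domain meets its own
        # threshold and every selected family its sequence threshold
        for seed in range(40):
            inst = generate_instance(
                InstanceParams(k=9, conflict_rate=0.4, frac_ttilde_positive=0.0),
                seed=seed,
            )
            model = estimate_scores({}, sorted(inst.meta), alpha=1e-3)
            sol = predict(inst.candidates, inst.meta, model)
            fam_sums = {}
            for c in sol.selected:
                assert c.bitscore >= inst.meta[c.family_id].t_dom - 1e-9
                fam_sums[c.family_id] = fam_sums.get(c.family_id, 0.0) + c.bitscore
            for fam, total in fam_sums.items():
                assert total >= inst.meta[fam].t_seq - 1e-9

    def test_negative_objective_never_returned(self, make_cand, make_meta_map, zero_context_model):
        meta = make_meta_map({"A": {"t_dom": 10.0}})
        model = zero_context_model(["A"])
        sol = predict([make_cand("A", 1, 50, bitscore=5.0)], meta, model)
        assert sol.status == "empty" and sol.objective == 0.0


class TestAndPolytope:
    """Geometry of the pair-variable linearisation."""

    @staticmethod
    def _tight_interval(xi, xj):
        lo = max(0.0, xi + xj - 1.0)
        hi = min(xi, xj, 1.0)
        return lo, hi

    @pytest.mark.parametrize("xi,xj", [(0, 0), (0, 1), (1, 0), (1, 1)])
    def test_three_constraints_force_and(self, xi, xj):
        lo, hi = self._tight_interval(xi, xj)
        assert lo == hi == (xi and xj)

    def test_weak_two_constraint_variant_admits_half_point(self):
        # x_ij >= x_i + x_j - 1 and 2 x_ij <= x_i + x_j
        xi = xj = xij = 0.5
        assert xij >= xi + xj - 1.0
        assert 2 * xij <= xi + xj
        # the tight system pins x_ij to a point only at integral (x_i, x_j);
        # the weak polytope has genuinely fractional vertices (below)

    @staticmethod
    def _vertices(constraints):
        """Vertices of {x : a.x <= b} in 3D by active-set enumeration."""
        verts = []
        for rows in itertools.combinations(constraints, 3):
            A = np.array([r[0] for r in rows], dtype=float)
            b = np.array([r[1] for r in rows], dtype=float)
            if abs(np.linalg.det(A)) < 1e-9:
                continue
            x = np.linalg.solve(A, b)
            if all(np.dot(a, x) <= bb + 1e-9 for a, bb in constraints):
                verts.append(tuple(np.round(x, 9)))
        return set(verts)

    @staticmethod
    def _box():
        cons = []
        for axis in range(3):
            e = [0.0, 0.0, 0.0]
            e[axis] = 1.0
            cons.append((tuple(e), 1.0))
            cons.append((tuple(-v for v in e), 0.0))
        return cons

    def test_tight_polytope_vertices_integral(self):
        # coords (x_i, x_j, x_ij)
        cons = self._box() + [
            ((-1.0, 0.0, 1.0), 0.0),   # x_ij <= x_i
            ((0.0, -1.0, 1.0), 0.0),   # x_ij <= x_j
            ((1.0, 1.0, -1.0), 1.0),   # x_i + x_j - x_ij <= 1
        ]
        verts = self._vertices(cons)
        assert verts  # non-degenerate polytope
        for v in verts:
            assert all(abs(c - round(c)) < 1e-9 for c in v), v
            xi, xj, xij = (round(c) for c in v)
            assert xij == (xi and xj)

    def test_weak_polytope_has_fractional_vertices(self):
        cons = self._box() + [
            ((1.0, 1.0, -1.0), 1.0),   # x_ij >= x_i + x_j - 1
            ((-1.0, -1.0, 2.0), 0.0),  # 2 x_ij <= x_i + x_j
        ]
        verts = self._vertices(cons)
        fractional = [v for v in verts if any(abs(c - round(c)) > 1e-9 for c in v)]
        assert fractional  # e.g. (1, 0, 0.5)
        assert (1.0, 0.0, 0.5) in verts


def test_solution_rejects_negative_objective():
    with pytest.raises(ValueError):
        Solution(selected=(), objective=-1.0, status="empty")
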