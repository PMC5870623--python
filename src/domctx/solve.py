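"""Exact maximisation of the context objective over conflict-free subsets.

Pipeline per protein: positive elimination prunes candidates that cannot
contribute positively even when granted every positive context score; a
sound trivial-solution test returns pruned sets that are provably optimal
as-is; everything else goes through a 0/1 integer linear program whose pair
variables are linearised with the tight three-constraint AND polytope and
whose conflicts enter as clique constraints.

Backends: "highs" (scipy.optimize.milp) and "bnb", a dependency-free
branch-and-bound over the candidate variables. A brute-force enumerator is
provided as an independent oracle for testing (k <= 20).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from domctx.conflicts import (
    DEFAULT_OVERLAP,
    ConflictGraph,
    OverlapConfig,
    build_conflict_graph,
    greedy_clique_cover,
)
from domctx.context import ContextModel
from domctx.io_formats import CandidateDomain, FamilyMeta
from domctx.scoring import objective, order_candidates

__all__ = [
    "SolverTimeout",
    "ILPInstance",
    "Solution",
    "positive_elimination",
    "is_trivial",
    "build_ilp",
    "solve_ilp",
    "brute_force",
    "predict",
]

BRUTE_FORCE_LIMIT = 20


class SolverTimeout(RuntimeError):
    """The MILP backend hit its time limit; carries the best dual bound."""

    def __init__(self, message: str, best_bound: float | None = None):
        super().__init__(message)
        self.best_bound = best_bound


@dataclass(frozen=True)
class Solution:
    """A conflict-free selection with its objective in bits.

    status: "optimal" (via ILP), "trivial" (shortcut, provably optimal) or
    "empty" (the null model won). The empty set always scores 0, so the
    objective is never negative.
    """

    selected: tuple[CandidateDomain, ...]
    objective: float
    status: str
    diagnostics: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.objective < -1e-9:
            raise ValueError(f"solution objective negative: {self.objective}")


def _prepare(
    candidates: Sequence[CandidateDomain],
    meta: Mapping[str, FamilyMeta],
    model: ContextModel,
    overlap: OverlapConfig,
) -> tuple[list[CandidateDomain], np.ndarray, np.ndarray, np.ndarray]:
    """Start-order candidates plus gains, directed S matrix and conflict matrix."""
    ordered = order_candidates(candidates)
    k = len(ordered)
    gains = np.array(
        [c.bitscore - meta[c.family_id].t_dom for c in ordered], dtype=float
    )
    smat = np.zeros((k, k), dtype=float)
    for i in range(k):
        for j in range(i + 1, k):
            smat[i, j] = model.score(ordered[i].family_id, ordered[j].family_id)
    graph = build_conflict_graph(ordered, meta, overlap)
    conf = np.zeros((k, k), dtype=bool)
    for u, v in graph.edges:
        conf[u, v] = conf[v, u] = True
    return ordered, gains, smat, conf


def positive_elimination(
    candidates: Sequence[CandidateDomain],
    meta: Mapping[str, FamilyMeta],
    model: ContextModel,
    overlap: OverlapConfig = DEFAULT_OVERLAP,
    stats: dict | None = None,
) -> list[CandidateDomain]:
    """Iteratively discard candidates that cannot help any solution.

    Each iteration evaluates every remaining candidate's optimistic score
    ``S+ = (H - t_dom) + sum of positive context with all remaining,
    non-conflicting partners`` (conflicting pairs contribute 0, since they
    can never co-occur). Candidates with ``S+ < 0`` are dropped — they would
    lower the objective of any subset containing them. Then each family
    whose surviving instances' summed ``S+`` falls below its sequence
    surplus ``t_tilde`` is dropped wholesale: even granted every positive
    context score those instances cannot pay the family's surplus. Repeats
    to fixpoint. One iteration is O(k^2).

    Every member of the true optimum survives; the brute-force optimum is
    unchanged (tested, not assumed).
    """
    ordered, gains, smat, conf = _prepare(candidates, meta, model, overlap)
    k = len(ordered)
    spos = np.where(conf, 0.0, np.maximum(smat, 0.0))
    alive = np.ones(k, dtype=bool)
    iterations = 0
    pair_evals = 0
    changed = True
    while changed:
        changed = False
        iterations += 1
        idx = np.flatnonzero(alive)
        pair_evals += len(idx) ** 2
        # S+ per remaining candidate: gain + positive context with remaining
        splus = gains[idx] + spos[np.ix_(idx, idx)].sum(axis=1) + spos[
            np.ix_(idx, idx)
        ].sum(axis=0)
        keep_dom = splus >= 0.0
        if not keep_dom.all():
            alive[idx[~keep_dom]] = False
            changed = True
        # family surplus test over the domain-level survivors of this pass
        surv_idx = idx[keep_dom]
        surv_splus = splus[keep_dom]
        fam_sums: dict[str, float] = {}
        for pos, i in enumerate(surv_idx):
            fam = ordered[i].family_id
            fam_sums[fam] = fam_sums.get(fam, 0.0) + surv_splus[pos]
        for fam, total in fam_sums.items():
            if total < meta[fam].t_tilde:
                for i in surv_idx:
                    if ordered[i].family_id == fam:
                        alive[i] = False
                changed = True
    if stats is not None:
        stats["iterations"] = iterations
        stats["pair_evals"] = pair_evals
    return [ordered[i] for i in np.flatnonzero(alive)]


def is_trivial(
    survivors: Sequence[CandidateDomain],
    meta: Mapping[str, FamilyMeta],
    model: ContextModel,
    overlap: OverlapConfig = DEFAULT_OVERLAP,
) -> bool:
    """Sufficient condition under which all survivors are jointly optimal.

    True iff the survivors have no conflicting pair, no negative context
    score between any ordered pair, every survivor meets its own domain
    threshold (``H >= t_dom``) and every family's summed threshold surplus
    covers its ``t_tilde``. Then every objective term of the full set is
    non-negative and removing any subset can only lose
    ``sum(gains) + touched pair scores - freed t_tilde <= 0``, so the full
    survivor set attains the optimum and the ILP can be skipped.

    Note this is deliberately stronger than "no conflicts and no negative
    context" alone: with negative individual gains, two candidates can share
    one positive pair score that neither earns jointly, making the full set
    suboptimal even though each looks locally justified. The extra
    per-candidate and per-family conditions close that gap (soundness is
    verified against the brute-force oracle, never assumed).
    """
    ordered, gains, smat, conf = _prepare(survivors, meta, model, overlap)
    k = len(ordered)
    if conf.any():
        return False
    for i in range(k):
        for j in range(i + 1, k):
            if smat[i, j] < 0.0:
                return False
    if (gains < 0.0).any():
        return False
    fam_gain: dict[str, float] = {}
    for i, c in enumerate(ordered):
        fam_gain[c.family_id] = fam_gain.get(c.family_id, 0.0) + gains[i]
    for fam, total in fam_gain.items():
        if total < meta[fam].t_tilde:
            return False
    return True


@dataclass(frozen=True)
class ILPInstance:
    """Structured 0/1 program for one protein's surviving candidates.

    Variables: one ``x_i`` per candidate (start order); one pair variable
    per ordered, non-conflicting pair with a nonzero context score; one
    family variable per family with a positive sequence surplus. Pair
    variables are tied to their endpoints with the three tight AND
    constraints, family variables with the two OR constraints, and each
    conflict clique contributes one at-most-one row.
    """

    candidates: tuple[CandidateDomain, ...]
    gains: tuple[float, ...]
    pair_scores: Mapping[tuple[int, int], float]  # (i, j) with i<j, S != 0
    family_surplus: Mapping[str, float]  # family -> t_tilde > 0
    family_instances: Mapping[str, tuple[int, ...]]
    cliques: tuple[frozenset[int], ...]

    @property
    def n_variables(self) -> int:
        return len(self.candidates) + len(self.pair_scores) + len(self.family_surplus)

    def variable_labels(self) -> list[str]:
        labels = [f"x_{i}" for i in range(len(self.candidates))]
        labels += [f"p_{i}_{j}" for (i, j) in sorted(self.pair_scores)]
        labels += [f"f_{fam}" for fam in sorted(self.family_surplus)]
        return labels

    def to_matrix(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Dense (c, A, lb, ub) with maximisation objective c; rows are the
        AND, OR and clique constraints with lb <= A @ x <= ub."""
        k = len(self.candidates)
        pairs = sorted(self.pair_scores)
        fams = sorted(self.family_surplus)
        pair_col = {p: k + t for t, p in enumerate(pairs)}
        fam_col = {f: k + len(pairs) + t for t, f in enumerate(fams)}
        nvar = self.n_variables

        c = np.zeros(nvar)
        c[:k] = self.gains
        for p in pairs:
            c[pair_col[p]] = self.pair_scores[p]
        for f in fams:
            c[fam_col[f]] = -self.family_surplus[f]

        rows: list[np.ndarray] = []
        lbs: list[float] = []
        ubs: list[float] = []

        def add(coeffs: dict[int, float], lb: float, ub: float) -> None:
            row = np.zeros(nvar)
            for col, val in coeffs.items():
                row[col] = val
            rows.append(row)
            lbs.append(lb)
            ubs.append(ub)

        for (i, j) in pairs:
            p = pair_col[(i, j)]
            add({p: 1.0, i: -1.0}, -np.inf, 0.0)  # x_ij <= x_i
            add({p: 1.0, j: -1.0}, -np.inf, 0.0)  # x_ij <= x_j
            add({p: 1.0, i: -1.0, j: -1.0}, -1.0, np.inf)  # x_ij >= x_i + x_j - 1
        for f in fams:
            fc = fam_col[f]
            inst = self.family_instances[f]
            for i in inst:
                add({fc: 1.0, i: -1.0}, 0.0, np.inf)  # x_F >= x_i
            add({fc: 1.0, **{i: -1.0 for i in inst}}, -np.inf, 0.0)  # x_F <= sum x_i
        for clique in self.cliques:
            add({i: 1.0 for i in clique}, -np.inf, 1.0)

        A = np.vstack(rows) if rows else np.zeros((0, nvar))
        return c, A, np.array(lbs), np.array(ubs)


def build_ilp(
    survivors: Sequence[CandidateDomain],
    meta: Mapping[str, FamilyMeta],
    model: ContextModel,
    cliques: Sequence[frozenset[int]] | None = None,
    overlap: OverlapConfig = DEFAULT_OVERLAP,
) -> ILPInstance:
    """Formulate the selection ILP over start-ordered survivors.

    ``cliques`` must cover every conflict edge (indices into the start-
    ordered survivor list); when omitted they are computed here with the
    greedy cover. Pair variables are created only for non-conflicting pairs
    with a nonzero score (conflicting pairs can never co-occur, zero scores
    contribute nothing); family variables only where ``t_tilde > 0``.
    """
    if not survivors:
        raise ValueError("survivors must be nonempty")
    ordered, gains, smat, conf = _prepare(survivors, meta, model, overlap)
    k = len(ordered)
    if cliques is None:
        graph = build_conflict_graph(ordered, meta, overlap)
        cliques = greedy_clique_cover(graph)
    pair_scores = {
        (i, j): smat[i, j]
        for i in range(k)
        for j in range(i + 1, k)
        if smat[i, j] != 0.0 and not conf[i, j]
    }
    family_surplus: dict[str, float] = {}
    family_instances: dict[str, list[int]] = {}
    for i, cand in enumerate(ordered):
        fam = meta[cand.family_id]
        if fam.t_tilde > 0:
            family_surplus[fam.family_id] = fam.t_tilde
            family_instances.setdefault(fam.family_id, []).append(i)
    return ILPInstance(
        candidates=tuple(ordered),
        gains=tuple(gains),
        pair_scores=pair_scores,
        family_surplus=family_surplus,
        family_instances={f: tuple(v) for f, v in family_instances.items()},
        cliques=tuple(cliques),
    )


def _solve_highs(instance: ILPInstance, timeout: float | None) -> tuple[list[int], float]:
    from scipy.optimize import Bounds, LinearConstraint, milp

    c, A, lbs, ubs = instance.to_matrix()
    nvar = instance.n_variables
    options = {}
    if timeout is not None:
        options["time_limit"] = float(timeout)
    constraints = [LinearConstraint(A, lbs, ubs)] if A.shape[0] else []
    res = milp(
        c=-c,  # milp minimises
        constraints=constraints,
        integrality=np.ones(nvar),
        bounds=Bounds(0.0, 1.0),
        options=options,
    )
    if res.status == 1:
        bound = -res.mip_dual_bound if res.mip_dual_bound is not None else None
        raise SolverTimeout("MILP time limit reached", best_bound=bound)
    if res.status != 0 or res.x is None:
        raise RuntimeError(f"MILP solver failed: {res.message}")
    selected = [i for i in range(len(instance.candidates)) if res.x[i] > 0.5]
    return selected, float(-res.fun)


def _solve_bnb(instance: ILPInstance, timeout: float | None) -> tuple[list[int], float]:
    """Dependency-free exact branch-and-bound over the candidate variables.

    Pair and family variables are implied by the candidate choice (pair
    variables equal the AND of their endpoints at any optimum, family
    variables the OR of their instances), so only x_i is branched on.
    The bound grants each undecided candidate its gain plus every positive
    pair score with any non-conflicting partner — an overestimate, hence
    admissible.
    """
    k = len(instance.candidates)
    gains = np.array(instance.gains)
    smat = np.zeros((k, k))
    for (i, j), s in instance.pair_scores.items():
        smat[i, j] = s
    conf = np.zeros((k, k), dtype=bool)
    for clique in instance.cliques:
        for u, v in itertools.combinations(sorted(clique), 2):
            conf[u, v] = conf[v, u] = True
    spos = np.maximum(smat, 0.0)
    opt = gains + spos.sum(axis=0) + spos.sum(axis=1)  # per-candidate optimistic add
    fam_of = {}
    for f, inst in instance.family_instances.items():
        for i in inst:
            fam_of[i] = f

    best_val = 0.0
    best_set: list[int] = []

    def value(chosen: list[int]) -> float:
        v = gains[chosen].sum()
        for a, b in itertools.combinations(chosen, 2):
            v += smat[a, b] if a < b else smat[b, a]
        fams = {fam_of[i] for i in chosen if i in fam_of}
        v -= sum(instance.family_surplus[f] for f in fams)
        return float(v)

    # order by optimistic contribution so good solutions surface early
    order = sorted(range(k), key=lambda i: -opt[i])
    suffix_opt = np.zeros(k + 1)
    for t in range(k - 1, -1, -1):
        suffix_opt[t] = suffix_opt[t + 1] + max(0.0, opt[order[t]])

    def dfs(t: int, chosen: list[int], val: float) -> None:
        nonlocal best_val, best_set
        if val > best_val + 1e-12:
            best_val = val
            best_set = list(chosen)
        if t == k or val + suffix_opt[t] <= best_val + 1e-12:
            return
        i = order[t]
        if not any(conf[min(i, c), max(i, c)] for c in chosen):
            delta = gains[i] + sum(
                smat[min(i, c), max(i, c)] for c in chosen
            )
            f = fam_of.get(i)
            if f is not None and not any(fam_of.get(c) == f for c in chosen):
                delta -= instance.family_surplus[f]
            chosen.append(i)
            dfs(t + 1, chosen, val + float(delta))
            chosen.pop()
        dfs(t + 1, chosen, val)

    dfs(0, [], 0.0)
    return sorted(best_set), value(best_set) if best_set else 0.0


def solve_ilp(
    instance: ILPInstance,
    backend: str = "highs",
    timeout: float | None = None,
) -> tuple[list[int], float]:
    """Solve to proven optimality; returns (selected indices, objective).

    The all-zero assignment is feasible, so the optimum is never below 0 —
    when nothing scores positively the empty selection comes back.
    """
    if backend == "highs":
        return _solve_highs(instance, timeout)
    if backend == "bnb":
        return _solve_bnb(instance, timeout)
    raise ValueError(f"unknown backend {backend!r} (expected 'highs' or 'bnb')")


def brute_force(
    candidates: Sequence[CandidateDomain],
    meta: Mapping[str, FamilyMeta],
    model: ContextModel,
    overlap: OverlapConfig = DEFAULT_OVERLAP,
    limit: int = BRUTE_FORCE_LIMIT,
) -> Solution:
    """Independent oracle: enumerate all conflict-free subsets (k <= limit).

    Ties are broken toward fewer domains, then the lexicographically
    smallest index set (deterministic). The winning subset's objective is
    recomputed through :func:`domctx.scoring.objective`.
    """
    k = len(candidates)
    if k > limit:
        raise ValueError(f"brute force limited to {limit} candidates, got {k}")
    if k == 0:
        return Solution(selected=(), objective=0.0, status="empty")
    ordered, gains, smat, conf = _prepare(candidates, meta, model, overlap)

    n_masks = 1 << k
    masks = np.arange(n_masks, dtype=np.uint32)
    bits = ((masks[:, None] >> np.arange(k, dtype=np.uint32)) & 1).astype(float)
    values = bits @ gains
    for i in range(k):
        for j in range(i + 1, k):
            if smat[i, j] != 0.0:
                values += smat[i, j] * bits[:, i] * bits[:, j]
    fam_instances: dict[str, list[int]] = {}
    for i, c in enumerate(ordered):
        if meta[c.family_id].t_tilde > 0:
            fam_instances.setdefault(c.family_id, []).append(i)
    for fam, inst in fam_instances.items():
        present = bits[:, inst].max(axis=1)
        values -= meta[fam].t_tilde * present
    feasible = np.ones(n_masks, dtype=bool)
    for i in range(k):
        for j in range(i + 1, k):
            if conf[i, j]:
                feasible &= ~((bits[:, i] > 0) & (bits[:, j] > 0))
    values = np.where(feasible, values, -np.inf)

    vmax = values.max()
    if vmax < 0.0:
        return Solution(selected=(), objective=0.0, status="empty")
    tied = np.flatnonzero(values == vmax)
    def mask_key(m: int) -> tuple:
        members = tuple(i for i in range(k) if m >> i & 1)
        return (len(members), members)
    best_mask = min((int(m) for m in tied), key=mask_key)
    selected = tuple(ordered[i] for i in range(k) if best_mask >> i & 1)
    obj = objective(selected, meta, model, overlap)
    status = "empty" if not selected else "optimal"
    return Solution(selected=selected, objective=max(obj, 0.0), status=status)


def predict(
    candidates: Sequence[CandidateDomain],
    meta: Mapping[str, FamilyMeta],
    model: ContextModel,
    overlap: OverlapConfig = DEFAULT_OVERLAP,
    backend: str = "highs",
    timeout: float | None = None,
) -> Solution:
    """Full per-protein pipeline: positive elimination, trivial check, ILP."""
    if not candidates:
        return Solution(selected=(), objective=0.0, status="empty")
    pe_stats: dict = {}
    survivors = positive_elimination(candidates, meta, model, overlap, stats=pe_stats)
    diagnostics = {
        "n_input": len(candidates),
        "n_survivors": len(survivors),
        "pe_iterations": pe_stats.get("iterations", 0),
        "used_ilp": False,
    }
    if not survivors:
        return Solution(selected=(), objective=0.0, status="empty", diagnostics=diagnostics)
    if is_trivial(survivors, meta, model, overlap):
        obj = objective(survivors, meta, model, overlap)
        return Solution(
            selected=tuple(order_candidates(survivors)),
            objective=obj,
            status="trivial",
            diagnostics=diagnostics,
        )
    instance = build_ilp(survivors, meta, model, overlap=overlap)
    diagnostics["used_ilp"] = True
    diagnostics["n_variables"] = instance.n_variables
    diagnostics["n_cliques"] = len(instance.cliques)
    selected_idx, _ilp_obj = solve_ilp(instance, backend=backend, timeout=timeout)
    selected = tuple(instance.candidates[i] for i in selected_idx)
    obj = objective(selected, meta, model, overlap) if selected else 0.0
    if obj < 0.0:
        selected, obj = (), 0.0
    status = "empty" if not selected else "optimal"
    return Solution(selected=selected, objective=obj, status=status, diagnostics=diagnostics)
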