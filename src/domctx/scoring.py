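"""Objective functions over candidate subsets, plus the curated-threshold baseline.

The main objective, for a subset ordered by start coordinate, is

    sum_i (H_i - t_dom_i)  +  sum_{i<j} S(F_i, F_j)  -  sum_{F present} t_tilde_F

where H_i is the candidate's bit score, S the directional context score of
the earlier family preceding the later one, and the family surplus term is
charged once per distinct predicted family. Every ordered pair contributes
— not just adjacent ones — which is what distinguishes this objective from
a first-order Markov chain over domain order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from domctx.conflicts import DEFAULT_OVERLAP, OverlapConfig, in_conflict, overlap_length
from domctx.context import ContextModel
from domctx.io_formats import CandidateDomain, FamilyMeta

__all__ = [
    "ScoredSubset",
    "order_candidates",
    "objective",
    "score_breakdown",
    "markov_score",
    "standard_pfam_filter",
]


def order_candidates(subset: Sequence[CandidateDomain]) -> list[CandidateDomain]:
    """Start-coordinate order; ties broken by end then family id (deterministic)."""
    return sorted(subset, key=CandidateDomain.sort_key)


def _gain(c: CandidateDomain, meta: Mapping[str, FamilyMeta]) -> float:
    fam = meta.get(c.family_id)
    if fam is None:
        raise KeyError(f"no metadata for family {c.family_id!r}")
    return c.bitscore - fam.t_dom


def _check_no_conflicts(
    ordered: Sequence[CandidateDomain],
    meta: Mapping[str, FamilyMeta],
    overlap: OverlapConfig,
) -> None:
    for i in range(len(ordered)):
        for j in range(i + 1, len(ordered)):
            if in_conflict(ordered[i], ordered[j], meta, overlap):
                raise ValueError(
                    f"conflicting pair in subset: {ordered[i].family_id} "
                    f"[{ordered[i].ali_start}-{ordered[i].ali_end}] vs "
                    f"{ordered[j].family_id} "
                    f"[{ordered[j].ali_start}-{ordered[j].ali_end}]"
                )


@dataclass(frozen=True)
class ScoredSubset:
    """A conflict-free subset with its objective and per-term breakdown.

    The objective equals the sum of all breakdown terms. Domain terms are
    ``(candidate, H - t_dom)``; pair terms ``((i, j), S)`` over ordered index
    pairs in start order; family terms ``(family_id, -t_tilde)`` for each
    distinct family present with a positive surplus.
    """

    members: tuple[CandidateDomain, ...]
    objective: float
    domain_terms: tuple[tuple[CandidateDomain, float], ...]
    pair_terms: tuple[tuple[tuple[int, int], float], ...]
    family_terms: tuple[tuple[str, float], ...]


def score_breakdown(
    subset: Sequence[CandidateDomain],
    meta: Mapping[str, FamilyMeta],
    model: ContextModel,
    overlap: OverlapConfig = DEFAULT_OVERLAP,
) -> ScoredSubset:
    """Score a subset and keep the individual terms (see :class:`ScoredSubset`).

    Raises ``ValueError`` if the subset contains a conflicting pair; callers
    must pre-filter.
    """
    ordered = order_candidates(subset)
    _check_no_conflicts(ordered, meta, overlap)

    domain_terms = tuple((c, _gain(c, meta)) for c in ordered)
    pair_terms = tuple(
        ((i, j), model.score(ordered[i].family_id, ordered[j].family_id))
        for i in range(len(ordered))
        for j in range(i + 1, len(ordered))
    )
    families = sorted({c.family_id for c in ordered})
    family_terms = tuple(
        (f, -meta[f].t_tilde) for f in families if meta[f].t_tilde > 0
    )
    total = (
        sum(t for _, t in domain_terms)
        + sum(t for _, t in pair_terms)
        + sum(t for _, t in family_terms)
    )
    return ScoredSubset(
        members=tuple(ordered),
        objective=total,
        domain_terms=domain_terms,
        pair_terms=pair_terms,
        family_terms=family_terms,
    )


def objective(
    subset: Sequence[CandidateDomain],
    meta: Mapping[str, FamilyMeta],
    model: ContextModel,
    overlap: OverlapConfig = DEFAULT_OVERLAP,
) -> float:
    """Total score in bits of a conflict-free subset; empty subset scores 0."""
    if not subset:
        return 0.0
    return score_breakdown(subset, meta, model, overlap).objective


def markov_score(
    subset: Sequence[CandidateDomain],
    meta: Mapping[str, FamilyMeta],
    model: ContextModel,
    overlap: OverlapConfig = DEFAULT_OVERLAP,
) -> float:
    """First-order Markov variant: only consecutive pairs carry context.

    The score is ``sum_i (H_i - t_dom_i + S(F_{i-1}, F_i))`` with the first
    domain's incoming term set to 0, minus the same family surplus terms as
    :func:`objective`. The two scores agree for subsets of size <= 2 and
    differ by exactly the sum of non-adjacent pair scores in general.
    """
    if not subset:
        return 0.0
    ordered = order_candidates(subset)
    _check_no_conflicts(ordered, meta, overlap)
    # term grouping mirrors score_breakdown so that the two scores are
    # bit-identical (not merely close) whenever the pair terms coincide
    dom = sum(_gain(c, meta) for c in ordered)
    pair = sum(
        model.score(prev.family_id, cur.family_id)
        for prev, cur in zip(ordered, ordered[1:])
    )
    families = sorted({c.family_id for c in ordered})
    fam = sum(-meta[f].t_tilde for f in families if meta[f].t_tilde > 0)
    return dom + pair + fam


def standard_pfam_filter(
    candidates: Sequence[CandidateDomain],
    meta: Mapping[str, FamilyMeta],
    coords: str = "ali",
) -> list[CandidateDomain]:
    """Curated-threshold baseline selection for one protein.

    1. Keep candidates meeting their family's per-domain threshold
       (``H >= t_dom``).
    2. Enforce the per-family sequence threshold: drop every instance of a
       family whose summed kept bit scores fall below ``t_seq``.
    3. Resolve strict overlaps (>= 1 shared residue, ``coords`` spans)
       between members of the same clan greedily by ascending P-value:
       the most significant survivor wins, losers are removed immediately.

    There is no cross-clan removal and no context here.
    """
    kept = []
    for c in candidates:
        fam = meta.get(c.family_id)
        if fam is None:
            continue
        if c.bitscore >= fam.t_dom:
            kept.append(c)

    sums: dict[str, float] = {}
    for c in kept:
        sums[c.family_id] = sums.get(c.family_id, 0.0) + c.bitscore
    kept = [c for c in kept if sums[c.family_id] >= meta[c.family_id].t_seq]

    # greedy clan resolution, most significant first
    by_sig = sorted(kept, key=lambda c: (c.pvalue, -c.bitscore) + c.sort_key())
    winners: list[CandidateDomain] = []
    for c in by_sig:
        clan = meta[c.family_id].clan_id
        clashes = False
        if clan:
            for w in winners:
                if (
                    meta[w.family_id].clan_id == clan
                    and w.protein_id == c.protein_id
                    and overlap_length(c, w, coords) >= 1
                ):
                    clashes = True
                    break
        if not clashes:
            winners.append(c)
    return order_candidates(winners)
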