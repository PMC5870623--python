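"""Spatial conflicts between candidate domains and clique covers for the ILP."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from domctx.io_formats import CandidateDomain, FamilyMeta

__all__ = [
    "OverlapConfig",
    "ConflictGraph",
    "overlap_length",
    "permissive_overlap",
    "in_conflict",
    "build_conflict_graph",
    "greedy_clique_cover",
]


@dataclass(frozen=True)
class OverlapConfig:
    """Permissive-overlap parameters.

    Two candidates conflict when they overlap by more than ``max_aa``
    residues or by more than ``max_frac`` of the shorter of the two ranges.
    ``coords`` selects which coordinate pair defines a candidate's extent:
    the HMMER envelope ("env", default — the region HMMER calls homologous)
    or the alignment ("ali").
    """

    max_aa: int = 40
    max_frac: float = 0.5
    coords: str = "env"

    def __post_init__(self) -> None:
        if self.coords not in ("ali", "env"):
            raise ValueError(f"coords must be 'ali' or 'env', got {self.coords!r}")
        if self.max_aa < 0 or not (0 <= self.max_frac <= 1):
            raise ValueError("overlap thresholds must be non-negative")


DEFAULT_OVERLAP = OverlapConfig()


def _span(d: CandidateDomain, coords: str) -> tuple[int, int]:
    if coords == "ali":
        return d.ali_start, d.ali_end
    return d.env_start, d.env_end


def overlap_length(d1: CandidateDomain, d2: CandidateDomain, coords: str = "env") -> int:
    """Shared residue count between two candidates (1-based inclusive spans)."""
    s1, e1 = _span(d1, coords)
    s2, e2 = _span(d2, coords)
    return max(0, min(e1, e2) - max(s1, s2) + 1)


def permissive_overlap(
    d1: CandidateDomain,
    d2: CandidateDomain,
    max_aa: int = 40,
    max_frac: float = 0.5,
    coords: str = "env",
) -> bool:
    """True iff the overlap exceeds ``max_aa`` residues or ``max_frac`` of the
    shorter range. Candidates on different proteins never overlap."""
    if d1.protein_id != d2.protein_id:
        return False
    olen = overlap_length(d1, d2, coords)
    if olen > max_aa:
        return True
    s1, e1 = _span(d1, coords)
    s2, e2 = _span(d2, coords)
    shorter = min(e1 - s1 + 1, e2 - s2 + 1)
    return olen > max_frac * shorter


def _nested_whitelisted(
    fam_a: str, fam_b: str, meta: Mapping[str, FamilyMeta]
) -> bool:
    # whitelist is symmetric: either side listing the other suffices
    ma = meta.get(fam_a)
    mb = meta.get(fam_b)
    if ma is not None and fam_b in ma.nesting_partners:
        return True
    if mb is not None and fam_a in mb.nesting_partners:
        return True
    return False


def in_conflict(
    d1: CandidateDomain,
    d2: CandidateDomain,
    meta: Mapping[str, FamilyMeta],
    overlap: OverlapConfig = DEFAULT_OVERLAP,
) -> bool:
    """True iff the pair permissively overlaps and is not nesting-whitelisted.

    Same-family and same-clan pairs get no special treatment here: conflict
    is purely spatial, softened only by the curated nesting whitelist.
    (Clan-based exclusion belongs to the curated-threshold baseline in the
    scoring module, not to the context method itself.)
    """
    if not permissive_overlap(
        d1, d2, max_aa=overlap.max_aa, max_frac=overlap.max_frac, coords=overlap.coords
    ):
        return False
    return not _nested_whitelisted(d1.family_id, d2.family_id, meta)


@dataclass(frozen=True)
class ConflictGraph:
    """Undirected conflict graph over candidate indices 0..n_nodes-1."""

    n_nodes: int
    edges: frozenset[tuple[int, int]]  # each edge stored as (lo, hi)

    def __post_init__(self) -> None:
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-edge at node {u}")
            if not (0 <= u < v < self.n_nodes):
                raise ValueError(f"edge ({u}, {v}) out of range or unordered")

    def has_edge(self, u: int, v: int) -> bool:
        if u > v:
            u, v = v, u
        return (u, v) in self.edges

    def neighbors(self, u: int) -> set[int]:
        out = set()
        for a, b in self.edges:
            if a == u:
                out.add(b)
            elif b == u:
                out.add(a)
        return out


def build_conflict_graph(
    candidates: Sequence[CandidateDomain],
    meta: Mapping[str, FamilyMeta],
    overlap: OverlapConfig = DEFAULT_OVERLAP,
) -> ConflictGraph:
    """Pairwise conflict test over one protein's candidates (O(k^2))."""
    edges = set()
    for i in range(len(candidates)):
        for j in range(i + 1, len(candidates)):
            if in_conflict(candidates[i], candidates[j], meta, overlap):
                edges.add((i, j))
    return ConflictGraph(n_nodes=len(candidates), edges=frozenset(edges))


def greedy_clique_cover(graph: ConflictGraph) -> list[frozenset[int]]:
    """Cover every conflict edge with maximal-ish cliques, deterministically.

    Iterates edges in lexicographic order; each still-uncovered edge seeds a
    clique that greedily absorbs the lowest-index node adjacent to all
    current members. Returned cliques may overlap but none is a subset of
    another; every edge of the graph lies inside at least one clique. An
    edgeless graph yields an empty list. (Minimum clique cover is NP-hard;
    covers affect ILP size, never correctness.)
    """
    adj: dict[int, set[int]] = {u: set() for u in range(graph.n_nodes)}
    for u, v in graph.edges:
        adj[u].add(v)
        adj[v].add(u)

    covered: set[tuple[int, int]] = set()
    cliques: list[frozenset[int]] = []
    for u, v in sorted(graph.edges):
        if (u, v) in covered:
            continue
        clique = {u, v}
        candidates = (adj[u] & adj[v]) - clique
        while candidates:
            w = min(candidates)
            clique.add(w)
            candidates = (candidates & adj[w]) - clique
        members = sorted(clique)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                covered.add((members[i], members[j]))
        cliques.append(frozenset(clique))

    # drop nested cliques (a later, larger seed can swallow an earlier one)
    keep: list[frozenset[int]] = []
    for c in cliques:
        if not any(c < other for other in cliques if other is not c):
            keep.append(c)
    # deduplicate identical cliques while preserving order
    seen: set[frozenset[int]] = set()
    out = []
    for c in keep:
        if c not in seen:
            seen.add(c)
            out.append(c)
    return out
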