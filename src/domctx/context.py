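"""Directional family-pair context model.

Counts how often a domain instance of one family occurs before an instance
of another family within the same protein, and converts those counts into
directional log2-odds scores with symmetric-Dirichlet smoothing. Scores are
computed lazily from the sparse count map; the family universe can exceed
10^4 entries without materialising an n x n matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "DEFAULT_ALPHA",
    "ContextModel",
    "build_context_counts",
    "estimate_scores",
    "pair_score",
    "symmetrize_counts",
]

DEFAULT_ALPHA = 1e-3


@dataclass(frozen=True)
class ContextModel:
    """Smoothed directional pair-probability model over a family universe.

    With counts ``c[i,j]``, total ``C`` and ``n`` families, the smoothed pair
    probability is ``(c[i,j] + alpha) / (C + alpha * n**2)`` over all ``n**2``
    ordered pairs (self-pairs included), each family has prior ``1/n``, and
    the pair score is ``log2(p_hat[i,j] / (p_hat[i] * p_hat[j]))``. Every
    unobserved ordered pair shares the fixed ``penalty``
    ``log2(alpha * n**2 / (C + alpha * n**2))``, negative whenever ``C > 0``.
    """

    families: frozenset[str]
    alpha: float
    counts: Mapping[tuple[str, str], int]
    C: int = field(init=False, default=0)
    penalty: float = field(init=False, default=0.0)

    def __post_init__(self) -> None:
        if not self.families:
            raise ValueError("family universe is empty")
        if self.alpha <= 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        for (fam_i, fam_j), count in self.counts.items():
            if fam_i not in self.families or fam_j not in self.families:
                raise ValueError(
                    f"count pair ({fam_i}, {fam_j}) outside the family universe"
                )
            if count < 2:
                raise ValueError(
                    f"count for ({fam_i}, {fam_j}) is {count}; counts of 1 must be "
                    "pruned at load time and counts must be positive"
                )
        total = sum(self.counts.values())
        an2 = self.alpha * self.n**2
        object.__setattr__(self, "C", total)
        object.__setattr__(self, "penalty", math.log2(an2 / (total + an2)))

    @property
    def n(self) -> int:
        return len(self.families)

    def pair_probability(self, fam_i: str, fam_j: str) -> float:
        self._check(fam_i)
        self._check(fam_j)
        c = self.counts.get((fam_i, fam_j), 0)
        return (c + self.alpha) / (self.C + self.alpha * self.n**2)

    def score(self, fam_i: str, fam_j: str) -> float:
        """Directional context score in bits for fam_i occurring before fam_j."""
        self._check(fam_i)
        self._check(fam_j)
        c = self.counts.get((fam_i, fam_j), 0)
        if c == 0:
            return self.penalty
        # log2(p_hat / (1/n^2)) since both family priors are 1/n
        return math.log2((c + self.alpha) * self.n**2 / (self.C + self.alpha * self.n**2))

    def _check(self, family_id: str) -> None:
        if family_id not in self.families:
            raise KeyError(f"unknown family {family_id!r}")


def build_context_counts(
    architectures: Iterable[tuple[str, Sequence[str]]],
) -> dict[tuple[str, str], int]:
    """Count ordered family pairs over per-protein domain architectures.

    Each architecture is the protein's domain instances ordered by start
    coordinate. Every ordered instance pair within one protein increments
    the directed count of its family pair; self-pairs count repeats.
    No pairs are formed across proteins.
    """
    counts: dict[tuple[str, str], int] = {}
    for _protein_id, fams in architectures:
        for p in range(len(fams)):
            for q in range(p + 1, len(fams)):
                key = (fams[p], fams[q])
                counts[key] = counts.get(key, 0) + 1
    return counts


def build_binary_context_counts(
    architectures: Iterable[tuple[str, Sequence[str]]],
) -> dict[tuple[str, str], int]:
    """Per-protein binarized variant: each ordered family pair counts at most
    once per protein, regardless of how many instance pairs realise it."""
    counts: dict[tuple[str, str], int] = {}
    for _protein_id, fams in architectures:
        seen: set[tuple[str, str]] = set()
        for p in range(len(fams)):
            for q in range(p + 1, len(fams)):
                seen.add((fams[p], fams[q]))
        for key in seen:
            counts[key] = counts.get(key, 0) + 1
    return counts


def estimate_scores(
    counts: Mapping[tuple[str, str], int],
    families: Iterable[str],
    alpha: float = DEFAULT_ALPHA,
) -> ContextModel:
    """Build a :class:`ContextModel` over an explicit family universe.

    The universe is supplied explicitly (normally every family in the
    metadata table, not just those appearing in counts): the unobserved-pair
    penalty depends on the full n^2 ordered-pair space, so inferring n from
    the counts file would inflate scores. Counts must already be pruned of
    singletons. A count family outside the universe is an error.
    """
    return ContextModel(families=frozenset(families), alpha=alpha, counts=dict(counts))


def pair_score(model: ContextModel, fam_i: str, fam_j: str) -> float:
    """Directional score in bits; the shared penalty for unobserved pairs."""
    return model.score(fam_i, fam_j)


def symmetrize_counts(
    counts: Mapping[tuple[str, str], int],
) -> dict[tuple[str, str], int]:
    """Order-blind ablation: replace c[i,j] and c[j,i] by their sum.

    Approximates an undirected context model for comparison runs; this is a
    labeled approximation, not a reimplementation of any earlier estimator.
    """
    out: dict[tuple[str, str], int] = {}
    for (fam_i, fam_j), count in counts.items():
        out[(fam_i, fam_j)] = out.get((fam_i, fam_j), 0) + count
        if fam_i != fam_j:
            out[(fam_j, fam_i)] = out.get((fam_j, fam_i), 0) + count
    return out
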