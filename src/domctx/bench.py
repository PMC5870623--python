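"""Evaluation statistics and the synthetic-instance generator.

The FDR estimator macro-averages per-protein false-positive fractions over
proteins that received at least one prediction. Decoy labeling follows the
reversed-sequence scheme: predictions on real sequences are true positives,
predictions on reversed sequences are false positives unless they overlap a
real prediction of the same family (palindromic profile signatures), in
which case they are removed; the resulting estimate is doubled.

The generator builds self-contained instances — candidates with
controllable overlap structure, family thresholds bracketing the bit
scores, and a random directed context network — so the whole pipeline is
testable from a seed with no external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from domctx.context import DEFAULT_ALPHA, ContextModel, estimate_scores
from domctx.io_formats import CandidateDomain, FamilyMeta
from domctx.conflicts import overlap_length

__all__ = [
    "LabeledPrediction",
    "InstanceParams",
    "SyntheticInstance",
    "fdr_estimate",
    "revseq_label",
    "generate_instance",
]

REVSEQ_DOUBLING = 2.0


@dataclass(frozen=True)
class LabeledPrediction:
    """One predicted domain with its benchmark label."""

    protein_id: str
    label: str  # "TP" | "FP"
    candidate: CandidateDomain | None = None

    def __post_init__(self) -> None:
        if self.label not in ("TP", "FP"):
            raise ValueError(f"label must be 'TP' or 'FP', got {self.label!r}")


def fdr_estimate(labeled: Sequence[LabeledPrediction]) -> float:
    """Macro-averaged per-protein FP fraction.

    ``mean over proteins with >= 1 prediction of FP / (TP + FP)``. Proteins
    absent from ``labeled`` have no predictions and are excluded from the
    average; an empty input is an error (the estimate is undefined).
    """
    per_protein: dict[str, list[int]] = {}
    for item in labeled:
        tp_fp = per_protein.setdefault(item.protein_id, [0, 0])
        tp_fp[0 if item.label == "TP" else 1] += 1
    if not per_protein:
        raise ValueError("FDR undefined: no protein has predictions")
    fractions = [fp / (tp + fp) for tp, fp in per_protein.values()]
    return float(np.mean(fractions))


def revseq_label(
    real_preds: Sequence[CandidateDomain],
    reversed_preds: Sequence[CandidateDomain],
    min_overlap: int = 1,
    coords: str = "ali",
) -> tuple[list[LabeledPrediction], float]:
    """Label pooled real/decoy predictions; returns (labels, doubling factor).

    Reversed-sequence coordinates must already be mapped back to the forward
    frame by the caller. A reversed prediction overlapping a same-family,
    same-protein real prediction by at least ``min_overlap`` residues is
    removed rather than counted (palindromic signatures); the reported FDR
    is ``doubling factor x fdr_estimate`` of the returned labels. The
    removal threshold defaults to a single shared residue and is
    configurable.
    """
    labeled = [
        LabeledPrediction(protein_id=p.protein_id, label="TP", candidate=p)
        for p in real_preds
    ]
    for r in reversed_preds:
        palindromic = any(
            p.protein_id == r.protein_id
            and p.family_id == r.family_id
            and overlap_length(p, r, coords) >= min_overlap
            for p in real_preds
        )
        if palindromic:
            continue
        labeled.append(LabeledPrediction(protein_id=r.protein_id, label="FP", candidate=r))
    return labeled, REVSEQ_DOUBLING


@dataclass(frozen=True)
class InstanceParams:
    """Knobs for :func:`generate_instance`.

    ``conflict_rate`` is the probability that a candidate is placed to
    overlap a previous one by >40 residues (forcing a conflict);
    ``frac_negative_context`` the fraction of ordered family pairs left
    unobserved (they share the negative penalty);
    ``frac_ttilde_positive`` the fraction of families given a sequence
    threshold strictly above the domain threshold. Bit scores are drawn
    around the family thresholds so that roughly half the candidates fail
    ``H >= t_dom`` when ``score_mean`` is 0 — the regime where context
    matters and every solver branch is exercised.
    """

    k: int = 8
    n_families: int = 6
    protein_length: int = 2500
    conflict_rate: float = 0.3
    score_mean: float = 0.0
    score_sd: float = 6.0
    frac_negative_context: float = 0.5
    frac_ttilde_positive: float = 0.25
    alpha: float = DEFAULT_ALPHA
    clan_rate: float = 0.3
    min_len: int = 50
    max_len: int = 120

    def __post_init__(self) -> None:
        if self.k < 0 or self.n_families < 1 or self.protein_length < self.max_len:
            raise ValueError("invalid instance parameters")
        if not (0 <= self.conflict_rate <= 1):
            raise ValueError("conflict_rate must be in [0, 1]")
        if not (0 <= self.frac_negative_context <= 1):
            raise ValueError("frac_negative_context must be in [0, 1]")
        if not (0 <= self.frac_ttilde_positive <= 1):
            raise ValueError("frac_ttilde_positive must be in [0, 1]")


@dataclass(frozen=True)
class SyntheticInstance:
    """A reproducible single-protein test instance."""

    protein_id: str
    protein_length: int
    candidates: tuple[CandidateDomain, ...]
    meta: dict[str, FamilyMeta]
    model: ContextModel
    seed: int
    params: InstanceParams = field(compare=False, default_factory=InstanceParams)

    def __post_init__(self) -> None:
        for c in self.candidates:
            if c.env_end > self.protein_length:
                raise ValueError(
                    f"candidate extends past protein end: {c.env_end} > {self.protein_length}"
                )


# sequence thresholds are ignored when t_dom >= 0.9 * t_seq (loader rule)
_SEQ_IGNORE_RATIO = 0.9


def _make_meta(rng: np.random.Generator, params: InstanceParams) -> dict[str, FamilyMeta]:
    metas: dict[str, FamilyMeta] = {}
    n_clans = max(1, params.n_families // 2)
    for i in range(params.n_families):
        fam = f"FAM{i:03d}"
        t_dom = float(np.round(rng.uniform(15.0, 30.0), 1))
        if rng.random() < params.frac_ttilde_positive:
            # strictly above the ignore ratio so the surplus stays active
            t_seq = float(np.round(t_dom / _SEQ_IGNORE_RATIO + rng.uniform(1.0, 6.0), 1))
            t_tilde = t_seq - t_dom
        else:
            t_seq = t_dom
            t_tilde = 0.0
        clan = f"CL{rng.integers(0, n_clans):03d}" if rng.random() < params.clan_rate else ""
        metas[fam] = FamilyMeta(
            family_id=fam, t_dom=t_dom, t_seq=t_seq, t_tilde=t_tilde, clan_id=clan
        )
    return metas


def _place_intervals(
    rng: np.random.Generator, params: InstanceParams
) -> list[tuple[int, int, int, int]]:
    """1-based inclusive (ali_start, ali_end, env_start, env_end) spans.

    Placement constraints are enforced on the envelope spans — the default
    coordinate pair for conflict tests — so ``conflict_rate = 0`` really
    yields an edgeless conflict graph.
    """
    spans: list[tuple[int, int, int, int]] = []
    for i in range(params.k):
        length = int(rng.integers(params.min_len, params.max_len + 1))
        pad_l = int(rng.integers(0, 9))
        pad_r = int(rng.integers(0, 9))
        env_len = length + pad_l + pad_r
        if spans and rng.random() < params.conflict_rate:
            # force > 40 aa envelope overlap with a random previous interval
            _, _, ps, pe = spans[int(rng.integers(0, len(spans)))]
            want = min(45, pe - ps + 1, env_len)
            env_start = max(1, pe - want + 1)
            env_end = env_start + env_len - 1
            if env_end > params.protein_length:
                env_start = max(1, params.protein_length - env_len + 1)
                env_end = env_start + env_len - 1
            spans.append((env_start + pad_l, env_start + pad_l + length - 1,
                          env_start, env_end))
            continue
        placed = False
        for _attempt in range(300):
            env_start = int(rng.integers(1, params.protein_length - env_len + 2))
            env_end = env_start + env_len - 1
            ok = True
            for _, _, ps, pe in spans:
                olen = max(0, min(env_end, pe) - max(env_start, ps) + 1)
                shorter = min(env_len, pe - ps + 1)
                if olen > 40 or olen > 0.5 * shorter:
                    ok = False
                    break
            if ok:
                spans.append((env_start + pad_l, env_start + pad_l + length - 1,
                              env_start, env_end))
                placed = True
                break
        if not placed:
            raise ValueError(
                f"cannot place {params.k} intervals of length <= {params.max_len} "
                f"in a protein of {params.protein_length} residues"
            )
    return spans


def _make_counts(
    rng: np.random.Generator, families: list[str], params: InstanceParams
) -> dict[tuple[str, str], int]:
    n = len(families)
    all_pairs = [(a, b) for a in families for b in families]
    n_observed = int(round((1.0 - params.frac_negative_context) * n * n))
    counts: dict[tuple[str, str], int] = {}
    if n_observed:
        chosen = rng.choice(len(all_pairs), size=n_observed, replace=False)
        for idx in chosen:
            counts[all_pairs[int(idx)]] = int(rng.integers(2, 60))
    return counts


def generate_instance(
    params: InstanceParams = InstanceParams(), seed: int = 0
) -> SyntheticInstance:
    """Deterministically build a single-protein instance from a seed.

    Raises ``ValueError`` when the requested intervals cannot fit.
    """
    rng = np.random.default_rng(seed)
    metas = _make_meta(rng, params)
    families = sorted(metas)
    spans = _place_intervals(rng, params)

    candidates = []
    for idx, (ali_start, ali_end, env_start, env_end) in enumerate(spans):
        fam = families[int(rng.integers(0, len(families)))]
        bitscore = float(
            np.round(metas[fam].t_dom + rng.normal(params.score_mean, params.score_sd), 1)
        )
        pvalue = float(min(1.0, max(1e-300, 2.0 ** (-max(bitscore, 0.0)))))
        candidates.append(
            CandidateDomain(
                protein_id=f"SYNTH{seed}",
                family_id=fam,
                ali_start=ali_start,
                ali_end=ali_end,
                env_start=env_start,
                env_end=env_end,
                bitscore=bitscore,
                pvalue=pvalue,
                clan_id=metas[fam].clan_id,
            )
        )

    counts = _make_counts(rng, families, params)
    model = estimate_scores(counts, families, alpha=params.alpha)
    return SyntheticInstance(
        protein_id=f"SYNTH{seed}",
        protein_length=params.protein_length,
        candidates=tuple(candidates),
        meta=metas,
        model=model,
        seed=seed,
        params=params,
    )
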