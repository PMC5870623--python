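"""On-disk formats: HMMER3 domtblout, family metadata, context counts, predictions.

All coordinates are 1-based inclusive, exactly as HMMER emits them; overlap
lengths elsewhere are therefore ``min(end) - max(start) + 1``.
"""

from __future__ import annotations

import math
from collections import OrderedDict
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Iterator, Mapping

__all__ = [
    "ParseError",
    "CandidateDomain",
    "FamilyMeta",
    "PredictionRecord",
    "parse_domtblout",
    "group_by_protein",
    "load_family_meta",
    "load_context_counts",
    "write_context_counts",
    "write_predictions",
    "load_architectures",
]

# Smallest P-value retained when the table reports 0 (extremely strong hits).
_MIN_PVALUE = 1e-300


class ParseError(ValueError):
    """Malformed input; carries the 1-based line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class CandidateDomain:
    """One per-domain profile-HMM hit on a protein.

    ``bitscore`` is the per-domain bit score (log2-odds of the HMM match vs
    the background residue model); ``pvalue`` the per-domain independent
    P-value. Alignment coordinates sit inside the envelope coordinates.
    """

    protein_id: str
    family_id: str
    ali_start: int
    ali_end: int
    env_start: int
    env_end: int
    bitscore: float
    pvalue: float
    clan_id: str = ""

    def __post_init__(self) -> None:
        if self.ali_start > self.ali_end:
            raise ValueError(
                f"coordinates out of order: ali {self.ali_start}..{self.ali_end}"
            )
        if self.env_start > self.ali_start or self.ali_end > self.env_end:
            raise ValueError(
                f"envelope {self.env_start}..{self.env_end} does not contain "
                f"alignment {self.ali_start}..{self.ali_end}"
            )
        if self.env_start < 1:
            raise ValueError(f"coordinates must be >= 1, got env_start={self.env_start}")
        if not math.isfinite(self.bitscore):
            raise ValueError(f"bitscore not finite: {self.bitscore}")
        if not (0.0 < self.pvalue <= 1.0):
            raise ValueError(f"pvalue outside (0, 1]: {self.pvalue}")

    def sort_key(self) -> tuple:
        """Deterministic within-protein ordering: start, end, family."""
        return (self.ali_start, self.ali_end, self.family_id)


@dataclass(frozen=True)
class FamilyMeta:
    """Per-family curated bit thresholds plus clan and nesting annotations.

    ``t_dom`` must be met by each domain instance, ``t_seq`` by the summed
    bit score of all instances of the family on one protein. ``t_tilde`` is
    the surplus ``t_seq - t_dom`` charged once per predicted family; it is
    forced to 0 whenever the sequence threshold is ignored (see
    :func:`load_family_meta`).
    """

    family_id: str
    t_dom: float
    t_seq: float
    t_tilde: float
    clan_id: str = ""
    nesting_partners: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.t_tilde < 0:
            raise ValueError(f"t_tilde must be >= 0, got {self.t_tilde}")


@dataclass(frozen=True)
class PredictionRecord:
    """A selected candidate plus its rank and the solution's objective."""

    candidate: CandidateDomain
    rank: int
    objective: float
    status: str

    def __post_init__(self) -> None:
        if not math.isfinite(self.objective):
            raise ValueError(f"objective not finite: {self.objective}")


def _as_lines(stream: IO[str] | Iterable[str]) -> Iterator[str]:
    return iter(stream)


def parse_domtblout(
    stream: IO[str] | Iterable[str],
    search_space: float = 1.0,
) -> list[CandidateDomain]:
    """Parse a HMMER3 ``--domtblout`` per-domain hit table.

    Expects the hmmscan orientation: the target is the family HMM, the query
    is the protein. The per-domain score column supplies ``bitscore`` and the
    per-domain independent E-value column supplies ``pvalue``. The contract
    is that hmmscan was run with ``-Z 1 --domZ 1`` so the E-value columns
    hold P-values already; ``search_space`` divides the raw values for runs
    made without those flags (the result is capped at 1).

    Comment lines (leading ``#``) and blank lines are skipped. Raises
    :class:`ParseError` naming the offending line on malformed input; empty
    input yields an empty list.
    """
    if search_space <= 0:
        raise ValueError(f"search_space must be positive, got {search_space}")
    out: list[CandidateDomain] = []
    for lineno, raw in enumerate(_as_lines(stream), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 23:
            raise ParseError(
                f"expected >= 23 whitespace-separated fields, got {len(fields)}",
                lineno,
            )
        try:
            family_id = fields[0]
            protein_id = fields[3]
            ievalue = float(fields[12])
            score = float(fields[13])
            ali_start = int(fields[17])
            ali_end = int(fields[18])
            env_start = int(fields[19])
            env_end = int(fields[20])
        except ValueError as exc:
            raise ParseError(f"non-numeric field: {exc}", lineno) from exc
        pvalue = min(ievalue / search_space, 1.0)
        if pvalue <= 0.0:
            pvalue = _MIN_PVALUE
        try:
            cand = CandidateDomain(
                protein_id=protein_id,
                family_id=family_id,
                ali_start=ali_start,
                ali_end=ali_end,
                env_start=env_start,
                env_end=env_end,
                bitscore=score,
                pvalue=pvalue,
            )
        except ValueError as exc:
            raise ParseError(str(exc), lineno) from exc
        out.append(cand)
    return out


def write_domtblout(
    candidates: Iterable[CandidateDomain],
    stream: IO[str],
    qlen: Mapping[str, int] | None = None,
) -> None:
    """Emit candidates as a HMMER3 ``--domtblout``-dialect table.

    One hit per row in the hmmscan orientation (target = family HMM,
    query = protein), with the E-value columns holding P-values as under
    ``-Z 1 --domZ 1``. Round-trips through :func:`parse_domtblout`.
    """
    stream.write(
        "#" + " ".join(
            [
                "target_name", "accession", "tlen", "query_name", "accession",
                "qlen", "E-value", "score", "bias", "#", "of", "c-Evalue",
                "i-Evalue", "score", "bias", "hmm_from", "hmm_to", "ali_from",
                "ali_to", "env_from", "env_to", "acc", "description",
            ]
        )
        + "\n"
    )
    for c in candidates:
        tlen = c.ali_end - c.ali_start + 1
        ql = qlen.get(c.protein_id, c.env_end) if qlen else c.env_end
        row = [
            c.family_id, "-", str(tlen), c.protein_id, "-", str(ql),
            f"{c.pvalue:.3g}", f"{c.bitscore:.1f}", "0.0", "1", "1",
            f"{c.pvalue:.3g}", f"{c.pvalue:.3g}", f"{c.bitscore:.1f}", "0.0",
            "1", str(tlen), str(c.ali_start), str(c.ali_end),
            str(c.env_start), str(c.env_end), "0.90", "-",
        ]
        stream.write(" ".join(row) + "\n")


def group_by_protein(
    candidates: Iterable[CandidateDomain],
) -> "OrderedDict[str, list[CandidateDomain]]":
    """Group candidates by protein, preserving first-seen protein order."""
    groups: OrderedDict[str, list[CandidateDomain]] = OrderedDict()
    for cand in candidates:
        groups.setdefault(cand.protein_id, []).append(cand)
    return groups


def annotate_clans(
    candidates: Iterable[CandidateDomain], meta: Mapping[str, FamilyMeta]
) -> list[CandidateDomain]:
    """Fill each candidate's clan from the family metadata (domtblout has none)."""
    out = []
    for cand in candidates:
        fam = meta.get(cand.family_id)
        if fam is not None and fam.clan_id and not cand.clan_id:
            cand = replace(cand, clan_id=fam.clan_id)
        out.append(cand)
    return out


# Sequence thresholds are dropped when the domain threshold already nearly
# implies them: t_dom >= (9/10) * t_seq.
_SEQ_THRESHOLD_IGNORE_RATIO = 0.9


def load_family_meta(stream: IO[str] | Iterable[str]) -> dict[str, FamilyMeta]:
    """Load the family metadata TSV.

    Columns: ``family_id  t_seq  t_dom  clan_id  nesting`` where ``clan_id``
    may be empty and ``nesting`` is a semicolon-joined list of family ids
    allowed to overlap this family without conflict (may be empty). A header
    line starting with ``family_id`` or ``#`` is skipped.

    ``t_tilde`` is ``t_seq - t_dom`` but forced to 0 when the thresholds are
    equal, when ``t_dom >= (9/10) * t_seq``, or when ``t_dom > t_seq`` (never
    negative).
    """
    metas: dict[str, FamilyMeta] = {}
    for lineno, raw in enumerate(_as_lines(stream), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if fields[0] == "family_id":
            continue
        if len(fields) < 3:
            raise ParseError(f"expected >= 3 tab-separated fields, got {len(fields)}", lineno)
        family_id = fields[0]
        if family_id in metas:
            raise ParseError(f"duplicate family_id {family_id!r}", lineno)
        try:
            t_seq = float(fields[1])
            t_dom = float(fields[2])
        except ValueError as exc:
            raise ParseError(f"non-numeric threshold: {exc}", lineno) from exc
        clan_id = fields[3] if len(fields) > 3 else ""
        nesting_raw = fields[4] if len(fields) > 4 else ""
        nesting = frozenset(p for p in nesting_raw.split(";") if p)
        t_tilde = t_seq - t_dom
        if t_tilde <= 0 or t_dom >= _SEQ_THRESHOLD_IGNORE_RATIO * t_seq:
            t_tilde = 0.0
        metas[family_id] = FamilyMeta(
            family_id=family_id,
            t_dom=t_dom,
            t_seq=t_seq,
            t_tilde=t_tilde,
            clan_id=clan_id,
            nesting_partners=nesting,
        )
    return metas


def write_family_meta(metas: Mapping[str, FamilyMeta], stream: IO[str]) -> None:
    stream.write("family_id\tt_seq\tt_dom\tclan_id\tnesting\n")
    for fam in metas.values():
        nesting = ";".join(sorted(fam.nesting_partners))
        stream.write(f"{fam.family_id}\t{fam.t_seq:g}\t{fam.t_dom:g}\t{fam.clan_id}\t{nesting}\n")


def load_context_counts(
    stream: IO[str] | Iterable[str],
) -> dict[tuple[str, str], int]:
    """Load the directed family-pair count TSV (``fam_i  fam_j  count``).

    Singleton counts (exactly 1) are assumed spurious and dropped at load
    time. Zero or negative counts and duplicate ordered pairs are errors.
    """
    counts: dict[tuple[str, str], int] = {}
    for lineno, raw in enumerate(_as_lines(stream), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise ParseError(f"expected 3 tab-separated fields, got {len(fields)}", lineno)
        fam_i, fam_j, raw_count = fields
        try:
            count = int(raw_count)
        except ValueError as exc:
            raise ParseError(f"non-integer count {raw_count!r}", lineno) from exc
        if count <= 0:
            raise ParseError(f"count must be positive, got {count}", lineno)
        key = (fam_i, fam_j)
        if key in counts:
            raise ParseError(f"duplicate pair ({fam_i}, {fam_j})", lineno)
        if count == 1:
            continue
        counts[key] = count
    return counts


def write_context_counts(
    counts: Mapping[tuple[str, str], int], stream: IO[str]
) -> None:
    """Write a directed count map as TSV rows sorted by (fam_i, fam_j)."""
    for (fam_i, fam_j) in sorted(counts):
        stream.write(f"{fam_i}\t{fam_j}\t{counts[(fam_i, fam_j)]}\n")


_PREDICTION_COLUMNS = [
    "protein_id",
    "family_id",
    "clan_id",
    "ali_start",
    "ali_end",
    "env_start",
    "env_end",
    "bitscore",
    "pvalue",
    "rank",
    "objective",
    "status",
]


def write_predictions(
    records: Iterable[PredictionRecord], stream: IO[str], version_header: bool = True
) -> None:
    """Write prediction records as TSV, sorted by protein then ali_start."""
    from domctx import __version__

    if version_header:
        stream.write(f"# domctx {__version__}\n")
    stream.write("\t".join(_PREDICTION_COLUMNS) + "\n")
    recs = sorted(
        records, key=lambda r: (r.candidate.protein_id,) + r.candidate.sort_key()
    )
    for rec in recs:
        c = rec.candidate
        row = [
            c.protein_id,
            c.family_id,
            c.clan_id,
            str(c.ali_start),
            str(c.ali_end),
            str(c.env_start),
            str(c.env_end),
            f"{c.bitscore:.1f}",
            f"{c.pvalue:.3g}",
            str(rec.rank),
            f"{rec.objective:.6f}",
            rec.status,
        ]
        stream.write("\t".join(row) + "\n")


def write_predictions_gff3(records: Iterable[PredictionRecord], stream: IO[str]) -> None:
    """GFF3 export: one protein_match feature per prediction, ali coordinates."""
    stream.write("##gff-version 3\n")
    recs = sorted(
        records, key=lambda r: (r.candidate.protein_id,) + r.candidate.sort_key()
    )
    for rec in recs:
        c = rec.candidate
        attrs = f"Name={c.family_id};rank={rec.rank};status={rec.status}"
        if c.clan_id:
            attrs += f";clan={c.clan_id}"
        stream.write(
            "\t".join(
                [
                    c.protein_id,
                    "domctx",
                    c.family_id,
                    str(c.ali_start),
                    str(c.ali_end),
                    f"{c.bitscore:.1f}",
                    ".",
                    ".",
                    attrs,
                ]
            )
            + "\n"
        )


def load_architectures(
    stream: IO[str] | Iterable[str],
) -> list[tuple[str, list[str]]]:
    """Load ordered domain architectures: ``protein_id<TAB>fam1,fam2,...``."""
    out: list[tuple[str, list[str]]] = []
    for lineno, raw in enumerate(_as_lines(stream), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise ParseError(f"expected 2 tab-separated fields, got {len(fields)}", lineno)
        protein_id, fams = fields
        out.append((protein_id, [f for f in fams.split(",") if f]))
    return out
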