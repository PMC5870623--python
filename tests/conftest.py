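import pytest

from domctx.context import estimate_scores
from domctx.io_formats import CandidateDomain, FamilyMeta


def _tilde(t_dom: float, t_seq: float) -> float:
    if t_seq > t_dom and t_dom < 0.9 * t_seq:
        return t_seq - t_dom
    return 0.0


@pytest.fixture
def make_cand():
    """Candidate factory; env defaults to the ali span (optionally padded)."""

    def _make(
        family_id="A",
        start=1,
        end=100,
        bitscore=30.0,
        protein_id="prot1",
        pvalue=1e-9,
        env_pad=0,
        clan_id="",
    ):
        return CandidateDomain(
            protein_id=protein_id,
            family_id=family_id,
            ali_start=start,
            ali_end=end,
            env_start=max(1, start - env_pad),
            env_end=end + env_pad,
            bitscore=bitscore,
            pvalue=pvalue,
            clan_id=clan_id,
        )

    return _make


@pytest.fixture
def make_meta():
    """Family-metadata factory applying the same t_tilde forcing as the loader."""

    def _make(family_id="A", t_dom=0.0, t_seq=None, clan_id="", nesting=()):
        if t_seq is None:
            t_seq = t_dom
        return FamilyMeta(
            family_id=family_id,
            t_dom=t_dom,
            t_seq=t_seq,
            t_tilde=_tilde(t_dom, t_seq),
            clan_id=clan_id,
            nesting_partners=frozenset(nesting),
        )

    return _make


@pytest.fixture
def make_meta_map(make_meta):
    """dict of FamilyMeta from {family: kwargs} specs."""

    def _make(specs):
        return {fam: make_meta(family_id=fam, **kw) for fam, kw in specs.items()}

    return _make


@pytest.fixture
def zero_context_model():
    """All pair scores exactly 0 (empty counts => uniform prior)."""

    def _make(families=("A", "B", "C")):
        return estimate_scores({}, families, alpha=1e-3)

    return _make


@pytest.fixture
def ab_model():
    """The worked 2-family model: n=2, alpha=1, c(A,B)=8.

    score(A,B) = log2(3); every unobserved pair scores -log2(3).
    """
    return estimate_scores({("A", "B"): 8}, ["A", "B"], alpha=1.0)
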