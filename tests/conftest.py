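"""Shared fixtures: small sequence sets, toy databases, synthetic hits."""

import random

import pytest

from srnahunt.blastio import ExtendedHit, Hit
from srnahunt.pipeline import ClassifiedHomolog, SearchConfig, classify_pi


def make_classified(pi: float, ident: str = "h", cfg: SearchConfig | None = None,
                    seq: str = "ACGTACGT") -> ClassifiedHomolog:
    """A ClassifiedHomolog with a prescribed PI, for selection-stage tests."""
    cfg = cfg or SearchConfig()
    hit = Hit(query_id="q", subject_id=ident, pident_local=pi, qstart=1,
              qend=len(seq), sstart=1, send=len(seq), evalue=1e-10,
              qlen=len(seq))
    ext = ExtendedHit(subject_id=ident, region_start=1, region_end=len(seq),
                      strand="plus", sequence=seq, source_hit=hit)
    return ClassifiedHomolog(extended=ext, pi=pi, klass=classify_pi(pi, cfg))


@pytest.fixture
def rng():
    return random.Random(20240917)


@pytest.fixture
def classified_factory():
    return make_classified
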