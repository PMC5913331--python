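"""Iterative homolog search orchestration.

One round = local search -> asymmetric extension -> global-PI
classification.  Hits with PI > 70% to the query are true homologs; hits
between the lower PI threshold (default 52%) and 70% are candidates
deferred to the structure filter; everything below is discarded (counted in
provenance only).  Selected hits with PI in (65, 80] — up to 45 each from
(65, 70] and (70, 80], up to 10 from (80, 100] — seed the next search
round.  Coordinate-jittered re-discoveries of one locus are collapsed
before the structure filter runs.

All PI values, in every round, are computed against the *original* query.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import blastio, londen
from .blastio import ExtendedHit, Hit, SequenceDatabase
from .seqident import AlignmentParams, normalize_sequence, percent_identity

logger = logging.getLogger(__name__)

__all__ = [
    "SearchConfig",
    "ClassifiedHomolog",
    "HomologSet",
    "classify_hits",
    "classify_pi",
    "select_reblast_queries",
    "collapse_duplicates",
    "run_search",
]

# re-BLAST seed caps per half-open PI interval (lo, hi]
REBLAST_INTERVALS: tuple[tuple[float, float, int], ...] = (
    (65.0, 70.0, 45),
    (70.0, 80.0, 45),
    (80.0, 100.0, 10),
)


@dataclass(frozen=True)
class SearchConfig:
    """Tunable knobs of the search; defaults are the tool's standard mode."""

    evalue: float = 1.0
    lower_pi: float = 52.0
    true_pi: float = 70.0
    max_rounds: int = 2
    structure_filter: str = "auto"        # "auto" | "manual" | "off"
    lambda_manual: float = 2.0
    londen_single_cut: bool = False
    caps: tuple[tuple[float, float, int], ...] = REBLAST_INTERVALS
    ktuple_k: int = 2
    pregroup_threshold: float = 85.0
    structure_backend: str = "rnapdist"
    blast_executable: str = "blastn"

    def __post_init__(self) -> None:
        if not (0 < self.lower_pi < self.true_pi <= 100):
            raise ValueError("require 0 < lower_pi < true_pi <= 100")
        if self.max_rounds < 1:
            raise ValueError("max_rounds must be >= 1")
        if self.structure_filter not in ("auto", "manual", "off"):
            raise ValueError("structure_filter must be auto, manual or off")


@dataclass(frozen=True)
class ClassifiedHomolog:
    """An extended hit with its global PI to the query and its class."""

    extended: ExtendedHit
    pi: float
    klass: str   # "true_homolog" | "candidate" | "discarded"

    @property
    def id(self) -> str:
        e = self.extended
        return f"{e.subject_id}:{e.region_start}-{e.region_end}({e.strand})"

    @property
    def sequence(self) -> str:
        return self.extended.sequence


@dataclass
class HomologSet:
    """Final result of a search: classified, filtered, with provenance."""

    query_id: str
    query_seq: str
    true_homologs: list[ClassifiedHomolog] = field(default_factory=list)
    candidates: list[ClassifiedHomolog] = field(default_factory=list)
    accepted: list[ClassifiedHomolog] = field(default_factory=list)
    provenance: list[dict] = field(default_factory=list)

    @property
    def accepted_pis(self) -> list[float]:
        return [h.pi for h in self.accepted]


def classify_pi(pi: float, cfg: SearchConfig) -> str:
    """Class of a hit with global percent identity ``pi`` under ``cfg``."""
    if pi > cfg.true_pi:
        return "true_homolog"
    if pi >= cfg.lower_pi:
        return "candidate"
    return "discarded"


def classify_hits(
    extended: list[ExtendedHit],
    query_seq: str,
    cfg: SearchConfig | None = None,
    params: AlignmentParams | None = None,
) -> list[ClassifiedHomolog]:
    """Annotate every extended hit with its global PI to the query."""
    cfg = cfg or SearchConfig()
    params = params or AlignmentParams()
    query_seq = normalize_sequence(query_seq, name="query")
    out = []
    for ext in extended:
        try:
            pi = percent_identity(query_seq, ext.sequence, params)
        except ValueError as exc:
            logger.warning("skipping hit %s:%d-%d: %s", ext.subject_id,
                           ext.region_start, ext.region_end, exc)
            continue
        out.append(ClassifiedHomolog(extended=ext, pi=pi,
                                     klass=classify_pi(pi, cfg)))
    return out


def _evenly_spaced(items: list, cap: int) -> list:
    """Evenly spaced subsample (by list position) of at most ``cap`` items."""
    if len(items) <= cap:
        return list(items)
    idx = np.unique(np.round(np.linspace(0, len(items) - 1, cap)).astype(int))
    picked = [items[i] for i in idx]
    # rounding collisions are possible in principle; top up from the rest
    if len(picked) < cap:
        chosen = set(idx)
        for i in range(len(items)):
            if i not in chosen:
                picked.append(items[i])
                if len(picked) == cap:
                    break
    return picked


def select_reblast_queries(
    classified: list[ClassifiedHomolog], cfg: SearchConfig | None = None
) -> list[ClassifiedHomolog]:
    """Pick the seed set for the next search round.

    From each PI interval (65, 70], (70, 80], (80, 100] at most its cap
    (45, 45, 10) is taken; when over cap, an evenly spaced subsample across
    the PI-sorted interval maximises the sequence diversity of the seeds.
    """
    cfg = cfg or SearchConfig()
    seeds: list[ClassifiedHomolog] = []
    seen: set[str] = set()
    for lo, hi, cap in cfg.caps:
        bucket = sorted(
            (c for c in classified
             if lo < c.pi <= hi and c.klass != "discarded"),
            key=lambda c: (c.pi, c.id),
        )
        for c in _evenly_spaced(bucket, cap):
            if c.id not in seen:
                seen.add(c.id)
                seeds.append(c)
    return seeds


def _overlaps(a: ExtendedHit, b: ExtendedHit) -> bool:
    return (a.subject_id == b.subject_id and a.strand == b.strand
            and a.region_start <= b.region_end and b.region_start <= a.region_end)


def collapse_duplicates(homologs: list[ClassifiedHomolog]) -> list[ClassifiedHomolog]:
    """Collapse re-discoveries of a locus: same subject and strand with
    overlapping regions keep only the earliest-found record.  Identical
    sequences at distinct loci are distinct homologs and are all kept."""
    kept: list[ClassifiedHomolog] = []
    for cand in homologs:
        if any(_overlaps(cand.extended, k.extended) for k in kept):
            continue
        kept.append(cand)
    return kept


def _search_round(
    queries: list[tuple[str, str]],
    db_path: str | Path | None,
    cfg: SearchConfig,
    hit_table: str | Path | None,
    qlen_map: dict[str, int],
) -> list[Hit]:
    return blastio.run_search_backend(
        queries, db_path, cfg.evalue,
        hit_table=hit_table, executable=cfg.blast_executable,
        qlen_map=qlen_map,
    )


def run_search(
    query: tuple[str, str],
    db: str | Path | SequenceDatabase,
    cfg: SearchConfig | None = None,
    *,
    hit_tables: list[str | Path] | None = None,
    params: AlignmentParams | None = None,
) -> HomologSet:
    """Run the full iterative search and filtering workflow.

    ``query`` is an ``(id, sequence)`` pair.  ``db`` is a FASTA path (the
    search backend is run against it) or a :class:`SequenceDatabase`
    combined with ``hit_tables`` — one pre-computed tabular hit file per
    round (offline mode; rounds beyond the supplied tables stop the
    iteration).
    """
    cfg = cfg or SearchConfig()
    params = params or AlignmentParams()
    query_id, query_seq = query[0], normalize_sequence(query[1], name="query")

    if isinstance(db, SequenceDatabase):
        seqdb, db_path = db, None
        if hit_tables is None:
            raise ValueError("offline mode (SequenceDatabase) requires hit_tables")
    else:
        db_path = Path(db)
        seqdb = SequenceDatabase.from_fasta(db_path)

    result = HomologSet(query_id=query_id, query_seq=query_seq)
    classified: list[ClassifiedHomolog] = []
    round_queries: list[tuple[str, str]] = [(query_id, query_seq)]
    qlen_map: dict[str, int] = {query_id: len(query_seq)}

    for rnd in range(1, cfg.max_rounds + 1):
        table = None
        if hit_tables is not None:
            if rnd > len(hit_tables):
                break
            table = hit_tables[rnd - 1]
        qlen_map.update({qid: len(seq) for qid, seq in round_queries})
        hits = _search_round(round_queries, db_path, cfg, table, qlen_map)
        extended = [blastio.asymmetric_extend(h, seqdb) for h in hits]
        newly = classify_hits(extended, query_seq, cfg, params)
        n_before = len(classified)
        classified = collapse_duplicates(
            classified + [c for c in newly if c.klass != "discarded"]
        )
        n_new = len(classified) - n_before
        n_disc = sum(1 for c in newly if c.klass == "discarded")
        seeds = select_reblast_queries(classified, cfg)
        result.provenance.append({
            "round": rnd,
            "hits": len(hits),
            "new_loci": n_new,
            "true_homologs": sum(1 for c in classified if c.klass == "true_homolog"),
            "candidates": sum(1 for c in classified if c.klass == "candidate"),
            "discarded": n_disc,
            "selected_seeds": len(seeds),
        })
        logger.info(
            "round %d: %d hits, %d new loci, %d true, %d candidates, "
            "%d seeds selected",
            rnd, len(hits), n_new,
            result.provenance[-1]["true_homologs"],
            result.provenance[-1]["candidates"], len(seeds),
        )
        if rnd == cfg.max_rounds or n_new == 0 or not seeds:
            break
        round_queries = [(s.id, s.sequence) for s in seeds]

    result.true_homologs = [c for c in classified if c.klass == "true_homolog"]
    result.candidates = [c for c in classified if c.klass == "candidate"]

    if not result.candidates:
        accepted_cand = []
    elif cfg.structure_filter == "off":
        accepted_cand = list(result.candidates)
    else:
        lam = None
        if cfg.structure_filter == "manual":
            lam = londen.manual_lambda(cfg.lambda_manual, cfg.londen_single_cut)
        accepted_ids = londen.structure_filter(
            query_id, query_seq,
            [(c.id, c.sequence, c.pi) for c in result.true_homologs],
            [(c.id, c.sequence, c.pi) for c in result.candidates],
            lambda_params=lam,
            backend=cfg.structure_backend,
            pregroup_threshold=cfg.pregroup_threshold,
            ktuple_k=cfg.ktuple_k,
        )
        accepted_cand = [c for c in result.candidates if c.id in accepted_ids]

    result.accepted = sorted(
        result.true_homologs + accepted_cand, key=lambda c: (-c.pi, c.id)
    )
    return result
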