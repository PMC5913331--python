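"""Candidate hit acquisition and asymmetric hit extension.

A local-alignment search (BLASTn) typically returns hits shorter than the
sRNA query.  Because a truncated homolog is useless for downstream structure
comparison, every hit is widened on the subject sequence by the query-side
deficits: ``qstart - 1`` nucleotides on the query-5' side and
``qlen - qend`` on the query-3' side, mapped through the hit's strand.  The
widened region is clamped at the subject boundaries (draft-genome contig
edges) and the clamped amounts are recorded rather than the hit dropped.

Hits arrive either from a live ``blastn`` run against a FASTA database or
from a pre-computed 12-column tabular hit file (offline mode); both routes
produce identical :class:`Hit` records.

Coordinates are 1-based inclusive throughout, the BLAST native convention;
``sstart > send`` signals a minus-strand hit.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import reverse_complement

from .seqident import normalize_sequence

__all__ = [
    "Hit",
    "ExtendedHit",
    "SequenceDatabase",
    "BackendUnavailableError",
    "BackendFailureError",
    "HitTableParseError",
    "MissingRecordError",
    "parse_blast_tabular",
    "fetch_subsequence",
    "fetch_subsequence_clamped",
    "asymmetric_extend",
    "run_search_backend",
    "write_fasta",
]


class BackendUnavailableError(RuntimeError):
    """No search executable found and no offline hit table supplied."""


class BackendFailureError(RuntimeError):
    """The external search backend exited abnormally."""


class HitTableParseError(ValueError):
    """Malformed row in a tabular hit file."""


class MissingRecordError(KeyError):
    """Subject identifier absent from the sequence database."""


@dataclass(frozen=True)
class Hit:
    """One local-alignment match of the query in a database sequence."""

    query_id: str
    subject_id: str
    pident_local: float
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    qlen: int
    slen: int = 0  # 0 = unknown

    def __post_init__(self) -> None:
        if not (1 <= self.qstart <= self.qend <= self.qlen):
            raise ValueError(
                f"invalid query coordinates {self.qstart}..{self.qend} "
                f"for qlen={self.qlen}"
            )
        if self.evalue < 0:
            raise ValueError("evalue must be non-negative")

    @property
    def strand(self) -> str:
        return "minus" if self.sstart > self.send else "plus"

    @property
    def s_lo(self) -> int:
        return min(self.sstart, self.send)

    @property
    def s_hi(self) -> int:
        return max(self.sstart, self.send)


@dataclass(frozen=True)
class ExtendedHit:
    """A hit widened to full putative homolog length, in query orientation."""

    subject_id: str
    region_start: int
    region_end: int
    strand: str
    sequence: str
    source_hit: Hit
    clamped_5p: int = 0
    clamped_3p: int = 0

    def __post_init__(self) -> None:
        if self.region_start > self.region_end:
            raise ValueError("region_start must be <= region_end")
        if len(self.sequence) != self.region_end - self.region_start + 1:
            raise ValueError("sequence length inconsistent with region")

    @property
    def locus(self) -> tuple[str, int, int, str]:
        return (self.subject_id, self.region_start, self.region_end, self.strand)


class SequenceDatabase:
    """In-memory nucleotide database with strand-aware subsequence access.

    Emulates ``blastdbcmd`` retrieval over a FASTA file; adequate for the
    genome-scale inputs this tool targets (bacterial contigs).
    """

    def __init__(self, records: dict[str, str]):
        self._records = {rid: normalize_sequence(seq, name=rid)
                         for rid, seq in records.items()}

    @classmethod
    def from_fasta(cls, path: str | Path) -> "SequenceDatabase":
        records = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            records[rec.id] = str(rec.seq)
        if not records:
            raise MissingRecordError(f"no FASTA records in {path}")
        return cls(records)

    def __contains__(self, subject_id: str) -> bool:
        return subject_id in self._records

    def ids(self) -> list[str]:
        return list(self._records)

    def length(self, subject_id: str) -> int:
        try:
            return len(self._records[subject_id])
        except KeyError:
            raise MissingRecordError(subject_id) from None

    def record(self, subject_id: str) -> str:
        try:
            return self._records[subject_id]
        except KeyError:
            raise MissingRecordError(subject_id) from None

    def subsequence_clamped(
        self, subject_id: str, start: int, end: int, strand: str = "plus"
    ) -> tuple[str, int, int]:
        """Retrieve [start, end] (1-based inclusive), clamped to the record.

        Returns ``(sequence, clamp_5p, clamp_3p)`` where the clamp amounts
        count nucleotides truncated at the 5' and 3' ends *of the returned
        (query-oriented) sequence*: on the minus strand the subject high end
        is the sequence 5' end.
        """
        seq = self.record(subject_id)
        slen = len(seq)
        if start > end:
            raise ValueError(f"start {start} > end {end}")
        c_lo = max(0, 1 - start)
        c_hi = max(0, end - slen)
        lo, hi = start + c_lo, end - c_hi
        if lo > hi:
            raise ValueError(
                f"interval {start}..{end} lies entirely outside {subject_id}"
            )
        sub = seq[lo - 1 : hi]
        if strand == "minus":
            return reverse_complement(sub), c_hi, c_lo
        return sub, c_lo, c_hi


def fetch_subsequence(
    db: SequenceDatabase, subject_id: str, start: int, end: int, strand: str = "plus"
) -> str:
    """Subject subsequence in the requested orientation (see the db method)."""
    seq, _, _ = db.subsequence_clamped(subject_id, start, end, strand)
    return seq


def fetch_subsequence_clamped(
    db: SequenceDatabase, subject_id: str, start: int, end: int, strand: str = "plus"
) -> tuple[str, int, int]:
    return db.subsequence_clamped(subject_id, start, end, strand)


def asymmetric_extend(hit: Hit, db: SequenceDatabase) -> ExtendedHit:
    """Widen a local hit by the query-side deficits, through the strand.

    Plus strand: the query-5' deficit (``qstart - 1``) extends the subject
    region downwards and the query-3' deficit (``qlen - qend``) upwards.
    Minus strand: the mapping flips — the query-5' deficit raises the
    subject high end and the query-3' deficit lowers the low end.
    """
    up = hit.qstart - 1          # missing on the query-5' side
    down = hit.qlen - hit.qend   # missing on the query-3' side
    if hit.strand == "plus":
        start = hit.s_lo - up
        end = hit.s_hi + down
    else:
        start = hit.s_lo - down
        end = hit.s_hi + up
    seq, c5, c3 = db.subsequence_clamped(hit.subject_id, start, end, hit.strand)
    slen = db.length(hit.subject_id)
    return ExtendedHit(
        subject_id=hit.subject_id,
        region_start=max(start, 1),
        region_end=min(end, slen),
        strand=hit.strand,
        sequence=seq,
        source_hit=hit,
        clamped_5p=c5,
        clamped_3p=c3,
    )


_TABULAR_COLUMNS = 12  # qseqid sseqid pident length mismatch gapopen qstart qend sstart send evalue bitscore


def parse_blast_tabular(
    path: str | Path, qlen: int | dict[str, int], slens: dict[str, int] | None = None
) -> list[Hit]:
    """Read a standard 12-column BLAST tabular file into :class:`Hit` records.

    ``qlen`` may be a single length (one query) or a map qseqid -> length,
    since the 12-column format does not carry query lengths.
    """
    hits: list[Hit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != _TABULAR_COLUMNS:
                raise HitTableParseError(
                    f"line {lineno}: expected {_TABULAR_COLUMNS} columns, "
                    f"got {len(fields)}"
                )
            qid, sid = fields[0], fields[1]
            try:
                ql = qlen[qid] if isinstance(qlen, dict) else int(qlen)
                hit = Hit(
                    query_id=qid,
                    subject_id=sid,
                    pident_local=float(fields[2]),
                    qstart=int(fields[6]),
                    qend=int(fields[7]),
                    sstart=int(fields[8]),
                    send=int(fields[9]),
                    evalue=float(fields[10]),
                    qlen=ql,
                    slen=(slens or {}).get(sid, 0),
                )
            except (ValueError, KeyError) as exc:
                raise HitTableParseError(f"line {lineno}: {exc}") from exc
            hits.append(hit)
    return hits


def _sort_hits(hits: list[Hit]) -> list[Hit]:
    return sorted(hits, key=lambda h: (h.evalue, h.subject_id, h.sstart))


def run_search_backend(
    queries: list[tuple[str, str]],
    db: str | Path | None,
    evalue_cutoff: float = 1.0,
    *,
    hit_table: str | Path | None = None,
    executable: str = "blastn",
    extra_args: tuple[str, ...] = ("-task", "blastn", "-dust", "no"),
    qlen_map: dict[str, int] | None = None,
) -> list[Hit]:
    """Obtain hits for one or more queries, online or offline.

    ``queries`` is a list of ``(id, sequence)`` pairs.  If ``hit_table`` is
    given it is parsed instead of running the backend (offline mode);
    otherwise ``blastn`` is run against ``db`` (a FASTA path, formatted on
    the fly with ``makeblastdb`` if needed).  Only hits with
    ``evalue <= evalue_cutoff`` are returned, ordered by (evalue,
    subject_id, sstart).
    """
    if evalue_cutoff <= 0:
        raise ValueError("evalue_cutoff must be positive")
    qlens = {qid: len(normalize_sequence(seq, name=qid)) for qid, seq in queries}
    if qlen_map:
        qlens = {**qlen_map, **qlens}

    if hit_table is not None:
        hits = parse_blast_tabular(hit_table, qlens)
        return _sort_hits([h for h in hits if h.evalue <= evalue_cutoff])

    if shutil.which(executable) is None:
        raise BackendUnavailableError(
            f"{executable!r} not on PATH and no offline hit table supplied"
        )
    if db is None or not Path(db).exists():
        raise BackendFailureError(f"database path {db!r} does not exist")

    with tempfile.TemporaryDirectory(prefix="srnahunt_blast_") as tmp:
        tmpdir = Path(tmp)
        qpath = tmpdir / "query.fa"
        write_fasta(qpath, queries)
        dbprefix = tmpdir / "db"
        mkdb = subprocess.run(
            ["makeblastdb", "-in", str(db), "-dbtype", "nucl",
             "-out", str(dbprefix)],
            capture_output=True, text=True,
        )
        if mkdb.returncode != 0:
            raise BackendFailureError(
                f"makeblastdb failed (exit {mkdb.returncode}): {mkdb.stderr.strip()}"
            )
        cmd = [
            executable, "-query", str(qpath), "-db", str(dbprefix),
            "-outfmt", "6", "-evalue", str(evalue_cutoff),
            "-num_threads", "1", *extra_args,
        ]
        proc = subprocess.run(cmd, capture_output=True, text=True)
        if proc.returncode != 0:
            raise BackendFailureError(
                f"{executable} failed (exit {proc.returncode}): "
                f"{proc.stderr.strip()}"
            )
        out = tmpdir / "hits.tsv"
        out.write_text(proc.stdout)
        hits = parse_blast_tabular(out, qlens)
    return _sort_hits([h for h in hits if h.evalue <= evalue_cutoff])


def write_fasta(path: str | Path, records: list[tuple[str, str]], wrap: int = 70) -> None:
    """Write (id, sequence) pairs as FASTA wrapped at ``wrap`` columns."""
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), wrap):
                fh.write(seq[i : i + wrap] + "\n")
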