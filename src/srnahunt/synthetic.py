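"""Synthetic sRNA families, decoys and toy genome databases.

Everything the pipeline consumes — query sequences, genome-like FASTA
databases, tabular hit files, lineage maps — can be generated here from an
integer seed, so the whole workflow is testable without downloads or
external binaries.

The generator emulates the two populations a real search must separate:

* *members* — variants of a family seed sequence mutated at a per-site
  rate, with substitutions at paired positions applied compensatorily
  (both partners replaced by a random Watson–Crick or GU pair), so sequence
  identity drops while the secondary structure survives;
* *decoys* — the seed with the bases of its paired regions scrambled but
  its loops retained.  This keeps the overall identity to the seed inside
  the candidate range (roughly 52-60%) while destroying the stems, which
  makes the decoys rejectable only by the structure filter, not by the PI
  thresholds.

All randomness flows through explicit ``rng_seed`` arguments.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from .blastio import SequenceDatabase, write_fasta
from .seqident import normalize_sequence

__all__ = [
    "FamilySpec",
    "PlantedLocus",
    "ToyDatabase",
    "StructureError",
    "pair_table",
    "design_family_seed",
    "mutate_preserving_structure",
    "scramble_paired_regions",
    "shuffle_decoys",
    "make_toy_database",
    "naive_hit_table",
    "BenchmarkReplicate",
    "make_benchmark_replicate",
]

_BASES = "ACGT"
_PAIRS = ["AT", "TA", "GC", "CG", "GT", "TG"]  # WC + GU (DNA alphabet)
_LINEAGES = [
    ["Bacteria", "Proteobacteria", "Enterobacterales", "Escherichia"],
    ["Bacteria", "Proteobacteria", "Enterobacterales", "Salmonella"],
    ["Bacteria", "Firmicutes", "Bacillales", "Bacillus"],
    ["Bacteria", "Cyanobacteria", "Synechococcales", "Synechocystis"],
    ["Bacteria", "Actinobacteria", "Mycobacteriales", "Mycobacterium"],
]


class StructureError(ValueError):
    """Malformed dot-bracket string."""


def pair_table(structure: str) -> list[tuple[int, int]]:
    """(i, j) base-pair index pairs (0-based, i < j) from dot-bracket."""
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise StructureError(f"unbalanced ')' at position {i}")
            pairs.append((stack.pop(), i))
        elif c != ".":
            raise StructureError(f"invalid character {c!r} at position {i}")
    if stack:
        raise StructureError(f"unclosed '(' at position {stack[-1]}")
    return pairs


@dataclass(frozen=True)
class FamilySpec:
    """Recipe for one synthetic sRNA family."""

    seed_sequence: str
    structure: str
    n_members: int = 8
    substitution_rate: float = 0.1
    compensatory: bool = True
    rng_seed: int = 0
    loop_substitution_rate: float | None = None  # None = same as paired rate
    phylogeny: str = "star"  # "star": variants of the seed; "lineage": tree-like descent

    def __post_init__(self) -> None:
        normalize_sequence(self.seed_sequence, name="seed_sequence")
        if len(self.structure) != len(self.seed_sequence):
            raise StructureError("structure and seed length differ")
        pair_table(self.structure)  # validates brackets
        if not (0.0 <= self.substitution_rate <= 1.0):
            raise ValueError("substitution_rate must be in [0, 1]")
        if self.loop_substitution_rate is not None and not (
            0.0 <= self.loop_substitution_rate <= 1.0
        ):
            raise ValueError("loop_substitution_rate must be in [0, 1]")
        if self.phylogeny not in ("star", "lineage"):
            raise ValueError("phylogeny must be 'star' or 'lineage'")

    @property
    def effective_loop_rate(self) -> float:
        return (self.substitution_rate if self.loop_substitution_rate is None
                else self.loop_substitution_rate)


def design_family_seed(
    rng_seed: int, stem: int = 13, loop: int = 6, spacer: int = 6,
    head: int = 5, tail: int = 6, n_hairpins: int = 3,
) -> tuple[str, str]:
    """Design a multi-hairpin sRNA-like seed and its dot-bracket structure.

    The layout head-(hairpin-spacer)*-tail mimics a typical sRNA: several
    stem-loops ending in a terminator-like 3' hairpin.  Stems are perfect
    Watson-Crick duplexes so the molecule folds firmly into the declared
    structure.  Defaults give 119 nt with ~66% of positions paired,
    mid-range for bacterial sRNAs (~50-450 nt); the high paired fraction
    puts stem-scrambled decoys squarely in the candidate identity range.
    """
    rng = random.Random(rng_seed)

    def rand(n: int) -> str:
        return "".join(rng.choice(_BASES) for _ in range(n))

    def hairpin() -> tuple[str, str]:
        s = rand(stem)
        comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
        rc = "".join(comp[c] for c in reversed(s))
        lp = rand(loop)
        return s + lp + rc, "(" * stem + "." * loop + ")" * stem

    seq, dot = rand(head), "." * head
    for i in range(n_hairpins):
        h, d = hairpin()
        seq += h
        dot += d
        if i < n_hairpins - 1:
            seq += rand(spacer)
            dot += "." * spacer
    seq += rand(tail)
    dot += "." * tail
    return seq, dot


def mutate_preserving_structure(spec: FamilySpec) -> list[str]:
    """Generate family members mutated at ``substitution_rate`` per site.

    Paired positions mutate as a unit: with probability
    ``substitution_rate`` the pair is replaced by a random different
    Watson-Crick/GU pair (when ``compensatory``), keeping every stem fully
    complementary.  Unpaired positions mutate independently to a random
    different base at ``loop_substitution_rate`` (defaults to the paired
    rate).  Distinct rates emulate the classic evolutionary signature of
    structured RNAs — fast covarying stems, conserved loops — which is
    exactly the signal a structure-aware filter must pick up where plain
    sequence identity fails.

    In ``star`` phylogeny every member mutates the seed independently
    (equidistant family); in ``lineage`` phylogeny each member descends from
    a randomly chosen earlier member, so divergence accumulates along a
    random tree and pairwise distances are hierarchical, as in a real
    family.
    """
    rng = random.Random(spec.rng_seed)
    seed = normalize_sequence(spec.seed_sequence)
    pairs = pair_table(spec.structure)
    paired_idx = {i for p in pairs for i in p}
    loop_rate = spec.effective_loop_rate

    def mutate(parent: str) -> str:
        seq = list(parent)
        for i, j in pairs:
            if rng.random() < spec.substitution_rate:
                if spec.compensatory:
                    old = seq[i] + seq[j]
                    choices = [p for p in _PAIRS if p != old]
                    new = rng.choice(choices)
                    seq[i], seq[j] = new[0], new[1]
                else:
                    seq[i] = rng.choice([b for b in _BASES if b != seq[i]])
                    seq[j] = rng.choice([b for b in _BASES if b != seq[j]])
        for i in range(len(seq)):
            if i not in paired_idx and rng.random() < loop_rate:
                seq[i] = rng.choice([b for b in _BASES if b != seq[i]])
        return "".join(seq)

    variants: list[str] = []
    for _ in range(spec.n_members):
        if spec.phylogeny == "star" or not variants:
            parent = seed
        else:
            parent = rng.choice([seed] + variants)
        variants.append(mutate(parent))
    return variants


def scramble_paired_regions(
    seed_sequence: str, structure: str, n: int, rng_seed: int
) -> list[str]:
    """Decoys: permute the bases occupying paired positions, keep loops.

    Composition is preserved, stems are destroyed; overall identity to the
    seed stays in the candidate range for typical ~55-65% paired layouts.
    """
    rng = random.Random(rng_seed)
    seed = normalize_sequence(seed_sequence)
    idx = sorted({i for p in pair_table(structure) for i in p})
    decoys = []
    for _ in range(n):
        bases = [seed[i] for i in idx]
        rng.shuffle(bases)
        seq = list(seed)
        for pos, b in zip(idx, bases):
            seq[pos] = b
        decoys.append("".join(seq))
    return decoys


def _mono_shuffle(seq: str, rng: random.Random) -> str:
    chars = list(seq)
    rng.shuffle(chars)
    return "".join(chars)


def _dinucleotide_shuffle(seq: str, rng: random.Random) -> str:
    """Altschul-Erickson shuffle: random sequence with identical
    dinucleotide (and hence mononucleotide) counts."""
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    last = seq[-1]
    vertices = list(edges)
    while True:  # sample "last edges" forming an arborescence into `last`
        last_edge = {v: rng.choice(edges[v]) for v in vertices if v != last}
        ok = True
        for v in last_edge:
            seen = {v}
            w = v
            while w != last:
                w = last_edge.get(w)
                if w is None or w in seen:
                    ok = False
                    break
                seen.add(w)
            if not ok:
                break
        if ok:
            break
    walk_edges: dict[str, list[str]] = {}
    for v, targets in edges.items():
        rest = list(targets)
        if v in last_edge:
            rest.remove(last_edge[v])
        rng.shuffle(rest)
        if v in last_edge:
            rest.append(last_edge[v])
        walk_edges[v] = rest
    out = [seq[0]]
    pos: dict[str, int] = {v: 0 for v in walk_edges}
    v = seq[0]
    while pos.get(v, 0) < len(walk_edges.get(v, [])):
        w = walk_edges[v][pos[v]]
        pos[v] += 1
        out.append(w)
        v = w
    return "".join(out)


def shuffle_decoys(
    seed_sequence: str, n: int, order: str = "di", rng_seed: int = 0
) -> list[str]:
    """Composition-preserving shuffles of the seed (mono- or di-nucleotide)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    seed = normalize_sequence(seed_sequence)
    rng = random.Random(rng_seed)
    if order == "mono":
        return [_mono_shuffle(seed, rng) for _ in range(n)]
    if order == "di":
        return [_dinucleotide_shuffle(seed, rng) for _ in range(n)]
    raise ValueError("order must be 'mono' or 'di'")


@dataclass(frozen=True)
class PlantedLocus:
    """Ground-truth record of one sequence planted in the toy database."""

    record_id: str
    start: int        # 1-based inclusive, plus-strand subject coordinates
    end: int
    strand: str       # orientation the planted sequence reads in
    label: str        # "member" | "decoy"
    family: int
    planted_id: str
    sequence: str     # the planted sequence, in its own (query) orientation


@dataclass
class ToyDatabase:
    """A set of synthetic genome records with known planted loci."""

    records: dict[str, str]
    truth: list[PlantedLocus]
    lineages: dict[str, list[str]] = field(default_factory=dict)

    def to_sequence_database(self) -> SequenceDatabase:
        return SequenceDatabase(self.records)

    def write_fasta(self, path: str | Path) -> None:
        write_fasta(path, list(self.records.items()))

    def write_lineages(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for rid, lin in self.lineages.items():
                fh.write(f"{rid}\t{';'.join(lin)}\n")

    def write_truth(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("record\tstart\tend\tstrand\tlabel\tfamily\tplanted_id\n")
            for t in self.truth:
                fh.write(f"{t.record_id}\t{t.start}\t{t.end}\t{t.strand}\t"
                         f"{t.label}\t{t.family}\t{t.planted_id}\n")


_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def make_toy_database(
    families: list[FamilySpec],
    decoys_per_family: int | list[int] = 4,
    flank_length: int = 60,
    rng_seed: int = 0,
) -> ToyDatabase:
    """Embed family members and stem-scrambled decoys in flanked records.

    Each planted sequence becomes one contig-like record: random flanks of
    ``flank_length`` nt on both sides, random strand.  The truth table
    records exact coordinates so every planted sequence is recoverable via
    subsequence retrieval.
    """
    if not families:
        raise ValueError("need at least one family")
    rng = random.Random(rng_seed)
    records: dict[str, str] = {}
    truth: list[PlantedLocus] = []
    lineages: dict[str, list[str]] = {}
    counter = 0

    def plant(seq: str, label: str, fam_idx: int, planted_id: str) -> None:
        nonlocal counter
        counter += 1
        rid = f"g{counter:04d}"
        left = "".join(rng.choice(_BASES) for _ in range(flank_length))
        right = "".join(rng.choice(_BASES) for _ in range(flank_length))
        strand = rng.choice(["plus", "minus"])
        insert = seq if strand == "plus" else _revcomp(seq)
        records[rid] = left + insert + right
        truth.append(PlantedLocus(
            record_id=rid, start=flank_length + 1,
            end=flank_length + len(seq), strand=strand,
            label=label, family=fam_idx, planted_id=planted_id, sequence=seq,
        ))
        lineages[rid] = _LINEAGES[counter % len(_LINEAGES)]

    n_decoys = ([decoys_per_family] * len(families)
                if isinstance(decoys_per_family, int) else list(decoys_per_family))
    if len(n_decoys) != len(families):
        raise ValueError("decoys_per_family list must match families")
    for fam_idx, spec in enumerate(families):
        members = mutate_preserving_structure(spec)
        for m_idx, member in enumerate(members):
            plant(member, "member", fam_idx, f"fam{fam_idx}_m{m_idx}")
        decoys = scramble_paired_regions(
            spec.seed_sequence, spec.structure, n_decoys[fam_idx],
            rng_seed=spec.rng_seed + 7919,
        )
        for d_idx, decoy in enumerate(decoys):
            plant(decoy, "decoy", fam_idx, f"fam{fam_idx}_d{d_idx}")
    return ToyDatabase(records=records, truth=truth, lineages=lineages)


@dataclass(frozen=True)
class BenchmarkReplicate:
    """One standard recovery benchmark: query, database and offline hits."""

    query_id: str
    query_seq: str
    family: FamilySpec
    database: ToyDatabase
    hit_rows: list[str]

    def write_hit_table(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(self.hit_rows) + "\n")


def make_benchmark_replicate(
    rng_seed: int,
    n_members: int = 8,
    n_decoys: int = 16,
    pair_rate: float = 0.07,
    loop_rate: float = 0.05,
    flank_length: int = 60,
    max_truncation: tuple[int, int] = (10, 10),
) -> BenchmarkReplicate:
    """Build the standard end-to-end recovery fixture for one seed.

    Emulates a *diverse* sRNA family — the regime where sequence identity
    alone cannot decide and the structure filter carries the burden: family
    members evolved along a random lineage with covarying stems (identity
    to the query spanning roughly 60-95%), plus a decoy population of
    stem-scrambled sequences whose identity sits inside the candidate
    window, embedded in flanked genome records together with an offline
    hit table (hits randomly truncated to exercise the extension).
    """
    seq, dot = design_family_seed(rng_seed)
    family = FamilySpec(
        seed_sequence=seq, structure=dot, n_members=n_members,
        substitution_rate=pair_rate, loop_substitution_rate=loop_rate,
        rng_seed=rng_seed + 100, phylogeny="lineage",
    )
    db = make_toy_database([family], decoys_per_family=n_decoys,
                           flank_length=flank_length, rng_seed=rng_seed + 999)
    rows = naive_hit_table(db, "query", seq, max_truncation=max_truncation,
                           rng_seed=rng_seed + 5)
    return BenchmarkReplicate(query_id="query", query_seq=seq,
                              family=family, database=db, hit_rows=rows)


def _ungapped_identity(a: str, b: str) -> float:
    n = min(len(a), len(b))
    return 100.0 * sum(1 for x, y in zip(a, b) if x == y) / n


def naive_hit_table(
    db: ToyDatabase,
    query_id: str,
    query_seq: str,
    path: str | Path | None = None,
    *,
    max_truncation: tuple[int, int] = (0, 0),
    rng_seed: int = 0,
) -> list[str]:
    """Emit a 12-column tabular hit file for every planted locus.

    Stands in for a local-alignment search at toy scale: every planted
    sequence is reported as one hit of the query, optionally truncated by a
    random number of nucleotides (up to ``max_truncation`` = (5', 3')) to
    exercise the asymmetric extension.  Planted sequences are substitution
    -only variants of the query length, so query and subject coordinates
    correspond 1:1.
    """
    rng = random.Random(rng_seed)
    qlen = len(query_seq)
    rows = []
    for t in db.truth:
        if t.end - t.start + 1 != qlen:
            continue  # only same-length plantings map 1:1
        t5 = rng.randint(0, max_truncation[0])
        t3 = rng.randint(0, max_truncation[1])
        if t5 + t3 >= qlen:
            t5 = t3 = 0
        qstart, qend = 1 + t5, qlen - t3
        if t.strand == "plus":
            sstart, send = t.start + t5, t.end - t3
        else:
            sstart, send = t.end - t5, t.start + t3
        frag = t.sequence[t5: qlen - t3]
        pid = _ungapped_identity(query_seq[t5: qlen - t3], frag)
        mism = round((qend - qstart + 1) * (100.0 - pid) / 100.0)
        rows.append("\t".join(map(str, [
            query_id, t.record_id, f"{pid:.2f}", qend - qstart + 1, mism, 0,
            qstart, qend, sstart, send, "1e-10", 100,
        ])))
    if path is not None:
        Path(path).write_text("\n".join(rows) + ("\n" if rows else ""))
    return rows
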