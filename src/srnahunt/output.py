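"""Result emission: homolog FASTA, diversity statistics, taxonomy JSON.

The diversity summary reports the maximum pairwise diversity
``mPD = 100 - min(PI)`` over the accepted homologs — the single number that
says how far beyond trivial near-identical hits the search reached — plus
the mean and median of the per-homolog diversities ``100 - PI``.

The taxonomic tree merges the root-first lineage path of every accepted
hit into one counted tree: a node's count is the number of hits whose path
passes through it.  Hits without a known lineage are collected under an
``unclassified`` child of the root and do not contribute to the root count.
"""

from __future__ import annotations

import json
import statistics
from dataclasses import dataclass, field
from pathlib import Path

from .blastio import write_fasta
from .pipeline import HomologSet

__all__ = [
    "DiversityStats",
    "TaxTreeNode",
    "EmptyResultError",
    "write_homologs_fasta",
    "diversity_summary",
    "build_taxonomic_tree",
    "parse_lineage_tsv",
    "write_taxonomic_json",
]


class EmptyResultError(ValueError):
    """Statistics requested over an empty accepted set."""


def write_homologs_fasta(
    result: HomologSet, path: str | Path,
    taxids: dict[str, str] | None = None,
) -> None:
    """Write query plus accepted homologs (descending PI) as 70-col FASTA.

    Homolog headers:  ``subject_id:start-end(strand)|PI:<pi>|taxid:<id-or-NA>``.
    """
    taxids = taxids or {}
    records = [(result.query_id, result.query_seq)]
    for hom in sorted(result.accepted, key=lambda c: (-c.pi, c.id)):
        tax = taxids.get(hom.extended.subject_id, "NA")
        records.append((f"{hom.id}|PI:{hom.pi:.2f}|taxid:{tax}", hom.sequence))
    write_fasta(path, records, wrap=70)


@dataclass(frozen=True)
class DiversityStats:
    """Diversity of an accepted homolog set relative to the query."""

    mpd: float                 # 100 - min(PI)
    mean_diversity: float      # mean of (100 - PI)
    median_diversity: float    # median of (100 - PI)
    n: int


def diversity_summary(result: HomologSet) -> DiversityStats:
    """mPD, mean and median diversity over the accepted homologs."""
    pis = result.accepted_pis
    if not pis:
        raise EmptyResultError("no accepted homologs to summarise")
    div = [100.0 - pi for pi in pis]
    return DiversityStats(
        mpd=max(div),
        mean_diversity=statistics.fmean(div),
        median_diversity=statistics.median(div),
        n=len(div),
    )


@dataclass
class TaxTreeNode:
    """Counted node of the merged lineage tree."""

    name: str
    taxid: str = ""
    count: int = 0
    children: list["TaxTreeNode"] = field(default_factory=list)

    def child(self, name: str, taxid: str = "") -> "TaxTreeNode":
        for c in self.children:
            if c.name == name:
                return c
        node = TaxTreeNode(name=name, taxid=taxid)
        self.children.append(node)
        return node

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "taxid": self.taxid,
            "count": self.count,
            "children": [c.to_dict() for c in self.children],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TaxTreeNode":
        node = cls(name=d["name"], taxid=d.get("taxid", ""),
                   count=d.get("count", 0))
        node.children = [cls.from_dict(c) for c in d.get("children", [])]
        return node


def parse_lineage_tsv(path: str | Path) -> dict[str, list[str]]:
    """Read ``id <TAB> Root;Phylum;...;Species`` lines into a lineage map."""
    lineages: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            rid, _, path_str = line.partition("\t")
            lineages[rid] = [t.strip() for t in path_str.split(";") if t.strip()]
    return lineages


def build_taxonomic_tree(
    subject_ids: list[str], lineages: dict[str, list[str]],
    root_name: str = "root",
) -> TaxTreeNode:
    """Merge per-hit lineage paths into one counted tree.

    ``subject_ids`` is one entry per accepted hit (duplicates allowed and
    counted); ``lineages`` maps an id to its root-first taxon path.
    """
    root = TaxTreeNode(name=root_name)
    unclassified: TaxTreeNode | None = None
    for sid in subject_ids:
        path = lineages.get(sid)
        if not path:
            if unclassified is None:
                unclassified = root.child("unclassified")
            unclassified.count += 1
            continue
        root.count += 1
        node = root
        for taxon in path:
            node = node.child(taxon)
            node.count += 1
    return root


def write_taxonomic_json(tree: TaxTreeNode, path: str | Path) -> None:
    Path(path).write_text(json.dumps(tree.to_dict(), indent=2) + "\n")
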