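"""Structure-based cluster filtering of candidate homologs ("Londen").

Candidate homologs (52% <= PI <= 70%) share too little sequence with the
query to be accepted outright; what they may still share is the secondary
structure.  The filter proceeds in five steps:

1. *Pre-grouping* — candidates are coarsely grouped by fast k-tuple
   similarity (>= 85% to a representative).  Representatives are picked
   most-distant-to-the-query first, which avoids the chaining artefacts of
   single linkage and keeps near-identical sequences from compressing the
   branch-length scale of the tree below.
2. *Structure distances* — the thermodynamic-ensemble base-pairing profile
   distance (RNApdist) between every pair of representatives, query and
   true-homolog anchors included.
3. *Tree* — a neighbor-joining tree over that distance matrix.
4. *Inconsistent-edge cutting* — every edge e = (i, j) with length L^e is
   compared against lambda times the mean length M_i (M_j) of the other
   edges at its endpoints; edges exceeding the cutting radius on one end
   (single-cut mode) or both ends (double-cut mode) are removed.  The
   stringency factor lambda is set manually or auto-scaled from the query
   length and the diversity ratio r = alpha/beta (alpha = #sequences with
   PI >= 60, beta = #sequences with PI < 60, floored at 2).
5. *Cluster selection* — connected components that contain the query or a
   true-homolog anchor are positive; their candidate representatives, and
   transitively all their pre-group members, are accepted.
"""

from __future__ import annotations

import logging
import math
import shutil
import tempfile
import subprocess
from dataclasses import dataclass

import networkx as nx
import numpy as np
from skbio import DistanceMatrix as _SkbioDM
from skbio.tree import nj as _skbio_nj

from .seqident import ktuple_similarity, normalize_sequence

logger = logging.getLogger(__name__)

__all__ = [
    "PreGrouping",
    "LondenParams",
    "CutDecision",
    "InvalidMatrixError",
    "StructureBackendError",
    "pregroup_candidates",
    "structure_distance_matrix",
    "build_nj_tree",
    "auto_lambda",
    "cut_edges",
    "cut_decisions",
    "select_positive_clusters",
    "structure_filter",
    "tree_to_newick",
]

LAMBDA_CAP = 2.4          # auto-mode ceiling on the stringency factor
LAMBDA_MANUAL_RANGE = (0.0, 3.0)
PREGROUP_THRESHOLD = 85.0  # percent k-tuple similarity for group absorption
PI_DIVERSITY_SPLIT = 60.0  # PI split defining the diversity ratio r


class InvalidMatrixError(ValueError):
    """Distance matrix is not symmetric or contains NaN."""


class StructureBackendError(RuntimeError):
    """The requested structure-distance backend is not usable."""


# ---------------------------------------------------------------------------
# Pre-grouping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PreGrouping:
    """Partition of sequences into >=85%-similarity groups.

    ``groups`` maps each representative id to its member ids (representative
    included); ``order`` lists representatives in selection order, i.e.
    ascending PI to the query at the time of selection.
    """

    groups: dict[str, list[str]]
    order: list[str]

    def members_of(self, representative: str) -> list[str]:
        return self.groups[representative]


def pregroup_candidates(
    candidates: list[tuple[str, str, float]],
    threshold: float = PREGROUP_THRESHOLD,
    k: int = 2,
) -> PreGrouping:
    """Group sequences around most-distant-to-query representatives.

    ``candidates`` holds ``(id, sequence, PI-to-query)`` triples.  Repeatedly
    the remaining sequence with the lowest PI becomes a representative and
    absorbs every remaining sequence with k-tuple similarity >= ``threshold``
    to it.
    """
    if not (0 < threshold <= 100):
        raise ValueError("threshold must be in (0, 100]")
    remaining = sorted(candidates, key=lambda c: (c[2], c[0]))
    groups: dict[str, list[str]] = {}
    order: list[str] = []
    while remaining:
        rep_id, rep_seq, _ = remaining[0]
        members = [rep_id]
        rest = []
        for cid, cseq, cpi in remaining[1:]:
            if ktuple_similarity(rep_seq, cseq, k) >= threshold:
                members.append(cid)
            else:
                rest.append((cid, cseq, cpi))
        groups[rep_id] = members
        order.append(rep_id)
        remaining = rest
    return PreGrouping(groups=groups, order=order)


# ---------------------------------------------------------------------------
# Structure distances
# ---------------------------------------------------------------------------

def _profile_distance_vienna(seqs: list[str]) -> np.ndarray:
    """Ensemble base-pairing profile distances via the ViennaRNA bindings.

    Reproduces the RNApdist computation: partition-function fold per
    sequence, per-position pairing profile, profile edit distance per pair.
    """
    try:
        import RNA
    except ImportError as exc:  # pragma: no cover - bindings ship with ViennaRNA
        raise StructureBackendError("ViennaRNA python bindings unavailable") from exc

    profiles = []
    try:
        for s in seqs:
            RNA.pf_fold(s)
            profiles.append(RNA.Make_bp_profile(len(s)))
            RNA.free_pf_arrays()
        n = len(seqs)
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d = RNA.profile_edit_distance(profiles[i], profiles[j])
                D[i, j] = D[j, i] = max(0.0, float(d))
        return D
    finally:
        for p in profiles:
            RNA.free_profile(p)


def _pair_profiles_internal(seq: str) -> np.ndarray:
    """(P_paired_downstream, P_paired_upstream, P_unpaired) per position."""
    import RNA

    fc = RNA.fold_compound(seq)
    fc.pf()
    bpp = np.array(fc.bpp())  # (n+1) x (n+1), 1-indexed upper triangle
    n = len(seq)
    down = bpp[1 : n + 1, 1 : n + 1].sum(axis=1)   # i pairs with j > i
    up = bpp[1 : n + 1, 1 : n + 1].sum(axis=0)     # i pairs with j < i
    unpaired = np.clip(1.0 - up - down, 0.0, 1.0)
    return np.column_stack([down, up, unpaired])


def _profile_align_distance(pa: np.ndarray, pb: np.ndarray) -> float:
    """End-gap-penalised global alignment of two pairing-profile matrices.

    Column substitution cost is the Euclidean distance between profile
    vectors; a gapped column costs its distance to the fully-unpaired
    profile plus a small opening increment, so runs of unpaired positions
    are cheap to skip but paired columns are not.
    """
    gap_vec = np.array([0.0, 0.0, 1.0])
    gap_bonus = 0.1
    na, nb = len(pa), len(pb)
    gap_a = np.linalg.norm(pa - gap_vec, axis=1) + gap_bonus
    gap_b = np.linalg.norm(pb - gap_vec, axis=1) + gap_bonus
    D = np.empty((na + 1, nb + 1))
    D[0, 0] = 0.0
    D[1:, 0] = np.cumsum(gap_a)
    D[0, 1:] = np.cumsum(gap_b)
    for i in range(1, na + 1):
        sub = np.linalg.norm(pa[i - 1] - pb, axis=1)
        row_prev = D[i - 1]
        row = D[i]
        for j in range(1, nb + 1):
            row[j] = min(
                row_prev[j - 1] + sub[j - 1],
                row_prev[j] + gap_a[i - 1],
                row[j - 1] + gap_b[j - 1],
            )
    return float(D[na, nb])


def _profile_distance_internal(seqs: list[str]) -> np.ndarray:
    profiles = [_pair_profiles_internal(s) for s in seqs]
    n = len(seqs)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = _profile_align_distance(profiles[i], profiles[j])
    return D


def _profile_distance_rnapdist_binary(seqs: list[str]) -> np.ndarray:
    """Distances via the RNApdist executable (used as an external oracle)."""
    if shutil.which("RNApdist") is None:
        raise StructureBackendError("RNApdist executable not on PATH")
    fasta = "".join(f">s{i}\n{s}\n" for i, s in enumerate(seqs))
    # run in a scratch directory: the tool drops *_dp.ps plots in its cwd
    with tempfile.TemporaryDirectory(prefix="srnahunt_pdist_") as tmp:
        proc = subprocess.run(
            ["RNApdist", "-Xm"], input=fasta, capture_output=True, text=True,
            cwd=tmp,
        )
    if proc.returncode != 0:
        raise StructureBackendError(f"RNApdist failed: {proc.stderr.strip()}")
    values: list[float] = []
    for line in proc.stdout.splitlines():
        line = line.strip()
        if not line or line.startswith(">"):
            continue
        values.extend(float(tok) for tok in line.split())
    n = len(seqs)
    D = np.zeros((n, n))
    it = iter(values)
    for i in range(1, n):
        for j in range(i):
            v = max(0.0, next(it))
            D[i, j] = D[j, i] = v
    return D


_BACKENDS = {
    "bindings": _profile_distance_vienna,
    "internal": _profile_distance_internal,
    "rnapdist": _profile_distance_rnapdist_binary,
}


def structure_distance_matrix(
    seqs: list[tuple[str, str]], backend: str = "rnapdist"
) -> tuple[np.ndarray, list[str]]:
    """Pairwise secondary-structure ensemble distance matrix.

    ``backend`` is ``"bindings"`` (ViennaRNA python bindings, default),
    ``"internal"`` (own partition-function pairing-profile distance) or
    ``"rnapdist"`` (the external executable).  Returns ``(matrix, ids)``;
    the matrix is symmetric, non-negative with a zero diagonal.
    """
    if len(seqs) < 2:
        raise ValueError("need at least two sequences for a distance matrix")
    ids = [sid for sid, _ in seqs]
    norm = []
    for sid, s in seqs:
        ns = normalize_sequence(s, name=sid)
        if len(ns) < 4:
            raise ValueError(f"{sid}: too short to fold (< 4 nt)")
        norm.append(ns.replace("T", "U"))
    try:
        fn = _BACKENDS[backend]
    except KeyError:
        raise StructureBackendError(f"unknown structure backend {backend!r}") from None
    return fn(norm), ids


# ---------------------------------------------------------------------------
# Neighbor-joining tree
# ---------------------------------------------------------------------------

def build_nj_tree(D: np.ndarray, labels: list[str]) -> nx.Graph:
    """Canonical neighbor-joining tree as an undirected weighted graph.

    Leaves carry the input labels; internal nodes are named ``_nj<i>``.
    Negative branch lengths (an NJ artefact on non-additive matrices) are
    clamped to zero.  Edge lengths live in the ``length`` edge attribute;
    leaf nodes carry ``leaf=True``.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1] or D.shape[0] != len(labels):
        raise InvalidMatrixError("matrix shape inconsistent with labels")
    if np.isnan(D).any():
        raise InvalidMatrixError("matrix contains NaN")
    if not np.allclose(D, D.T, atol=1e-8):
        raise InvalidMatrixError("matrix is not symmetric")
    D = (D + D.T) / 2.0  # remove float jitter before strict NJ validation

    g = nx.Graph()
    for lab in labels:
        g.add_node(lab, leaf=True)
    n = len(labels)
    if n == 1:
        return g
    if n == 2:
        g.add_edge(labels[0], labels[1], length=max(0.0, float(D[0, 1])))
        return g

    tree = _skbio_nj(_SkbioDM(D, labels))
    counter = 0
    for node in tree.traverse(include_self=True):
        if node.name is None:
            counter += 1
            node.name = f"_nj{counter}"
            g.add_node(node.name, leaf=False)
    for node in tree.traverse(include_self=False):
        length = max(0.0, float(node.length or 0.0))
        g.add_edge(node.parent.name, node.name, length=length)
    # skbio roots the unrooted NJ result; a degree-2 root is an artefact —
    # splice it out so internal nodes all have degree 3.
    for node in [x for x in g.nodes if g.degree(x) == 2 and not g.nodes[x]["leaf"]]:
        (a, da), (b, db) = [(nbr, g.edges[node, nbr]["length"])
                            for nbr in g.neighbors(node)]
        g.remove_node(node)
        g.add_edge(a, b, length=da + db)
    return g


def tree_to_newick(g: nx.Graph) -> str:
    """Serialize the (unrooted) tree graph to Newick, rooted arbitrarily."""
    root = next(n for n in sorted(g.nodes(), key=str) if not g.nodes[n].get("leaf"))\
        if any(not g.nodes[n].get("leaf") for n in g.nodes) else next(iter(g.nodes))

    def rec(node, parent) -> str:
        children = [nbr for nbr in g.neighbors(node) if nbr != parent]
        if not children:
            return str(node)
        inner = ",".join(
            f"{rec(c, node)}:{g.edges[node, c]['length']:.6g}" for c in children
        )
        name = "" if str(node).startswith("_nj") else str(node)
        return f"({inner}){name}"

    return rec(root, None) + ";"


# ---------------------------------------------------------------------------
# Stringency factor
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LondenParams:
    """Cutting parameters: stringency factor, mode and their provenance."""

    lambda_: float
    mode: str                      # "single" | "double"
    auto: bool = True
    r: float = float("nan")        # diversity ratio alpha / beta
    alpha: int = 0                 # sequences with PI >= 60
    beta: int = 0                  # sequences with PI < 60, floored at 2
    L: int = 0                     # query length, nt

    def __post_init__(self) -> None:
        if self.mode not in ("single", "double"):
            raise ValueError("mode must be 'single' or 'double'")
        if self.lambda_ < 0:
            raise ValueError("lambda must be non-negative")


def auto_lambda(candidate_pis: list[float], L: int) -> LondenParams:
    """Auto-scale the stringency factor from diversity and query length.

    r = alpha/beta with alpha = #(PI >= 60), beta = max(#(PI < 60), 2).
    Diverse inputs (r < 1) use single-cut mode with
    lambda = min(0.29*log10(L) + r, 2.4); homogeneous inputs (r >= 1) use
    double-cut mode with lambda = min(0.01*log10(L) + r, 2.4).  Short
    queries carry less sequence information, hence the stricter (smaller)
    lambda at small L.
    """
    if L < 1:
        raise ValueError("query length must be >= 1")
    alpha = sum(1 for pi in candidate_pis if pi >= PI_DIVERSITY_SPLIT)
    beta = max(sum(1 for pi in candidate_pis if pi < PI_DIVERSITY_SPLIT), 2)
    r = alpha / beta
    if r < 1:
        mode = "single"
        lam = min(0.29 * math.log10(L) + r, LAMBDA_CAP)
    else:
        mode = "double"
        lam = min(0.01 * math.log10(L) + r, LAMBDA_CAP)
    return LondenParams(lambda_=lam, mode=mode, auto=True,
                        r=r, alpha=alpha, beta=beta, L=L)


def manual_lambda(lambda_: float, single_cut: bool = False) -> LondenParams:
    """Manually chosen stringency factor (clamped to [0, 3]); double-cut
    mode unless the single-cut switch is set."""
    lo, hi = LAMBDA_MANUAL_RANGE
    lam = min(max(lambda_, lo), hi)
    return LondenParams(lambda_=lam, mode="single" if single_cut else "double",
                        auto=False)


# ---------------------------------------------------------------------------
# Edge cutting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CutDecision:
    """Outcome of the cutting rule for one edge."""

    edge: tuple[str, str]
    length: float
    M_i: float | None   # mean neighbor-edge length at endpoint i (None at leaves)
    M_j: float | None
    removed: bool
    mode: str


def _mean_other_edges(g: nx.Graph, node, edge) -> float | None:
    others = [g.edges[node, nbr]["length"] for nbr in g.neighbors(node)
              if frozenset((node, nbr)) != frozenset(edge)]
    if not others:
        return None
    return sum(others) / len(others)


def cut_decisions(g: nx.Graph, params: LondenParams) -> list[CutDecision]:
    """Evaluate the inconsistent-edge rule on every edge of the tree.

    An edge is inconsistent when its length exceeds the cutting radius
    lambda * M at one endpoint (single mode: OR over defined means) or at
    both (double mode: AND; a pendant edge, whose leaf endpoint has no
    other edges and hence no defined mean, is never removed in double
    mode).  The comparison is strict (``>``): an edge exactly on the radius
    survives.
    """
    decisions = []
    lam = params.lambda_
    for i, j in sorted(g.edges(), key=lambda e: tuple(sorted(map(str, e)))):
        L = g.edges[i, j]["length"]
        M_i = _mean_other_edges(g, i, (i, j))
        M_j = _mean_other_edges(g, j, (i, j))
        exceeds = [L > lam * M for M in (M_i, M_j) if M is not None]
        if params.mode == "single":
            removed = any(exceeds)
        else:
            removed = len(exceeds) == 2 and all(exceeds)
        decisions.append(CutDecision(edge=(str(i), str(j)), length=L,
                                     M_i=M_i, M_j=M_j, removed=removed,
                                     mode=params.mode))
    return decisions


def cut_edges(g: nx.Graph, params: LondenParams) -> list[set[str]]:
    """Remove inconsistent edges; return leaf-id clusters (the forest).

    Components containing no leaf (possible when several internal edges
    fall) contribute no cluster.
    """
    decisions = cut_decisions(g, params)
    pruned = g.copy()
    pruned.remove_edges_from([d.edge for d in decisions if d.removed])
    clusters = []
    for comp in nx.connected_components(pruned):
        leaves = {str(n) for n in comp if g.nodes[n].get("leaf")}
        if leaves:
            clusters.append(leaves)
    return clusters


def select_positive_clusters(
    clusters: list[set[str]],
    references: set[str],
    grouping: PreGrouping | None = None,
    query_id: str | None = None,
) -> set[str]:
    """Accept every leaf sharing a cluster with a reference sequence.

    References are the query and the true-homolog representatives.
    Acceptance propagates from a representative to all its pre-group
    members.  Raises if the query leaf is missing from the forest
    (internal inconsistency).
    """
    all_leaves = set().union(*clusters) if clusters else set()
    if query_id is not None and query_id not in all_leaves:
        raise RuntimeError(f"query leaf {query_id!r} absent from the cluster forest")
    accepted: set[str] = set()
    for cluster in clusters:
        if cluster & references:
            accepted |= cluster - references
    if grouping is not None:
        for rep in list(accepted):
            if rep in grouping.groups:
                accepted |= set(grouping.members_of(rep))
    return accepted


# ---------------------------------------------------------------------------
# Full filter
# ---------------------------------------------------------------------------

def structure_filter(
    query_id: str,
    query_seq: str,
    true_homologs: list[tuple[str, str, float]],
    candidates: list[tuple[str, str, float]],
    *,
    lambda_params: LondenParams | None = None,
    backend: str = "rnapdist",
    pregroup_threshold: float = PREGROUP_THRESHOLD,
    ktuple_k: int = 2,
) -> set[str]:
    """Run the whole structure filter; return accepted candidate ids.

    ``true_homologs`` and ``candidates`` hold ``(id, sequence, PI)``
    triples.  When ``lambda_params`` is None the stringency factor is
    auto-scaled from all PIs and the query length.
    """
    if not candidates:
        return set()
    cand_groups = pregroup_candidates(candidates, pregroup_threshold, ktuple_k)
    true_groups = pregroup_candidates(true_homologs, pregroup_threshold, ktuple_k) \
        if true_homologs else PreGrouping({}, [])

    seq_of = {cid: cseq for cid, cseq, _ in candidates}
    seq_of.update({tid: tseq for tid, tseq, _ in true_homologs})
    leaves = [(query_id, query_seq)]
    leaves += [(rep, seq_of[rep]) for rep in true_groups.order]
    leaves += [(rep, seq_of[rep]) for rep in cand_groups.order]

    if lambda_params is None:
        pis = [pi for _, _, pi in true_homologs] + [pi for _, _, pi in candidates]
        lambda_params = auto_lambda(pis, len(query_seq))
    logger.info(
        "structure filter: %d candidate groups, %d anchor groups, "
        "lambda=%.3f (%s mode)",
        len(cand_groups.order), len(true_groups.order),
        lambda_params.lambda_, lambda_params.mode,
    )

    if len(leaves) == 1:
        return set()
    D, ids = structure_distance_matrix(leaves, backend=backend)
    tree = build_nj_tree(D, ids)
    clusters = cut_edges(tree, lambda_params)
    references = {query_id} | set(true_groups.order)
    accepted_reps = select_positive_clusters(
        clusters, references, grouping=None, query_id=query_id
    )
    accepted: set[str] = set()
    for rep in accepted_reps:
        if rep in cand_groups.groups:
            accepted |= set(cand_groups.members_of(rep))
    return accepted
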