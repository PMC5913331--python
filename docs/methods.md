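# Methods

This note records the model assumptions, parameter choices and numerical
conventions behind `srnahunt`, and what the synthetic benchmark does and
does not demonstrate.

## Sequence comparison

Percent identity (PI) is computed from one optimal global alignment:
identical columns divided by total alignment columns, gaps included. The
scoring is match +2, mismatch −1, and an affine-like gap cost where a gap
of length *g* costs 0.5 + 0.1·(*g* − 1); end gaps are penalised (true
global mode). The alignment itself is delegated to Biopython's
`PairwiseAligner`, whose gap semantics match this definition exactly.
Among co-optimal alignments the aligner's first traceback is used — it is
deterministic, and because PI canonicalises its argument order (shorter /
lexicographically smaller sequence first) the reported PI is exactly
symmetric, which the rest of the pipeline assumes. `U` is normalised to
`T` before any comparison; `N` scores as a mismatch and never counts as an
identical column, so ambiguous draft-genome positions cannot inflate PI.

The pre-grouping stage uses a k-tuple similarity instead of alignment:
shared k-mers counted with multiplicity (capped pairwise) over the word
count of the shorter sequence, k = 2 by default. This is a multiset
measure, not positional: two sequences of similar composition score high
even when the word order differs. That coarseness is acceptable — and in
practice useful — because the measure is only ever compared against the
85% grouping threshold to merge near-identical sequences, and composition
look-alikes that slip into one group are still judged collectively by the
structure filter through their representative.

## Hit extension and coordinates

All coordinates are 1-based inclusive, BLAST's native convention, with
`sstart > send` denoting a minus-strand hit. Extension widens the subject
region by exactly the query-side deficits; insertions or deletions inside
the local hit are deliberately ignored (they shift the ideal extension by
at most the indel length, which the downstream global alignment absorbs).
Extensions running past a contig end are truncated silently but the
truncated amounts are kept on the record (`clamped_5p/3p`), because
dropping boundary hits would systematically lose homologs on draft
assemblies. Classification in *every* round is against the original query,
never the round's seed, so PI values remain comparable across rounds.

Duplicate collapsing treats two records as one locus when they share
subject, strand and at least one overlapping nucleotide; the
earliest-found record wins. Identical sequences at distinct loci are kept
separately — repeated genes are genuinely distinct homologs.

## Structure distances

Three interchangeable backends produce the candidate distance matrix:

* `rnapdist` (default): the RNApdist executable, i.e. the thermodynamic
  ensemble base-pairing-profile distance.
* `bindings`: the same computation through the ViennaRNA Python bindings
  (`pf_fold` → `Make_bp_profile` → `profile_edit_distance`); verified in
  the test suite to agree with the executable to printed precision.
* `internal`: a self-contained fallback — per-position profiles
  (P(paired downstream), P(paired upstream), P(unpaired)) from the
  partition-function base-pair matrix, compared by an end-gap-penalised
  global alignment of profile columns with Euclidean column cost and a gap
  cost equal to the column's distance from the fully-unpaired profile plus
  a 0.1 opening increment. It reproduces the default backend's qualitative
  behavior (structure-preserving mutants score closer than shuffles;
  asserted on fixtures), not its absolute scale.

The executable is the default rather than the bindings purely for process
hygiene: the SWIG-level profile objects emit unsuppressible destructor
warnings in long-running processes; the numbers are identical.

## Tree building and cutting

Neighbor joining is scikit-bio's canonical Saitou–Nei implementation;
the skbio tree is converted to an undirected weighted graph, an artefactual
degree-2 root is spliced out, and negative branch lengths (an NJ artefact
on non-additive matrices) are clamped to zero. Tests confirm exactness on
additive matrices: every split and branch length of the generating tree is
recovered (Robinson–Foulds distance 0, lengths within 1e-9).

Edge cutting follows the inconsistency rule with strict inequality
(`L > λ·M`; an edge exactly on the radius survives). Conventions for the
cases the rule leaves open:

* **Pendant edges.** The mean `M` is undefined at a leaf. In single-cut
  mode the internal endpoint's radius alone can sever a pendant edge; in
  double-cut mode pendant edges are exempt (both radii are required).
  A consequence worth knowing: double-cut mode can never isolate a single
  outlier leaf — it separates clades, not points.
* **Zero-length neighborhoods.** When `M = 0`, any positive edge exceeds
  the radius, while zero-length edges themselves never fall (0 > 0 is
  false), so groups of identical structures stay together.
* **Determinism.** Edges are evaluated in sorted label order and the rule
  is local per edge, so results are independent of traversal order; ties
  in NJ are resolved by scikit-bio's deterministic implementation.

The tree contains the query plus one representative per pre-group of true
homologs and of candidates. Representatives are chosen
most-distant-from-the-query first, which prevents both chaining and the
collapse of the branch-length scale by near-duplicates. Manual λ is
clamped to [0, 3] and implies double-cut mode unless the single-cut switch
is set; automatic λ is capped at 2.4.

## Synthetic benchmark: what it emulates

`make_benchmark_replicate` freezes the study conditions for the recovery
benchmark:

* **Query/seed**: a designed 119-nt, three-hairpin sRNA-like sequence
  (stems 13 bp, loops 6 nt, ~66% of positions paired) — mid-range length
  for bacterial sRNAs, with a terminator-like 3' hairpin. The high paired
  fraction pins the decoys (below) inside the candidate PI window.
* **Members** (n = 8): evolved along a random lineage (each member
  descends from a randomly chosen earlier member), stems mutating
  compensatorily at 0.07 per pair per branch (random Watson–Crick/GU
  replacement), loops at 0.05 per site per branch. This reproduces the
  classic covariation signature of structured RNAs and yields the
  hierarchical distance structure of a real family; identities to the
  query span roughly 65–98%.
* **Decoys** (n = 16): the seed with its paired-position bases permuted,
  loops intact — identity to the query ~52–60% (inside the candidate
  window, so only the structure filter can reject them), structure
  destroyed.
* **Embedding**: each planted sequence sits in its own contig-like record
  with 60-nt random flanks on a random strand; an offline hit table is
  produced from the truth coordinates with up to 10 nt of random
  truncation per end, exercising the asymmetric extension.

Under these conditions the candidate set is diversity-dominated
(r < 1), so the automatic λ selects single-cut mode — the regime where the
structure filter actually discriminates, consistent with the general
principle that structure information matters most where sequence
conservation is weakest. Measured over 20 seeded replicates at default
configuration: 98.8% of planted members accepted, 0% of decoys.

What the benchmark does **not** show:

* Real genomic background (flanks are uniform random, no repeats, no
  paralogy) and real BLAST statistics — offline hit tables report every
  planted locus, so sensitivity of the word-based search itself is tested
  only by the separate live-backend test.
* Family members here are mostly above the 70% true-homolog threshold, so
  member recovery is dominated by the PI classification; the structure
  filter's burden in the benchmark is decoy rejection. When member
  divergence is pushed deeper into the candidate window, recovery degrades
  (the diverse regime forces a small λ, and single-cut then severs some
  genuine members from the query cluster) — an inherent trade-off of the
  scale-free cutting rule, not a fixture artefact.
* Equidistant ("star") families are pathological for the method: NJ gives
  them near-zero internal edges, and relative-length cutting shatters
  them. The generator's lineage mode exists precisely because real
  families are hierarchical; the star mode remains available for stress
  testing.

## Degenerate inputs and numerical conventions

* n = 1 sequences yield a single-node tree; n = 2 a single edge, which no
  mode can cut (both endpoints are leaves).
* Sequences shorter than 4 nt are rejected by the structure backends.
* RNApdist occasionally reports tiny negative distances for identical
  sequences (floating point); distances are clamped to ≥ 0.
* β in the diversity ratio is floored at 2 even when no sequence falls
  below PI 60, following the published formula; the alternative reading
  (disable auto mode when β < 2) would leave λ undefined exactly where
  the filter is most needed.
* The per-interval re-seeding subsample is evenly spaced across the
  PI-sorted bucket (ties broken by locus id) — deterministic, and spreads
  the next round's seeds over the whole identity range.

## Known limitations

* Offline multi-round iteration requires one hit table per round; rounds
  beyond the supplied tables simply stop the iteration.
* Taxonomy is a user-supplied lineage TSV; no live taxonomy lookups, and
  hits without a lineage are counted under an `unclassified` node rather
  than resolved.
* The k-tuple measure's compositional blindness means decoy sets derived
  from a common source can share one pre-group; their fate is then decided
  by a single representative. For decoy *rejection* this is conservative
  in effect but coarse; a positional word measure would refine it.
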