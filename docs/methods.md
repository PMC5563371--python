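# Methods

This note records what `bgcnet` computes, the assumptions behind each
stage, the parameters that matter, and the choices made where the
design was genuinely open.

## Inputs and annotation model

The unit of analysis is an annotated **cluster record**: a BGC class
label (antiSMASH v3 product strings: `nrps`, `t1pks`, `t3pks`,
`t1t3pks`, `nrps-t1pks`, `transat-pks-nrps`, `bacteriocin`, `terpene`,
`siderophore`, ...), a genomic span, an ordered list of CDS, and a list
of enzymatic domain annotations.  A CDS counts as *biosynthetic* iff
any line of its `sec_met` qualifier carries a biosynthetic `Kind:`
classification; the raw qualifier text is retained for auditing.
Domain features (`aSDomain`) link to genes by `locus_tag` (falling back
to coordinate containment) and carry per-predictor substrate calls in
`specificity` qualifiers plus, optionally, the 10-residue adenylation
binding-pocket signature.

Coordinates are 1-based inclusive in all public containers (the GenBank
convention); Biopython's 0-based half-open locations are converted at
the I/O boundary only.  Minus-strand CDS store their translation N→C;
the genomic start still orders genes, and domain order within
minus-strand genes is reversed at parse time so `order_index` is always
protein order.

Genome statistics are: total length, fragment (contig) count, and
GC% = 100·(G+C)/(A+C+G+T) over unambiguous bases (N excluded from both
numerator and denominator; an all-N assembly is an error, not GC 0).

## Pairwise cluster comparison

Clusters are compared through the concatenation (genomic order) of
their biosynthetic-gene translations.  Alignment is true global
Needleman–Wunsch with Gotoh affine gaps:

- substitution matrix BLOSUM62, with `X` scoring 0 against everything
  (including itself) so unknown residues are neutral;
- gap of length *k* costs `10 + k` (open 10, extend 1), end gaps fully
  penalized;
- traceback prefers diagonal, then up, then left, and within gap states
  opening from a match state over extending, making results
  deterministic.

Because co-optimal alignments can differ in their column statistics,
the pair is ordered canonically (longer first, ties lexicographic)
before alignment, so `align(a,b)` and `align(b,a)` report identical
numbers.  The implementation is a numba-compiled DP over the three
Gotoh state matrices; the test suite checks it pairwise-exhaustively
against a memoized brute-force recursion (score, and membership of the
reported (identity, gaps) pair in the set attained by optimal
alignments) and cross-checks scores against Biopython's
`PairwiseAligner` under identical scoring.

Two statistics summarize an alignment of lengths `len(q)`, `len(t)`:

- **identity** = identical columns / `L_al` (gap columns count against
  identity);
- **coverage** = `(L_al − Gaps) / L_long`, with `Gaps` the number of
  gap-containing columns.  Under this reading the numerator is exactly
  the number of residue-to-residue columns, so coverage is bounded by 1
  and reaches 1 iff the alignment is gapless and the inputs equal
  length.  (Counting gap-*open* events instead would not bound the
  index; the column reading is the one used throughout.)

**Network thresholds.**  An edge requires identity ≥ 0.35 (inclusive)
and coverage > 0.10 (strict); both are configurable and applied
conjunctively — their order is immaterial.  Isolated clusters remain in
the node set.  Comparison against reference clusters (MIBiG-style
GenBank) uses the same alignment with both thresholds disabled;
reference–reference pairs are not aligned (references are context).
Networks are `networkx` graphs exported as GraphML or TSV edge lists;
re-import reproduces all attributes.

## Domain architectures and backbones

Module segmentation is greedy and left-to-right over the cluster's full
gene-ordered, N→C domain-label list: each condensation/heterocyclization
opens an NRPS candidate and each KS a PKS candidate; tailoring domains
(KR, DH, ER, epimerization, TE, aminotransferase, docking) attach to
the open module.  A module is complete-NRPS iff it also contains
AMP-binding and PCP before the next opener, complete-PKS iff AT and ACP
(a KS–KR pair, for instance, is `incomplete`).  Domains preceding the
first opener form an implicit incomplete module; a standalone
adenylation domain there (or trailing, as in clusters ending in extra A
domains) still contributes a backbone position, and trailing incomplete
modules are flagged in the architecture report.

Backbone prediction is one monomer token per adenylation domain, in
order.  The vote pools the annotated per-predictor calls with the
native signature match (below) and requires a **strict majority**
(> 50% of informative calls); ties, no calls, and non-informative
tokens (`nrp`, `unk`, ...) all render as `x`.  Tokens format as
capitalized three-letter codes joined by dashes: `Gly-Thr-Tyr-...-x`.
The vote is order-independent by construction.

The native matcher compares a domain's 10-residue binding-pocket
signature positionally against a reference signature→monomer table and
returns the best-matching monomer with its match count; a cross-monomer
tie returns `x`.  The packaged table
(`data/stachelhaus_signatures.synthetic.tsv`) is **synthetic** — a
constructed, internally consistent stand-in for curated
specificity-code collections, adequate for fixtures — and users can
substitute their own TSV.

## Phylogenies

- **Redundancy reduction** (CD-HIT-style): sequences processed
  longest-first; each joins the first representative with global
  identity ≥ 0.95, else founds a cluster.  Identity here is identical
  columns / shorter length, so a fragment identical to part of a longer
  representative clusters with it.
- **Progressive MSA**: pairwise 3-mer distances → NJ guide order →
  profile–profile Needleman–Wunsch merges (sum-of-pairs column scores
  from BLOSUM62 for proteins or +5/−4 with neutral N for nucleotides;
  linear gap 8).  The aligner targets validity and downstream topology
  recovery, not column-identical agreement with any particular external
  tool; its invariants (equal row lengths, ungapping recovers inputs,
  pairwise case optimal under its scoring) are tested directly.
- **Trimming**: columns with gap fraction > 0.5 (configurable) are
  dropped, preserving order; 16S-style equal-length trimming instead
  removes every column covered by any row's terminal gap run.
- **Distances**: computed over columns where both rows are ungapped;
  models are p-distance, Jukes–Cantor `−(3/4)ln(1 − 4p/3)` and Kimura
  2-parameter for nucleotides, and Poisson `−ln(1 − p)` for proteins.
  Saturated pairs are capped (default 10 substitutions/site) and
  flagged.  This closed-form family replaces composite-likelihood
  estimation deliberately: each value is independently checkable.
- **Neighbor joining**: standard Saitou–Nei with the Q-criterion; ties
  break on the lowest index pair, negative branch lengths clamp to zero
  (logged).  On additive matrices the algorithm is exact, which the
  suite exploits (100 random 4–7-taxon trees recovered to 1e-9); on
  noisy matrices its topology is cross-checked against scikit-bio's NJ.
  NJ (deterministic, fully specified) is used for both domain trees and
  16S trees; approximate-ML heuristics are intentionally out of scope.
- **Bootstrap**: columns resampled with replacement (seeded NumPy
  generator), each replicate re-distanced and re-joined; support of an
  internal edge is the fraction of replicate trees containing its
  bipartition, written as internal node labels in Newick.
- **Subtree extraction**: the clade under the most recent common
  ancestor of the query leaves (on the rooted representation),
  preserving branch lengths and supports; non-query leaves inside the
  spanned clade are retained, mirroring the usual interactive-viewer
  workflow.

## Synthetic data: what it emulates and what it does not

The generator reproduces the *statistical* structure the analysis
relies on: families of clusters at a controlled expected identity
(ancestor mutated per gene with Binomial(len, 1 − target) uniform
substitutions — uniform so realized identity is analytically
predictable; matrix-biased substitution is available but off by
default), unrelated clusters at ~5% background identity (i.i.d. uniform
ancestors, safely below the 35% threshold), per-predictor substrate
calls with an exact agreement count (an `x` substrate engineers a
three-way tie), both strands, and multiple BGC classes per genome.
Default study conditions: families of 5 members at target identity
0.80, genes of 200–400 aa, 2–4 genes per cluster, 3 predictors.

It does **not** emulate: realistic nucleotide backbones outside cluster
spans (placeholder Ns), codon-level evolution, domain boundaries within
real protein folds, indel-rich divergence (indels optional,
default off), or antiSMASH's detection behavior.  Passing tests
therefore demonstrate correctness of the *comparison machinery* under
known ground truth, not detection performance on real genomes.
Sequence evolution along trees (for phylogeny validation) is a simple
per-edge substitution process with probability `1 − exp(−b)` per site —
adequate for topology-recovery checks, not a calibrated simulator.

## Numerical and degenerate-input choices

- Alignment scores are float64; score equality in tests uses 1e-9.
- Empty sequences, non-amino-acid characters, signatures ≠ 10 residues,
  all-N assemblies, domains referencing unknown genes, <3 taxa for NJ,
  and pairs with zero comparable columns are errors, not warnings.
- Clusters without biosynthetic genes are excluded from networks with a
  logged notice; per-file parse failures in a directory run are logged
  and skipped, and an entirely empty input directory aborts the run
  before any output is written.
- Pipeline reruns with the same seed and `deterministic=true` are
  byte-identical (timestamps suppressed).
- Reported problem sizes were chosen for fast, deterministic test
  cycles: the default fixture set has 11 clusters across 5 genomes;
  the acceptance computations use 200 sequences for the alignment
  oracle sweep, 100 random trees for NJ recovery, and 200 bootstrap
  replicates (the pipeline default remains 1000).

## Known limitations

- The similarity statistics depend on the configured scoring scheme;
  the original survey's aligner parameters are not recoverable, so
  absolute identity values are comparable within `bgcnet` runs, not
  across tools.  The coverage index compensates for length differences
  but not for domain rearrangements.
- The packaged specificity table is synthetic; real substrate
  prediction requires a curated table (drop-in TSV).
- The progressive aligner is a baseline; for large or highly divergent
  sets an external MSA can be imported as aligned FASTA and fed to the
  trimming/distance/NJ stages unchanged.
- Greedy redundancy reduction is order-dependent (longest-first, ties
  by id), matching the classic tool's behavior but not any particular
  version exactly.
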