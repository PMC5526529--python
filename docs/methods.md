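# Methods

This note documents the models and conventions implemented in `mitoaudit`,
the design choices made where the design was genuinely open, and what the
synthetic benchmark does and does not establish about real data.

## Coordinates and data structures

Genome coordinates are 1-based inclusive (GenBank convention) everywhere a
user sees them; a feature spanning the circular origin is stored with
`wraps_origin=True` and `start > end` rather than with modular arithmetic.
Supermatrix partition intervals are half-open `[start, end)` internally;
conversion happens only at module boundaries (e.g. the RAxML-style
partition writer emits 1-based inclusive ranges). Gene names are
canonicalized through a versioned synonym table
(`src/mitoaudit/data/gene_synonyms.tsv`); an unmappable CDS label demotes
the feature to `kind="other"` with a warning and never aborts a run.

## Supermatrix construction

Stop stripping follows the vertebrate mitochondrial code (TAA/TAG/AGA/AGG):
a trailing complete stop is removed; a length not divisible by 3 is trimmed
to a codon boundary and flagged, and if the last three bases form a stop in
that shifted frame the sequence is additionally flagged as a frameshift
suspect — which is exactly how a WEC ND3 presents. Column filtering removes
every column containing a gap or any non-ACGT symbol in any taxon, and
re-indexes the partition map and per-column codon labels consistently;
filtering is idempotent. The pipeline classifies ND3 before concatenation
and deletes the called insertion from WEC sequences, mirroring what
depositors of frameshift-free records do; this keeps the alignment
columnwise for indel-free inputs. Inputs whose genes still differ in length
after this normalization need an external aligner and are rejected with an
explicit message rather than silently padded. The named three-group
partition scheme (NADH subunits + ATPase + CYTB / the three COX genes /
ND6) is available as a preset.

## Distances, neighbor joining, bootstrap

Pairwise distances use the closed-form p, JC69, K80 and TN93 estimators;
sites with a gap or ambiguity in either sequence are excluded pairwise. A
non-positive logarithm argument (saturation) yields `inf` with no
exception; NJ refuses infinite matrices with advice to change model. NJ is
the standard agglomeration with two deliberate conventions: ties in the Q
criterion break to the lowest index pair in working order (determinism),
and negative branch-length estimates are clamped to zero. Bootstrap
resamples columns with replacement; support is the percentage of replicate
NJ trees containing each bipartition of the full-data tree.

Distance-based NJ deliberately stands in for Bayesian/ML inference: the
audit needs many tree inferences (13 single-gene + 13 jackknife + bootstrap
replicates), and at this scale the closed-form route is exact, seconds-fast
and dependency-free. Consequently the audit's RF and support values are not
expected to numerically match values computed with likelihood machinery on
real data; the *framework* (which partition dominates, what flips on
exclusion) is what is validated, on data where truth is planted. An
externally computed consensus (Newick) can be supplied to drive the audit
instead of the internal NJ tree.

## Robinson–Foulds and the five-taxon topology types

RF is computed on non-trivial unrooted bipartitions even for rooted inputs,
matching the bipartition-based convention of the common R implementations;
polytomies are allowed, so non-binary trees can yield odd distances. The
two competing five-species arrangements ("type I" and "type II") share both
cherries and differ only in the rooted position of one taxon; as unrooted
five-leaf trees they are identical (RF = 0). Classification therefore uses
the rooted restriction: trees larger than five taxa are rooted on the
lexicographically smallest non-target leaf (the attachment to the rest of
the tree provides the root direction), restricted to the five taxa, and the
rooted cluster set is compared against the two reference patterns; anything
else — including unresolved stars — is `other`. A dedicated test battery
covers rerooting and child-order invariance, because this rooted/unrooted
subtlety is the module's central trap.

## Parsimony, Bremer and partitioned Bremer support

Fitch small parsimony treats gaps and all ambiguity codes as fully missing
(the simplest defensible convention; a missing state never forces a
change). Bremer support enumerates all (2n−5)!! unrooted binary topologies
exhaustively and is exact; the operation refuses more than 8 taxa rather
than approximating with heuristic search. PBS for a clade is the
per-partition score difference between the best tree lacking the clade and
the best tree overall, so `Σᵢ PBSᵢ = Bremer` holds identically for any
tie choice; ties among equal-score trees break to the lexicographically
smallest Newick string for a deterministic decomposition. PBS values here
are integers by construction; fractional published PBS values come from
likelihood-based variants, which are out of scope, and reports state the
parsimony definition used.

## Saturation index

`Iss` is the mean per-site entropy (base 2, over observed unambiguous bases
at each site) divided by the expected per-site entropy at full saturation,
`H_FS`, computed exactly by enumerating base-count compositions of n
sequences drawn i.i.d. from the alignment-wide base frequencies. For large
alignments the index is averaged over random subsamples of 4/8/16/32 OTUs
(seed-controlled). The critical value `Iss.c` is estimated by Monte Carlo:
alignments are simulated under JC on random topologies along a ladder of
tree depths (default scales 0.01–25.6, branch lengths U(0.5, 1.5) × scale),
and `Iss.c` is the mean index at the first depth where NJ on p-distances
recovers the true topology in fewer than 95% of replicates. Default 500
replicates; fewer than 100 triggers an instability warning. The decision
rule is printed in every report: *little saturation* requires the observed
index to sit significantly **below** the critical value (t-test against the
replicate distribution, α = 0.05); otherwise saturation cannot be ruled
out. The inequality direction is frequently garbled in print, which is why
both values and the rule are always reported rather than a bare verdict.

## SNP bins and the colocation permutation test

A site is variable when at least two distinct unambiguous bases occur in
the alignment; columns containing gaps are excluded from numerator and
denominator and reported separately. Bins are non-overlapping 60-bp windows
anchored at position 1 (no sliding); the final short bin uses its true
width, and excluded columns shrink bin denominators. Candidate selection
sites arrive as protein-level codon indices and are expanded to all three
nucleotide positions. The colocation test is a raw-mean-difference
permutation test with the **bin** as the exchangeable unit — the scientific
claim compares windows around candidate loci against the remaining windows,
so bins, not sites, are the units; the unit choice is recorded in every
result. The p-value uses the add-one formula `(1 + #{null ≥ obs})/(1 + N)`
so it is never zero, one-sided "greater" by default per the directional
claim. The null is sampled from the sorted rate vector, which makes the
Monte-Carlo p-value exactly invariant to bin reordering.

## ND3 frameshift calling

A query is WEC when three signals agree: (i) global pairwise alignment to a
WOC reference shows exactly one 1-nt cytosine insertion in the 5′ two
thirds of the gene (terminal raggedness within 3 nt of either end is
ignored); (ii) naive translation (table 2) stops prematurely downstream of
the insertion; (iii) deleting the called base restores an open reading
frame through to the reference stop. No insertion plus a clean ORF is WOC;
any other combination is `ambiguous` and is carried through surveys rather
than dropped, since depositor-edited records are a known hazard for this
trait. Because the insertion lives in a cytosine homopolymer its placement
is inherently ambiguous; the caller reports the **leftmost position of the
run**. Two refinements make the coordinate robust on divergent sequence:
if the longest C-run within ±15 nt of the aligner's gap is exactly one base
longer in the query than in the reference, the insertion is assigned to
that run; otherwise the single-base deletion near the gap that minimizes
the Hamming distance to the reference is chosen, ties broken toward the
longest C-run and then leftmost. Published coordinates for this same
insertion differ between sources (147 vs 174), which this convention
sidesteps by always deriving the coordinate from the data; the WOC
reference is configurable (a passerine ND3 is the natural choice for real
surveys, since that order is uniformly WOC).

## The synthetic benchmark

`make_arborophila_benchmark(seed)` emulates the statistical structure the
analyses assume, on a 7-taxon tree (5 ingroup + 2 outgroups):

* **Model.** GTR+I+Γ with transition-biased exchangeabilities
  (AG = CT = 8, others 1), A/C-rich stationary frequencies
  (0.304, 0.313, 0.134, 0.249), p_inv = 0.25 and continuous gamma rates
  (α = 1) — continuous rather than discrete-gamma, which is immaterial to
  every property tested. Transition matrices come from the eigendecomposition
  of the reversible rate matrix, applied per site with per-site rates.
* **Gene lengths** are realistic avian values (ND5 longest at 1818 nt,
  ATP8 shortest at 165 nt), with per-gene rate multipliers (NADH subunits
  fast, COX slow), so length-driven dominance phenomena are reproducible.
* **Planted conflict.** Twelve partitions evolve on a type II species tree
  (conflicting internal edge 0.04 substitutions/site); the ND5 partition
  evolves on a type I tree whose discriminating edge (0.30) is long and
  whose other branches are short, at rate multiplier 2. The geometry is
  chosen so that the concatenated signal is dominated by ND5 — the
  type I : type II signal ratio at the disputed edge, weighted by
  length × rate, is roughly 2:1 — while every partition still carries
  enough signal for its own tree to be informative. Distance compression
  under rate heterogeneity flattens deep edges, which is why the ND5 tree
  concentrates its length on the discriminating edge rather than being
  uniformly long.
* **Clean ORFs.** First codon positions of every CDS are held invariant at
  C/G. All vertebrate mitochondrial stops begin with T or A, so this
  provably excludes in-frame stop codons without codon-aware simulation.
  The cost is that first positions carry no signal (pairwise profiles at
  `pos1` are empty), which is documented and tested.
* **ND3 insertion.** The ND3 partition carries an invariant
  `ACCCCCCACA` motif (cytosine homopolymer pinned by non-C flanks, the
  trailing codon chosen stop-free) and an invariant AGA stop codon in the
  +1-shifted downstream frame; one C is inserted into the run of every
  ingroup taxon at genome-assembly time. Evolution is otherwise indel-free,
  so alignment software is never a test dependency.
* **Hotspots.** Windows in ND1/ND2/ND4/ND5 multiply site rates by 5
  (configurable) and carry 43 planted candidate codons, 11 tiered
  significant — the study-scale candidate load.
* **Ledger.** Every planted signal — per-partition topology, variable
  columns, candidate sites with tiers, hotspot windows, per-branch
  substitution events, insertion positions — is recorded in a JSON ledger
  sufficient to score any pipeline output as right or wrong.

What passing the synthetic suite does *not* show: performance under real
indel alignment, codon-level selection (hotspots are rate multipliers, not
dN/dS machinery), tRNA-level annotation reconciliation, lineage sorting or
introgression, or agreement with likelihood-based support values on real
data.

## Problem sizes and defaults

Property tests run at the sizes that make their guarantees exact or
statistically decisive on one CPU: RF against the bipartition oracle on
1000 random pairs (n ≤ 8); NJ consistency on 1000 random additive matrices
(n ≤ 10); Fitch against exhaustive internal-state minimization for n ≤ 6;
permutation type-I error over 1000 null replicates against the binomial
99% band and power over 100 seeded benchmark replicates; Bremer/PBS
identities over every internal clade of the benchmark consensus. The
acceptance script uses 300-trial oracle checks, 400 calibration replicates
and 50 power seeds, which reproduce the same rates at lower cost.

## Known limitations

* Exhaustive Bremer/PBS is capped at 8 taxa by design; larger problems
  need heuristic search, which this package intentionally does not provide.
* The Iss.c construction follows the published idea (simulation to the
  recovery-collapse point) but the original tool's exact simulation
  protocol is not public; absolute Iss.c values are therefore
  convention-dependent, and only the relative decision (observed index far
  below the critical region) should be interpreted.
* The ND3 caller assumes a single-insertion difference; genes with
  additional real indels relative to the reference are classified
  `ambiguous` rather than resolved.
* Codon-aware alignment of real, indel-containing CDS sets is out of
  scope; the pipeline expects length-consistent genes after WEC
  normalization and says so when they are not.
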