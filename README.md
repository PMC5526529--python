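# mitoaudit

Comparative mitogenomics of closely related birds, built around a question
that recurs whenever complete mitochondrial genomes are concatenated into a
phylogenomic supermatrix: **which gene is actually driving the tree?** In
hill partridges (*Arborophila*), five species admit two competing rooted
arrangements that differ only in where *A. rufipectus* attaches —

* **type I**: `(((ardens, brunneopectus), rufipectus), (gingica, rufogularis))`
* **type II**: `(((gingica, rufogularis), rufipectus), (ardens, brunneopectus))`

— and a single long, fast-evolving gene (*ND5*) can pull the concatenated
tree from one type to the other. `mitoaudit` implements the full audit
workflow for this kind of problem, end to end:

1. **Genome I/O and descriptive statistics** — GenBank/FASTA readers for
   annotated mitogenomes (13 protein-coding genes, 22 tRNAs, 2 rRNAs,
   D-loop), gene extraction with strand and circular-origin handling, base
   composition.
2. **Supermatrix construction** — stop-codon stripping (vertebrate
   mitochondrial code), concatenation with a gene → column partition map and
   codon-position labels, and removal of every column containing a gap or
   ambiguous base.
3. **Saturation assessment** — transition/transversion trajectories against
   pairwise p-distance, and an entropy saturation index
   `Iss = H̄_site / H_FS` (mean per-site entropy in bits over the expected
   entropy at full saturation) with a Monte-Carlo critical value `Iss.c`
   located where neighbor joining stops recovering the true topology.
4. **SNP-hotspot colocation** — variable sites binned in 60-bp windows;
   a Fisher–Pitman-style permutation test of whether bins containing
   candidate positively selected sites have elevated SNP rates
   (statistic: difference of mean per-bin rates; flags permuted over bins).
5. **ND3 +1 frameshift survey** — detection of the avian extra-cytosine
   insertion (WEC/WOC classification) from three signals: a single 1-nt C
   insertion against a WOC reference, a premature stop in naive translation,
   and ORF restoration on deleting the called base; order-level tallies.
6. **Gene-influence audit** — per-gene trees, leave-one-gene-out
   (jackknife) trees, Robinson–Foulds distances to the consensus, and
   five-taxon topology typing; neighbor joining over closed-form distances
   (p, JC69, K80, TN93) with bootstrap support.
7. **Exact Bremer / partitioned Bremer support (PBS)** — exhaustive
   enumeration of all (2n−5)!! topologies (n ≤ 8), Fitch scoring, and the
   decomposition `Σᵢ PBSᵢ = Bremer` per clade.
8. **A synthetic-data generator** that simulates all of the above under
   GTR+I+Γ — including a planted dominant conflicting partition, hotspot
   windows with candidate sites, and the ND3 insertion — and emits a truth
   ledger so every pipeline output can be scored.

Tree inference is deliberately distance-based (NJ) rather than Bayesian/ML:
at audit scale it is exact, fast and reproducible, and the audit framework
is validated on simulated data where the per-partition truth is known.

## Worked example

```python
from mitoaudit import make_arborophila_benchmark, nj_tree, gene_audit, bremer_and_pbs
from mitoaudit.trees import classify_arborophila
from mitoaudit.variation import variable_sites, bin_profile, hotspot_association_test

bench = make_arborophila_benchmark(seed=0)
sm = bench.supermatrix
consensus = nj_tree(sm.rows, sm.taxa)
print(classify_arborophila(consensus))
rep = bremer_and_pbs(sm, ("ardens", "brunneopectus", "rufipectus"))
```

prints, for the default benchmark (5 ingroup + 2 outgroup taxa, 13
partitions, 11 376 bp):

```
supermatrix: 7 taxa x 11376 bp in 13 partitions
consensus five-species topology: type_I
ATP8  single=other    RF=4  jackknife=type_I   RF=0
ND4   single=type_II  RF=2  jackknife=type_I   RF=0
ND5   single=type_I   RF=2  jackknife=type_II  RF=2
Bremer support of (ardens,brunneopectus,rufipectus): 67
PBS: ND5=+151  ND4=-11  ATP8=+1
hotspot colocation: mean rate difference 0.175, p = 0.0001 (9999 permutations)
```

Reading this: the concatenated (consensus) tree shows the type I
arrangement, but only because of *ND5* — its single-gene tree is the only
one supporting type I, excluding it flips the jackknife tree to type II,
and at the disputed clade it contributes a large positive PBS (+151) while
most other genes push the other way. The permutation test confirms that
60-bp windows holding the planted candidate selection sites carry
significantly more SNPs than the rest of the alignment. This is precisely
the "one gene decides the topology" phenomenon the audit is designed to
expose.

The same workflow runs from the shell:

```sh
mitoaudit run-all --seed 0 --out runs/demo          # synthetic benchmark
mitoaudit run-all --genbank my_genomes.gb --out runs/real --seed 0
```

Each run directory contains the gene table, supermatrix (FASTA + RAxML-style
partition file), saturation report, consensus tree with bootstrap supports,
gene-audit table, Bremer/PBS table, SNP bin profile with the permutation
test, ND3 calls and order survey, plus a manifest recording inputs,
parameters and the seed. Re-running with the same config and seed
reproduces every report byte for byte.

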