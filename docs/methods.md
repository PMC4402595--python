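# Methods

## Model and assumptions

The package treats driver-pathway detection as a combinatorial pattern
search on a binary somatic mutation matrix *A* (*m* patients × *n* genes,
entry 1 = gene mutated in that patient). The underlying biological model is
that a driver pathway is perturbed by approximately one driver mutation per
tumour: across patients its member genes should together cover a large
fraction of the cohort (high coverage) while rarely co-occurring within a
patient (high mutual exclusivity). Nothing else — no interaction networks,
annotations or expression data — is used.

The three scores are exact functions of integer counts. For a gene set *M*:
ED(*M*) = |Γ(*M*)| / Σ|Γ(*g*)|, CD(*M*) = |Γ(*M*)|/*m*, ECD = ED·CD, where
Γ(·) are patient coverage sets. ED is undefined when no member gene carries
a mutation (zero denominator); a zero-coverage gene inside a larger set is
metric-neutral (contributes 0 to numerator and denominator) and is allowed.

## Pipeline and parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| `min_gene_fraction` | pre-filter: drop genes mutated in < this fraction of all patients | 0.05 | boundary kept: |Γ(g)| ≥ 0.05·m retained, compared without rounding; *m* counts all input patients, including ones left unmutated after filtering |
| `lambda_` (λ) | pairwise-ED threshold for network edges, and strict lower bound on set ED during growth | 0.95 | edge creation is inclusive (≥ λ), growth admissibility strict (> λ); both comparisons are deliberately kept as stated, each centralized in one place |
| `delta` (δ) | minimum coverage degree of a reported pathway | 0.3 | applied after growth |
| `min_set_size` | minimum reported set size | 3 | smaller local optima are discarded (reason recorded) |

The greedy stage seeds with the connected, never-yet-consumed gene pair of
highest pairwise ECD, then repeats best-improvement moves: every external
gene adjacent to the current set (via a boundary edge) is a candidate
addition, every member a candidate removal; a move is admissible iff it
strictly increases ECD and leaves ED > λ; the best admissible move is
applied (ties: higher ED, then additions before removals, then smallest
gene symbol). Each accepted move strictly increases an exact rational ECD
bounded by 1 over finitely many gene sets, so growth terminates; the outer
loop terminates because each round consumes at least the two seed genes.

Two scope decisions that were genuinely open:

* **Overlap.** Only *seeding* is restricted to unconsumed genes; growth may
  absorb genes already claimed by earlier sets. This is what lets reported
  pathways share genes (a gene participating in two biological processes),
  and also lets ejected seed "outliers" be picked up by a later cluster.
  The alternative (restricting additions to unconsumed genes) would make
  reported sets disjoint by construction and was rejected.
* **Seed objective.** Seed pairs maximize pairwise ECD (not raw edge
  weight/ED); with equal ECD the higher-ED, lexicographically smaller pair
  wins.

Genes of every grown set and its seeds are marked consumed whether or not
the set survives the δ/size filter — otherwise discarded candidates would
be re-seeded forever. Identical gene sets found from different seeds are
reported once.

## Numerical conventions

All ED/CD/ECD comparisons in the search are performed on
`fractions.Fraction` values; floats appear only at the output boundary.
User-supplied thresholds arrive as floats and are mapped to rationals via
their shortest decimal representation (`0.95` → 19/20), so a pair with ED
exactly 19/20 lies on the edge-creation boundary instead of an ulp below
it. Consequences: no floating-point livelock is possible in the growth
loop, and results for a fixed input and parameters are byte-identical
across runs and platforms. Edge weights are written to 12 decimal places.

## Synthetic data

`nbm.simulate.generate` emulates an implanted-pathway benchmark: *m* = 300
patients, *n* = 500 genes, five disjoint 5-gene pathways at random column
positions with coverage degrees 0.95/0.85/0.75/0.65/0.55. For pathway *i*,
round(c_i·m) distinct patients are drawn uniformly (285/255/225/195/165 at
the defaults) and each receives a driver mutation in exactly one uniformly
chosen member gene, making within-pathway drivers mutually exclusive and
CD exactly c_i at q = 0. Patient draws for different pathways are
independent, so one patient may carry drivers of several pathways.
Passenger mutations are then OR-ed into every cell independently with
probability q (`noise_scope="nondriver_genes_only"` restricts them to
non-implanted genes if a noise-free driver signal is wanted). A single
seeded `numpy` generator drives everything, so output is reproducible.

What the simulation does *not* emulate: patient-to-patient mutation-rate
heterogeneity, gene-length or expression-linked mutability, copy-number
events, and subtype structure. Passing recovery tests therefore show the
search behaves correctly under the stated generative model, not that it is
robust to every property of real cohorts.

A behaviour worth knowing about: even with q = 0, unrelated genes from
*different* implanted pathways are occasionally mutually exclusive by
chance at m = 300, which creates cross-pathway network edges. Because
growth may absorb consumed genes (the overlap mechanism above), the search
then sometimes reports, alongside the implanted pathways themselves, an
extra small mixed set or a one-gene superset of a pathway. Measured over
100 noise-free replicates, all five implanted sets are recovered in ~98%
of runs and the output equals the ground truth exactly (no extras) in
~83%. This is an intrinsic property of overlap-permitting greedy growth,
not a numerical artefact.

## Permutation significance (plumbing)

`permutation_pvalue` is a labelled convenience, not part of the core
method: it shuffles each gene's column independently (preserving per-gene
mutation counts), recomputes ECD of the candidate set, and returns the
add-one estimator p = (1 + #{ECD* ≥ observed}) / (1 + N), which is never 0.
It answers "is this set's ECD surprising given its genes' frequencies",
nothing more; it is not an enrichment test against annotated pathways.

## Problem sizes used in the test suite

Unit and property tests run on matrices up to 15×10 plus the 300×500
simulator output; recovery checks use 20 noise-free and 50 low-noise
(q = 0.001) replicates; the brute-force oracle comparison enumerates all
≤5-gene subsets of 10×8 matrices. The full suite completes in a few
seconds.

## Known limitations

* O(n²) pair enumeration with rational arithmetic is comfortable for
  post-filter gene counts in the hundreds to low thousands, not for
  exome-wide unfiltered matrices.
* Best-improvement growth is myopic: it can prefer a large immediate
  coverage gain that strands the set in a poorer local optimum than a
  smaller first step would have reached (see the synthetic-data note).
* Binary input only; mutation types, CNA dosage and per-patient rates are
  out of scope — users pre-binarize.
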