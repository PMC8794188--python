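# Methods

## Model and procedure

Gene selection is posed as a multiple criteria optimization (MCO) problem.
A comparative experiment provides expression values for N genes in two
sample groups A and B (optionally within sex strata). For each gene g and
each chosen location statistic `stat_c` the performance measure is

    PM_c(g) = | stat_c(x_{g,A}) − stat_c(x_{g,B}) |,  c = 1..C,

with `stat_c` drawn from {mean, median, mode, third quartile, quantile_q}.
Each PM is reflected into a minimisation criterion by the affine map

    z_c(g) = max_h PM_c(h) − PM_c(g),

so the gene(s) with the largest change in criterion c sit exactly at 0 and
the ideal point is the origin. Gene u dominates gene v when z(u) ≤ z(v) in
every coordinate and z(u) < z(v) in at least one; the first frontier is the
non-dominated set. Peeling — removing the current frontier and recomputing
— yields frontiers 1..F of decreasing significance. The procedure has no
tunable statistical parameters: no thresholds, no preference weights among
criteria, no assumed null distribution. Identical inputs give identical
output.

Because dominance depends only on the coordinate-wise orderings, every
frontier assignment is invariant under strictly increasing transforms
applied per criterion; in particular the choice of reflection (max − x
versus any other order-reversing affine map) cannot change membership. The
reflection's only role is the "toward the origin" geometry of the plots.

Two analysis shapes: *single* (one dataset, 2–3 PMs; the classical instance
uses |mean difference| and |median difference|) and *meta* (2–5 datasets,
one PM each, median by default). In meta mode each dataset contributes one
criterion, joined by strict intersection of gene identifiers: a Pareto
point needs a value on every criterion, and no cross-platform imputation or
unit harmonisation is attempted — which is the point of the construction,
since dominance is insensitive to each study's scale.

The four-comparison scheme for sex-annotated cohorts runs the configured
analysis with identical settings on MaleControl–MaleCase (MCO 1),
FemaleControl–FemaleCase (MCO 2), MaleControl–FemaleControl (MCO 3) and
MaleCase–FemaleCase (MCO 4), takes each comparison's union of frontiers
1..F, and returns (MCO1 ∩ MCO2) \ (MCO3 ∪ MCO4): genes responding to the
condition in both sexes, excluding genes whose apparent signal is
sex-dimorphic expression.

## Frontier engine

The production extractor sorts rows lexicographically (first criterion
primary) and scans once, testing each candidate only against the running
frontier: any dominator of a row precedes it in lexicographic order, and by
transitivity some non-dominated dominator does. Ties are kept — identical
rows never dominate each other, so duplicated criteria vectors co-exist on
a frontier rather than being silently dropped. Complexity is O(n log n +
n·k·C) with k the frontier size, and O(n²C) in the adversarial worst case.
Correctness is anchored to a deliberately naive O(n²C) exhaustive-dominance
oracle kept separate from the production path; the two are compared exactly
on hundreds of seeded random matrices (with and without ties) in the test
suite and the acceptance script.

The S-way split mirrors the published tool's memory device: genes are
ordered deterministically by identifier, cut into S contiguous blocks,
local frontiers are extracted per block, pooled, and re-filtered. The
result provably equals the global frontier for every S (a dominator of a
pooled point was itself pooled or is dominated by a pooled point), and the
tests assert exact agreement across S ∈ {1, 2, 5, 10, n}. S is therefore a
resource knob, never a result knob.

Numerical conventions: floating-point comparisons are exact — an epsilon
tolerance would be an undocumented parameter in a method advertised as
deterministic, so input values are compared as read. Quantiles use linear
interpolation between order statistics (Hyndman–Fan type 7, numpy's
default); Q3 ≡ quantile(0.75). The mode of continuous values is the most
frequent value after rounding to 4 decimals, ties resolved by the
arithmetic mean of the tied values (an all-distinct sample degenerates to
the mean); this is a deliberate parameter-light convention, since any
density-based mode would smuggle in a bandwidth. The reflection max − x is
computed once per criterion over the genes entering the analysis and is not
recomputed as frontiers are removed — membership is unaffected and reported
criteria values stay stable across frontiers. Requesting more frontiers
than the genes can fill is a warning, not an error.

## Missing values and probe collapsing

A gene with any missing value inside either group of a requested comparison
is excluded from that comparison and the exclusion is logged; exclusion is
deterministic where imputation would not be. Probe-level matrices are
collapsed to gene level by per-sample median over a gene's probes by
default (mean and keep-most-variable-probe are available); probes without a
mapping are dropped. Inputs are plain TSV and values are taken as-is — no
normalisation, background correction or log transformation is applied.

## Synthetic data and what passing tests show

The generator emulates the four-group case/control × sex layout at toy
scale. Defaults: 1000 genes, 10 samples per group (matching the smaller
public cohorts such layouts typically have), independent Gaussian noise
with unit scale, gene baselines uniform on [5, 10] (a log2-microarray-like
range), 10 condition genes and 10 sex genes planted as additive shifts of
5 noise units — condition genes shifted in both case groups, sex genes in
both female groups. Additive location shifts move mean and median
identically, so both default PMs respond; mean-only or median-only effects
are separate test cases, not the default. Meta collections share planted
genes across all datasets and a configurable fraction of null gene ids.

What the generator does *not* emulate: probe-level artefacts, batch
effects, heavy-tailed intensity distributions, correlated genes,
platform-specific dynamic ranges. Passing recovery tests therefore show
that the selection logic behaves as designed under clean location-shift
signal, not that any particular biological dataset will yield a particular
gene list.

## Behaviour of the four-way subtraction at large F

A property worth knowing before choosing F. In the four-way scheme each
comparison contributes the union of its F frontiers. The two sex
comparisons are null comparisons for condition-responsive genes, and
successive Pareto layers of exchangeable points are wide in higher criteria
dimensions: for ~1000 genes and four criteria, the first 10 layers cover
roughly 98% of all genes. The union (MCO3 ∪ MCO4) at F = 10 therefore
contains nearly every gene, and the subtraction annihilates the result set
— measured recovery of planted condition genes in the package's 4-dataset
study conditions is ≈ 0/10 at F = 10, ≈ 4/10 at F = 1 (where the loss is
instead the chance of sitting on frontier 1 of both disease comparisons),
and peaks between (≈ 9/10 at F = 2 under the same conditions; the
acceptance script recomputes the F = 10 and F = 1 figures). In 2D single-
dataset instances layers are far narrower and a deep F is the natural
choice, which is why the classical individual analyses use F = 10 while
meta analyses keep F = 1. F is a reporting depth shared by all four
comparisons, and the sex-exclusion guarantee (planted sex-dimorphic genes
never appear in the result) holds at every F tested.

## Problem sizes used in the shipped checks

Unit and property tests run on matrices up to a few hundred genes; the
oracle and split-invariance checks use 100 seeded matrices with 20–500
genes plus 2000-gene instances every twentieth matrix, 2–5 criteria; the
recovery study uses 20 seeds of the 4 × 1000-gene collection; the smoke run
is a 25 000-gene × 2-PM, F = 10 single analysis (a transcriptome-scale
instance, seconds on one CPU). These sizes were chosen to make the checks
sharp and quick to re-run; the engine itself has no built-in size limit,
and the CLI's five-dataset cap is the only guard rail.

## Known limitations

* Criteria are location statistics only; variance-based or test-statistic
  criteria are out of scope by design.
* Strict-intersection joining means a gene absent from one dataset of a
  meta-analysis cannot be selected regardless of its signal elsewhere.
* Exact float comparison means criteria that differ by numerical noise are
  treated as genuinely different; upstream rounding is the user's choice.
* The frontier is a set, not a ranking within a frontier: genes on the same
  frontier are incomparable by construction.
* Identifier harmonisation across platforms is the user's responsibility;
  no symbol translation is performed.
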