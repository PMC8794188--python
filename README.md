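# mcoselect

Deterministic gene selection by multiple criteria optimization (MCO):
rank genes on Pareto-efficient frontiers of conflicting expression-change
measures instead of thresholding a single statistic.

## The problem and who this is for

Comparative expression experiments (microarray case/control cohorts and
similar layouts — miRNA arrays, protein arrays, pseudobulked single-cell
contrasts) are usually mined for "differentially expressed" genes with a
test statistic plus user-chosen thresholds. Different statistics disagree:
the gene with the largest mean shift is rarely the gene with the largest
median shift. Choosing one statistic, a p-value cutoff, or a top-k count
injects analyst degrees of freedom, and two analysts can defensibly produce
different gene lists from the same data.

`mcoselect` takes the multi-criteria route. For each gene, compute several
*performance measures* (PMs) of expression change between groups A and B,

```
PM_c(g) = | stat_c(x_g,A) − stat_c(x_g,B) | ,   stat_c ∈ {mean, median, mode, Q3, quantile_q}
```

then reflect each PM into a minimisation criterion `z_c = max_h PM_c(h) − PM_c(g)`,
so the most-changed genes sit at the origin. Gene *u* **Pareto-dominates**
*v* when `z(u) ≤ z(v)` coordinate-wise with strict inequality somewhere; the
selected genes are the non-dominated set (the **Pareto-efficient
frontier**): no other gene offers a better compromise across all measures
simultaneously. Removing the frontier and recomputing *F* times yields a
hierarchy of frontiers with decreasing significance. There are no
thresholds, no distributional assumptions, and no preference weights — the
same inputs always produce the same selection, whoever runs it.

Two analysis shapes are supported:

* **single** — one dataset, 2–3 PMs as criteria;
* **meta** — 2–5 datasets, one PM each (median by default), joined on the
  genes shared by all datasets, so Pareto efficiency spans studies measured
  in different units with no cross-platform normalisation.

A **four-comparison scheme** isolates condition-specific genes in
sex-annotated cohorts. With groups MaleControl/MaleCase/FemaleControl/
FemaleCase, run the same analysis four times —
MCO 1: MaleControl–MaleCase, MCO 2: FemaleControl–FemaleCase,
MCO 3: MaleControl–FemaleControl, MCO 4: MaleCase–FemaleCase —
and select

```
genes of interest = (MCO1 ∩ MCO2) \ (MCO3 ∪ MCO4)
```

genes picked in both sex-stratified disease comparisons but in neither
sex-versus-sex comparison.

## Worked example

Four simulated cohorts (1000 genes, 10 samples per group) share ten planted
condition-responsive genes (shifted in both case groups) and ten planted
sex-dimorphic genes (shifted in both female groups). A four-way
meta-analysis with one |median difference| criterion per dataset:

```python
from mcoselect import AnalysisConfig, SimulationSpec, run_four_way, simulate_meta_collection

specs = [SimulationSpec(seed=7_000 + k, dataset_id=f"study{k + 1}") for k in range(4)]
datasets, truth = simulate_meta_collection(specs, shared_fraction=1.0)
goi = run_four_way(datasets, AnalysisConfig(mode="meta", datasets=datasets, F=1))
```

Running `python examples/four_way_selection.py` prints:

```
per-comparison selected genes: {'MCO1': 9, 'MCO2': 10, 'MCO3': 6, 'MCO4': 6}
genes of interest: ['g00075', 'g00163', 'g00210', 'g00255', 'g00463', 'g00522', 'g00523', 'g00753', 'g00817']
  planted condition genes among them: 9
  planted sex-dimorphic genes among them: 0 (the set subtraction removes them)
```

Each comparison's frontier holds the genes with the best joint compromise
of median shifts across the four studies. Nine of the ten planted disease
genes land on frontier 1 of both disease comparisons and in neither sex
comparison, so they survive the set algebra; every planted sex gene
surfaces in MCO 3/MCO 4 instead and is subtracted. The other examples
(`single_dataset_analysis.py`, `meta_analysis.py`,
`expression_io_and_collapsing.py`) walk the single-dataset path, the plain
meta join and the TSV/probe-collapsing I/O.

## Command line

The same flows are available as a thin CLI; every run writes frontier TSVs
plus a timestamp-free `manifest.json` (config, input checksums, per-stage
gene counts), so re-running a command reproduces byte-identical outputs.

```sh
mco simulate --spec sim.yaml --out data/
mco single  --matrix X.tsv --sheet S.tsv --pm mean --pm median \
            --comparison MaleControl MaleCase --frontiers 10 --out run/
mco meta    --dataset A.tsv:As.tsv --dataset B.tsv:Bs.tsv --frontiers 1 --out run/
mco fourway --dataset A.tsv:As.tsv --dataset B.tsv:Bs.tsv --out run/
mco plot    --in run/single_frontiers.tsv --axes 0,1 --out frontiers.png
```

Meta-analysis on the command line is capped at five datasets to keep the
cost of wide criteria spaces in check; the library itself accepts any K ≥ 2.

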