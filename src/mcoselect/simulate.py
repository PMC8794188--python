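"""Synthetic expression datasets with known ground truth.

The generator emulates the comparative layout the method targets: four
sample groups from the crossing of condition (case/control) and sex (M/F),
with three planted gene classes —

* ``condition`` genes: an additive shift in both case groups (the disease
  signal the four-way scheme should recover),
* ``sex`` genes: the same shift in both female groups (a confound the
  scheme should subtract away),
* ``null`` genes: noise around a gene-specific baseline.

Noise is independent Gaussian with unit scale and baselines are uniform on
a log2-microarray-like interval; effects are additive location shifts so
mean- and median-based measures respond identically.  Everything is driven
by an explicit integer seed: identical spec in, identical matrix out.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset, ValidationError

GENE_CLASSES = ("condition", "sex", "null")


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one synthetic dataset.

    Defaults give a compact study: 1000 genes, 10 samples per group (the
    size of the smaller public cohorts this layout mimics), 10 planted
    condition genes and 10 planted sex genes at effect size 5 (units of the
    unit-scale noise), baselines uniform on [5, 10].
    """

    n_genes: int = 1000
    n_per_group: int = 10
    n_condition_genes: int = 10
    n_sex_genes: int = 10
    effect_size: float = 5.0
    noise_sd: float = 1.0
    baseline_low: float = 5.0
    baseline_high: float = 10.0
    seed: int = 0
    dataset_id: str = "sim"

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_per_group) < 1:
            raise ValidationError("n_genes and n_per_group must be positive")
        if min(self.n_condition_genes, self.n_sex_genes) < 0:
            raise ValidationError("planted gene counts cannot be negative")
        if self.n_condition_genes + self.n_sex_genes > self.n_genes:
            raise ValidationError(
                "planted genes (condition + sex) cannot exceed n_genes"
            )
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        if self.baseline_high < self.baseline_low:
            raise ValidationError("baseline interval is inverted")


GROUP_LAYOUT = (
    ("MaleControl", "M", "control"),
    ("MaleCase", "M", "case"),
    ("FemaleControl", "F", "control"),
    ("FemaleCase", "F", "case"),
)


def _gene_ids(n: int, prefix: str = "g") -> np.ndarray:
    width = max(5, len(str(n)))
    return np.array([f"{prefix}{i:0{width}d}" for i in range(1, n + 1)], dtype=object)


def simulate_dataset(
    spec: SimulationSpec,
    gene_ids: np.ndarray | None = None,
    truth: pd.Series | None = None,
) -> tuple[ExpressionDataset, pd.Series]:
    """Generate one dataset and its ground-truth gene classes.

    Returns the dataset and a Series mapping gene id to its class in
    {"condition", "sex", "null"}.  ``gene_ids``/``truth`` let a caller
    impose a shared gene universe (used by :func:`simulate_meta_collection`
    so planted genes are planted consistently across datasets); by default
    planted genes are placed at seeded-random positions.
    """
    rng = np.random.default_rng(spec.seed)
    if gene_ids is None:
        gene_ids = _gene_ids(spec.n_genes)
        classes = np.array(["null"] * spec.n_genes, dtype=object)
        planted = rng.choice(
            spec.n_genes, size=spec.n_condition_genes + spec.n_sex_genes, replace=False
        )
        classes[planted[: spec.n_condition_genes]] = "condition"
        classes[planted[spec.n_condition_genes :]] = "sex"
        truth = pd.Series(classes, index=gene_ids, name="class")
    else:
        if truth is None or len(truth) != len(gene_ids):
            raise ValidationError("shared gene_ids require a matching truth series")
        gene_ids = np.asarray(gene_ids, dtype=object)
    n = len(gene_ids)

    sample_ids, sex_col, cond_col = [], [], []
    for gname, sex, cond in GROUP_LAYOUT:
        for i in range(1, spec.n_per_group + 1):
            sample_ids.append(f"{spec.dataset_id}_{gname}_{i:02d}")
            sex_col.append(sex)
            cond_col.append(cond)
    m = len(sample_ids)

    baseline = rng.uniform(spec.baseline_low, spec.baseline_high, size=n)
    X = baseline[:, None] + rng.normal(0.0, spec.noise_sd, size=(n, m))
    is_cond = (truth.loc[gene_ids] == "condition").to_numpy()
    is_sex = (truth.loc[gene_ids] == "sex").to_numpy()
    case_cols = np.array([c == "case" for c in cond_col])
    female_cols = np.array([s == "F" for s in sex_col])
    X[np.ix_(is_cond, case_cols)] += spec.effect_size
    X[np.ix_(is_sex, female_cols)] += spec.effect_size

    values = pd.DataFrame(X, index=gene_ids, columns=sample_ids)
    ann = pd.DataFrame(
        {"condition": cond_col, "sex": sex_col}, index=pd.Index(sample_ids, name="sample")
    )
    ds = ExpressionDataset(dataset_id=spec.dataset_id, values=values, annotations=ann)
    return ds, truth.loc[gene_ids].copy()


def simulate_meta_collection(
    specs: list[SimulationSpec],
    shared_fraction: float = 1.0,
) -> tuple[list[ExpressionDataset], pd.Series]:
    """Generate 2-5 datasets sharing a common core of gene ids.

    Planted condition and sex genes are always part of the shared core and
    are shifted consistently in every dataset; of the remaining null genes a
    ``shared_fraction`` keep the same id across datasets while the rest get
    dataset-specific ids (emulating platform differences, which the meta
    join later removes).  The returned truth covers the shared universe.
    """
    if not 2 <= len(specs) <= 5:
        raise ValidationError("a meta collection takes between 2 and 5 specs")
    if not 0.0 <= shared_fraction <= 1.0:
        raise ValidationError("shared_fraction must lie in [0, 1]")
    first = specs[0]
    for s in specs[1:]:
        if (
            s.n_genes != first.n_genes
            or s.n_condition_genes != first.n_condition_genes
            or s.n_sex_genes != first.n_sex_genes
        ):
            raise ValidationError(
                "all specs of a collection must agree on gene counts so planted "
                "genes can be shared"
            )
    ids = [s.dataset_id for s in specs]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"dataset ids must be unique, got {ids}")

    layout_rng = np.random.default_rng(first.seed)
    n = first.n_genes
    gene_ids = _gene_ids(n)
    classes = np.array(["null"] * n, dtype=object)
    planted = layout_rng.choice(
        n, size=first.n_condition_genes + first.n_sex_genes, replace=False
    )
    classes[planted[: first.n_condition_genes]] = "condition"
    classes[planted[first.n_condition_genes :]] = "sex"
    truth = pd.Series(classes, index=gene_ids, name="class")

    null_pos = np.flatnonzero(classes == "null")
    n_shared_null = int(round(shared_fraction * len(null_pos)))
    shared_null = set(layout_rng.choice(null_pos, size=n_shared_null, replace=False))

    datasets = []
    for k, spec in enumerate(specs):
        ds_ids = gene_ids.copy()
        for pos in null_pos:
            if pos not in shared_null:
                ds_ids[pos] = f"{gene_ids[pos]}_{spec.dataset_id}"
        ds_truth = pd.Series(classes, index=ds_ids, name="class")
        ds, _ = simulate_dataset(spec, gene_ids=ds_ids, truth=ds_truth)
        datasets.append(ds)
    return datasets, truth


def write_ground_truth(truth: pd.Series, path) -> None:
    """Write the gene-class table as TSV (columns: gene, class)."""
    truth.rename_axis("gene").to_frame().to_csv(path, sep="\t")


def spec_from_dict(d: dict) -> SimulationSpec:
    """Build a SimulationSpec from a plain dict (e.g. parsed YAML)."""
    known = SimulationSpec.__dataclass_fields__.keys()
    unknown = set(d) - set(known)
    if unknown:
        raise ValidationError(f"unknown simulation parameters: {sorted(unknown)}")
    return SimulationSpec(**d)
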