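"""Analysis orchestration: single-dataset, meta-analysis and the four-way scheme.

Two analyses are supported.  *Single*: one dataset, two or three performance
measures on one comparison — each PM is one criterion.  *Meta*: two to five
datasets, one PM per dataset (median by default) — each dataset contributes
one criterion, so Pareto efficiency spans datasets without any unit
harmonisation.  Genes enter a meta criteria matrix only if present (after
missing-value exclusion) in every dataset.

The four-way scheme runs the configured analysis once per sex-stratified
comparison —

    MCO 1: MaleControl vs MaleCase      (disease effect in males)
    MCO 2: FemaleControl vs FemaleCase  (disease effect in females)
    MCO 3: MaleControl vs FemaleControl (sex effect in controls)
    MCO 4: MaleCase vs FemaleCase       (sex effect in cases)

— and selects genes of interest by set algebra: picked in both disease
comparisons but in neither sex comparison,

    result = (MCO1 ∩ MCO2) \\ (MCO3 ∪ MCO4).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

from .dataset import ExpressionDataset, ValidationError, canonical_group_name
from .measures import PMSpec, compute_pm, to_minimization
from .pareto import CriteriaMatrix, FrontierAssignment, peel_frontiers

FOUR_WAY_COMPARISONS = {
    "MCO1": ("MaleControl", "MaleCase"),
    "MCO2": ("FemaleControl", "FemaleCase"),
    "MCO3": ("MaleControl", "FemaleControl"),
    "MCO4": ("MaleCase", "FemaleCase"),
}

#: CLI-facing cap on meta-analysis width; the library itself accepts any
#: K >= 2 (documented extension).
MAX_META_DATASETS = 5


@dataclass
class AnalysisConfig:
    """Configuration shared by the analysis flows.

    ``mode`` is ``"single"`` (one dataset, 2-3 PMs) or ``"meta"`` (2-5
    datasets, one PM each; median unless overridden).  ``F`` is the number
    of frontiers to peel and ``S`` the split count passed to the frontier
    engine.  ``comparison`` names the (group A, group B) pair.
    """

    mode: str
    datasets: list[ExpressionDataset]
    pm_specs: list[PMSpec] = field(default_factory=list)
    F: int = 1
    S: int = 1
    comparison: tuple[str, str] = ("Control", "Case")

    def __post_init__(self) -> None:
        if self.mode not in ("single", "meta"):
            raise ValidationError(f"unknown analysis mode {self.mode!r}")
        if self.F < 1 or self.S < 1:
            raise ValidationError("F and S must both be >= 1")
        self.comparison = (
            canonical_group_name(self.comparison[0]),
            canonical_group_name(self.comparison[1]),
        )
        if self.mode == "single":
            if len(self.datasets) != 1:
                raise ValidationError("single mode takes exactly one dataset")
            if not 2 <= len(self.pm_specs) <= 3:
                raise ValidationError(
                    f"single mode takes two or three PMs, got {len(self.pm_specs)}"
                )
        else:
            if len(self.datasets) < 2:
                raise ValidationError("meta mode needs at least two datasets")
            if not self.pm_specs:
                self.pm_specs = [PMSpec("median") for _ in self.datasets]
            if len(self.pm_specs) != len(self.datasets):
                raise ValidationError(
                    "meta mode takes exactly one PM per dataset "
                    f"({len(self.datasets)} datasets, {len(self.pm_specs)} PMs)"
                )
            ids = [ds.dataset_id for ds in self.datasets]
            if len(set(ids)) != len(ids):
                raise ValidationError(f"duplicate dataset ids in meta config: {ids}")

    def with_comparison(self, group_a: str, group_b: str) -> "AnalysisConfig":
        return replace(self, comparison=(group_a, group_b))


def build_criteria_matrix(cfg: AnalysisConfig) -> CriteriaMatrix:
    """Compute the raw PMs of a config, join genes, and reflect to minimisation.

    The reflection ``max - x`` is applied per criterion over exactly the
    genes entering the analysis (the joined set), once; peeling never
    recomputes it, so criteria values are stable across frontiers.
    """
    ga, gb = cfg.comparison
    raw = []
    if cfg.mode == "single":
        ds = cfg.datasets[0]
        raw = [compute_pm(ds, spec.with_groups(ga, gb)) for spec in cfg.pm_specs]
    else:
        raw = [
            compute_pm(ds, spec.with_groups(ga, gb))
            for ds, spec in zip(cfg.datasets, cfg.pm_specs)
        ]
    common = set(raw[0].gene_ids)
    for pm in raw[1:]:
        common &= set(pm.gene_ids)
    if not common:
        counts = {pm.source_dataset: len(pm) for pm in raw}
        raise ValidationError(
            f"no gene common to all criteria for comparison {ga} vs {gb}; "
            f"per-dataset gene counts: {counts}"
        )
    genes = sorted(common)
    transformed = [to_minimization(pm.restrict(genes)) for pm in raw]
    return CriteriaMatrix.from_pm_vectors(transformed)


def run_single(cfg: AnalysisConfig) -> FrontierAssignment:
    """Single-dataset analysis: 2-3 PMs as criteria, then F-frontier peeling."""
    if cfg.mode != "single":
        raise ValidationError(
            f"run_single requires mode='single', got mode={cfg.mode!r}"
        )
    cm = build_criteria_matrix(cfg)
    return peel_frontiers(cm, cfg.F, cfg.S)


def run_meta(cfg: AnalysisConfig) -> FrontierAssignment:
    """Meta-analysis: one PM per dataset as criteria, joined on shared genes."""
    if cfg.mode != "meta":
        raise ValidationError(
            f"run_meta requires mode='meta', got mode={cfg.mode!r}"
        )
    cm = build_criteria_matrix(cfg)
    return peel_frontiers(cm, cfg.F, cfg.S)


def run_analysis(cfg: AnalysisConfig) -> FrontierAssignment:
    return run_single(cfg) if cfg.mode == "single" else run_meta(cfg)


@dataclass
class GenesOfInterest:
    """Result of the four-way scheme.

    ``mco_sets`` maps MCO1..MCO4 to the union of each comparison's extracted
    frontiers; ``result`` is (MCO1 ∩ MCO2) minus (MCO3 ∪ MCO4).
    ``assignments`` keeps the full per-comparison frontier assignments for
    provenance and plotting.
    """

    mco_sets: dict[str, set]
    result: set
    assignments: dict[str, FrontierAssignment]

    def provenance(self) -> pd.DataFrame:
        """One row per gene seen in any comparison: membership + frontier index."""
        genes = sorted(set().union(*self.mco_sets.values()))
        rows = {"gene": genes}
        for name, fa in self.assignments.items():
            idx = {g: int(f) for g, f in zip(fa.gene_ids, fa.frontier_index) if f > 0}
            rows[f"in_{name}"] = [g in self.mco_sets[name] for g in genes]
            rows[f"{name}_frontier"] = [idx.get(g, pd.NA) for g in genes]
        df = pd.DataFrame(rows)
        df["selected"] = df["gene"].isin(self.result)
        return df


def run_four_way(
    datasets: list[ExpressionDataset], cfg: AnalysisConfig
) -> GenesOfInterest:
    """Run the four sex-stratified comparisons and apply the set algebra.

    The same mode, PM specs, F and S are used for every comparison; each
    comparison's gene set is the union of its frontiers 1..F.  Genes of
    interest are those selected in both disease comparisons (MCO1, MCO2)
    and in neither sex comparison (MCO3, MCO4).
    """
    base = replace(cfg, datasets=datasets)
    assignments: dict[str, FrontierAssignment] = {}
    sets: dict[str, set] = {}
    for name, (ga, gb) in FOUR_WAY_COMPARISONS.items():
        try:
            fa = run_analysis(base.with_comparison(ga, gb))
        except ValidationError as exc:
            raise ValidationError(f"{name} ({ga} vs {gb}): {exc}") from exc
        assignments[name] = fa
        sets[name] = fa.ranked_genes()
    result = (sets["MCO1"] & sets["MCO2"]) - (sets["MCO3"] | sets["MCO4"])
    return GenesOfInterest(mco_sets=sets, result=result, assignments=assignments)
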