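"""Per-gene performance measures (PMs) between two sample groups.

A performance measure is the absolute difference of a location statistic
between the two groups of a comparison, computed gene by gene:

    raw[g] = | stat(expr of g in group A) - stat(expr of g in group B) |

Genes with the largest expression change have the largest raw value.  To
pose gene selection as a minimisation problem the raw vector is reflected
with the linear map ``max - x``, so the most-changed genes sit at 0 and
solutions toward the origin are the most significant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .dataset import ExpressionDataset, ValidationError, resolve_groups

logger = logging.getLogger(__name__)

STATISTICS = ("mean", "median", "mode", "q3", "quantile")


@dataclass(frozen=True)
class PMSpec:
    """Declarative description of one performance measure.

    ``statistic`` is one of mean, median, mode, q3 or quantile; ``quantile_q``
    is required exactly when ``statistic == "quantile"`` (q3 is shorthand for
    quantile with q = 0.75).  ``group_a``/``group_b`` name the two sample
    groups being compared; flows fill them in from the comparison when left
    unset.
    """

    statistic: str
    quantile_q: float | None = None
    group_a: str | None = None
    group_b: str | None = None

    def __post_init__(self) -> None:
        if self.statistic not in STATISTICS:
            raise ValidationError(
                f"unknown statistic {self.statistic!r}; expected one of {STATISTICS}"
            )
        if self.statistic == "quantile":
            if self.quantile_q is None:
                raise ValidationError("statistic 'quantile' requires quantile_q")
            if not 0.0 < self.quantile_q < 1.0:
                raise ValidationError("quantile_q must lie strictly in (0, 1)")
        elif self.quantile_q is not None:
            raise ValidationError(
                f"quantile_q is only meaningful for statistic='quantile', "
                f"not {self.statistic!r}"
            )

    def with_groups(self, group_a: str, group_b: str) -> "PMSpec":
        return replace(self, group_a=group_a, group_b=group_b)

    def label(self) -> str:
        stat = (
            f"quantile{self.quantile_q:g}" if self.statistic == "quantile" else self.statistic
        )
        if self.group_a and self.group_b:
            return f"{stat}|{self.group_a}-{self.group_b}"
        return stat


@dataclass
class PMVector:
    """Per-gene values of one performance measure.

    ``values`` holds the nonnegative raw magnitudes ``|stat(A) - stat(B)|``,
    or the reflected minimisation criterion after :func:`to_minimization`
    (``transformed`` tells which).  Genes excluded for missing values are
    absent from ``gene_ids``.
    """

    gene_ids: np.ndarray
    values: np.ndarray
    spec: PMSpec
    source_dataset: str
    transformed: bool = False

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        if self.gene_ids.shape != self.values.shape:
            raise ValidationError("gene_ids and values must have equal length")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def restrict(self, gene_ids) -> "PMVector":
        """Subset (and reorder) to the given gene ids."""
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        idx = np.array([pos[g] for g in gene_ids], dtype=int)
        return PMVector(
            self.gene_ids[idx], self.values[idx], self.spec, self.source_dataset,
            self.transformed,
        )


def estimate_mode(values, decimals: int = 4) -> float:
    """Mode of a numeric sample, for continuous data.

    Values are rounded to ``decimals`` decimal places and the most frequent
    rounded value is returned; ties among equally frequent values are broken
    by their arithmetic mean.  With all-distinct values every value ties, so
    the result degenerates to the mean — a deliberate, parameter-light
    convention (a kernel-density mode would introduce a bandwidth choice).
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValidationError("cannot take the mode of an empty vector")
    rounded = np.round(arr, decimals)
    uniq, counts = np.unique(rounded, return_counts=True)
    tied = uniq[counts == counts.max()]
    return float(tied.mean())


def _column_stat(block: np.ndarray, spec: PMSpec) -> np.ndarray:
    """Row-wise location statistic of a (genes x samples) block."""
    if spec.statistic == "mean":
        return block.mean(axis=1)
    if spec.statistic == "median":
        return np.median(block, axis=1)
    if spec.statistic == "q3":
        # linear interpolation between order statistics (Hyndman-Fan type 7)
        return np.quantile(block, 0.75, axis=1)
    if spec.statistic == "quantile":
        return np.quantile(block, spec.quantile_q, axis=1)
    if spec.statistic == "mode":
        return np.array([estimate_mode(row) for row in block])
    raise ValidationError(f"unknown statistic {spec.statistic!r}")


def compute_pm(ds: ExpressionDataset, spec: PMSpec) -> PMVector:
    """Compute one performance measure for a comparison on one dataset.

    A gene with any missing value inside either group is excluded from this
    comparison (and the exclusion logged); no imputation is attempted.
    """
    if spec.group_a is None or spec.group_b is None:
        raise ValidationError("PMSpec needs group_a and group_b to be computed")
    ga, gb = resolve_groups(ds, spec.group_a, spec.group_b)
    block_a = ds.group_values(ga).to_numpy(dtype=float)
    block_b = ds.group_values(gb).to_numpy(dtype=float)
    ok = ~(np.isnan(block_a).any(axis=1) | np.isnan(block_b).any(axis=1))
    n_dropped = int((~ok).sum())
    if n_dropped:
        dropped = np.asarray(ds.feature_ids, dtype=object)[~ok]
        logger.info(
            "%s: excluded %d gene(s) with missing values from %s vs %s: %s%s",
            ds.dataset_id, n_dropped, ga.name, gb.name,
            ", ".join(map(str, dropped[:10])),
            "..." if n_dropped > 10 else "",
        )
    if not ok.any():
        raise ValidationError(
            f"{ds.dataset_id}: no gene has complete values in both groups"
        )
    raw = np.abs(_column_stat(block_a[ok], spec) - _column_stat(block_b[ok], spec))
    gene_ids = np.asarray(ds.feature_ids, dtype=object)[ok]
    return PMVector(gene_ids, raw, spec, ds.dataset_id, transformed=False)


def to_minimization(pm: PMVector) -> PMVector:
    """Reflect a raw PM vector into a minimisation criterion: ``max - x``.

    The gene(s) with the largest expression change land exactly at 0, so in
    criteria space the best compromises lie toward the origin.  The map is
    order-reversing and affine, hence Pareto membership downstream is
    unaffected by the particular choice of reflection.
    """
    if len(pm) == 0:
        raise ValidationError("cannot transform an empty PM vector")
    if pm.transformed:
        raise ValidationError("PM vector is already transformed to minimization")
    return PMVector(
        pm.gene_ids.copy(),
        pm.values.max() - pm.values,
        pm.spec,
        pm.source_dataset,
        transformed=True,
    )
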