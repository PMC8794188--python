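"""Pareto-efficient frontier extraction for minimisation criteria matrices.

Every gene is a point in C-dimensional criteria space (all criteria
oriented so smaller is better).  A gene u *dominates* v when u is no worse
in every criterion and strictly better in at least one; the first frontier
is the set of non-dominated genes — no other gene offers a better
compromise across all criteria simultaneously.  Removing a frontier and
recomputing yields successive frontiers of decreasing significance
("peeling").

Two structural features mirror the published tool: the gene set may be
split into S blocks whose local frontiers are pooled and re-filtered (a
memory device — the result provably equals the frontier of the full set),
and peeling is repeated F times to build a hierarchy.

Comparisons are exact floating-point comparisons: the method is
deterministic and an epsilon would be an undocumented parameter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import ValidationError
from .measures import PMSpec, PMVector


@dataclass
class CriteriaMatrix:
    """Genes-by-criteria matrix of transformed (minimised) values.

    ``criteria_meta`` carries per-column provenance as (source_dataset,
    PMSpec) pairs; analysis flows keep 2 <= C <= 5 but the core accepts any
    C >= 1.
    """

    gene_ids: np.ndarray
    criteria: np.ndarray
    criteria_meta: list[tuple[str, PMSpec]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.criteria = np.atleast_2d(np.asarray(self.criteria, dtype=float))
        if self.criteria.shape[0] != len(self.gene_ids):
            raise ValidationError("criteria row count must match gene_ids length")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("gene_ids must be unique")
        if not np.isfinite(self.criteria).all():
            raise ValidationError("criteria must be finite")
        if self.criteria.size and self.criteria.min() < 0:
            raise ValidationError("criteria must be >= 0 (minimisation-transformed)")
        if not self.criteria_meta:
            self.criteria_meta = [
                (f"criterion{j + 1}", PMSpec("median")) for j in range(self.C)
            ]
        if len(self.criteria_meta) != self.C:
            raise ValidationError("criteria_meta must have one entry per column")

    @property
    def n_genes(self) -> int:
        return self.criteria.shape[0]

    @property
    def C(self) -> int:
        return self.criteria.shape[1]

    @classmethod
    def from_pm_vectors(cls, pms: list[PMVector]) -> "CriteriaMatrix":
        """Join transformed PM vectors column-wise on their common genes."""
        if not pms:
            raise ValidationError("need at least one PM vector")
        for pm in pms:
            if not pm.transformed:
                raise ValidationError(
                    "PM vectors must be transformed to minimization first"
                )
        common = set(pms[0].gene_ids)
        for pm in pms[1:]:
            common &= set(pm.gene_ids)
        if not common:
            counts = {f"{pm.source_dataset}:{pm.spec.label()}": len(pm) for pm in pms}
            raise ValidationError(
                f"no gene is present in every criterion; per-criterion gene "
                f"counts: {counts}"
            )
        genes = np.array(sorted(common), dtype=object)
        cols = [pm.restrict(genes).values for pm in pms]
        meta = [(pm.source_dataset, pm.spec) for pm in pms]
        return cls(genes, np.column_stack(cols), meta)

    def column_labels(self) -> list[str]:
        return [f"{src}:{spec.label()}" for src, spec in self.criteria_meta]

    def take(self, idx: np.ndarray) -> "CriteriaMatrix":
        return CriteriaMatrix(self.gene_ids[idx], self.criteria[idx], self.criteria_meta)


@dataclass
class FrontierAssignment:
    """Per-gene frontier index 1..F; 0 marks genes beyond frontier F."""

    gene_ids: np.ndarray
    frontier_index: np.ndarray
    F: int

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.frontier_index = np.asarray(self.frontier_index, dtype=int)
        if self.gene_ids.shape != self.frontier_index.shape:
            raise ValidationError("gene_ids and frontier_index must align")

    @property
    def n_frontiers(self) -> int:
        """Number of non-empty frontiers actually extracted."""
        return int(self.frontier_index.max(initial=0))

    def frontier(self, f: int) -> set:
        """Genes on frontier f (1-based)."""
        return set(self.gene_ids[self.frontier_index == f])

    def ranked_genes(self) -> set:
        """Union of all extracted frontiers."""
        return set(self.gene_ids[self.frontier_index > 0])

    def to_frame(self, cm: CriteriaMatrix | None = None) -> pd.DataFrame:
        """Tabular view: gene, frontier, then one column per criterion."""
        df = pd.DataFrame(
            {
                "gene": self.gene_ids,
                "frontier": pd.array(self.frontier_index, dtype="Int64"),
            }
        )
        df.loc[df["frontier"] == 0, "frontier"] = pd.NA
        if cm is not None:
            pos = {g: i for i, g in enumerate(cm.gene_ids)}
            idx = np.array([pos[g] for g in self.gene_ids], dtype=int)
            for j, label in enumerate(cm.column_labels()):
                df[label] = cm.criteria[idx, j]
        df = df.sort_values(
            ["frontier", "gene"], na_position="last", kind="mergesort"
        ).reset_index(drop=True)
        return df


def dominates(u, v) -> bool:
    """True iff u Pareto-dominates v under minimisation.

    Weak inequality everywhere plus strict inequality somewhere; identical
    rows do not dominate each other.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValidationError(f"criteria rows differ in length: {u.shape} vs {v.shape}")
    return bool(np.all(u <= v) and np.any(u < v))


def _frontier_mask(X: np.ndarray) -> np.ndarray:
    """Boolean mask of non-dominated rows of X (minimisation).

    Rows are visited in lexicographic order (first criterion primary), so a
    row can only be dominated by an already-accepted frontier row: if some
    row dominates x then, by transitivity, some *non-dominated* row does,
    and any dominator of x precedes x lexicographically.  Each candidate is
    therefore checked against the running frontier only, which is small in
    practice; duplicated rows never dominate each other and are all kept.
    """
    n, C = X.shape
    order = np.lexsort(tuple(X[:, c] for c in range(C - 1, -1, -1)))
    buf = np.empty_like(X)
    k = 0
    keep = np.zeros(n, dtype=bool)
    for i in order:
        x = X[i]
        if k:
            front = buf[:k]
            if np.any(
                np.all(front <= x, axis=1) & np.any(front < x, axis=1)
            ):
                continue
        buf[k] = x
        k += 1
        keep[i] = True
    return keep


def pareto_frontier(cm: CriteriaMatrix) -> set:
    """Gene ids of the first Pareto-efficient frontier of ``cm``."""
    if cm.n_genes == 0:
        raise ValidationError("criteria matrix has no genes")
    return set(cm.gene_ids[_frontier_mask(cm.criteria)])


def brute_force_frontier(cm: CriteriaMatrix) -> set:
    """Reference frontier by exhaustive pairwise dominance (testing oracle).

    O(n^2 C); deliberately naive and independent of the production path.
    """
    if cm.n_genes == 0:
        raise ValidationError("criteria matrix has no genes")
    X = cm.criteria
    out = set()
    for i in range(len(X)):
        dominated = np.any(
            np.all(X <= X[i], axis=1) & np.any(X < X[i], axis=1)
        )
        if not dominated:
            out.add(cm.gene_ids[i])
    return out


def pareto_frontier_split(cm: CriteriaMatrix, S: int) -> set:
    """Frontier via S local frontiers pooled into a global filter.

    Genes are ordered deterministically by gene id and cut into S contiguous
    blocks; each block's local frontier is extracted, the locals are pooled,
    and the frontier of the pool is returned.  The result equals
    :func:`pareto_frontier` for every valid S — the split only bounds the
    working-set size.
    """
    if cm.n_genes == 0:
        raise ValidationError("criteria matrix has no genes")
    if not 1 <= S <= cm.n_genes:
        raise ValidationError(
            f"split count S={S} must lie in [1, {cm.n_genes}] for this matrix"
        )
    order = np.argsort(cm.gene_ids.astype(str), kind="mergesort")
    pooled_idx = []
    for block in np.array_split(order, S):
        if block.size == 0:
            continue
        local = _frontier_mask(cm.criteria[block])
        pooled_idx.append(block[local])
    pooled = np.concatenate(pooled_idx)
    global_mask = _frontier_mask(cm.criteria[pooled])
    return set(cm.gene_ids[pooled[global_mask]])


def peel_frontiers(cm: CriteriaMatrix, F: int, S: int = 1) -> FrontierAssignment:
    """Extract the first F frontiers by successive removal.

    Frontier 1 is the frontier of the full matrix; frontier f+1 is the
    frontier of what remains after removing frontiers 1..f.  If the genes
    run out before F frontiers, the extraction stops early with a warning.
    """
    if F < 1:
        raise ValidationError(f"frontier count F={F} must be >= 1")
    if cm.n_genes == 0:
        raise ValidationError("criteria matrix has no genes")
    assignment = np.zeros(cm.n_genes, dtype=int)
    remaining = np.arange(cm.n_genes)
    for f in range(1, F + 1):
        if remaining.size == 0:
            warnings.warn(
                f"genes exhausted after {f - 1} frontiers; {F} were requested",
                stacklevel=2,
            )
            break
        sub = cm.take(remaining)
        if S > 1:
            front_genes = pareto_frontier_split(sub, min(S, sub.n_genes))
            mask = np.array([g in front_genes for g in sub.gene_ids])
        else:
            mask = _frontier_mask(sub.criteria)
        assignment[remaining[mask]] = f
        remaining = remaining[~mask]
    return FrontierAssignment(cm.gene_ids.copy(), assignment, F)
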