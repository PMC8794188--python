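"""Expression matrices with sample annotations.

The unit of analysis is a genes-by-samples numeric matrix together with a
per-sample annotation sheet assigning each sample to ``case`` or ``control``
and, optionally, a sex (``M``/``F``).  Values are taken on whatever scale the
input provides: no normalisation, background correction or log transformation
is applied here, mirroring how public repository series matrices are consumed
as-is.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONDITIONS = ("control", "case")
SEXES = ("M", "F")

#: Canonical sample-group names.  ``MalePD`` is accepted as an alias of
#: ``MaleCase`` (and ``FemalePD`` of ``FemaleCase``) when naming comparisons.
GROUP_NAMES = (
    "Control",
    "Case",
    "MaleControl",
    "MaleCase",
    "FemaleControl",
    "FemaleCase",
)

_GROUP_ALIASES = {
    "malepd": "MaleCase",
    "femalepd": "FemaleCase",
}


class ValidationError(ValueError):
    """Raised when an input matrix/sheet violates the dataset contract."""


def canonical_group_name(name: str) -> str:
    """Resolve a group name, accepting PD-style aliases case-insensitively."""
    low = name.strip().lower()
    if low in _GROUP_ALIASES:
        return _GROUP_ALIASES[low]
    for g in GROUP_NAMES:
        if low == g.lower():
            return g
    raise ValidationError(
        f"unknown sample group {name!r}; expected one of {', '.join(GROUP_NAMES)}"
    )


@dataclass
class SampleGroup:
    """A named subset of a dataset's samples."""

    name: str
    member_sample_ids: tuple[str, ...]

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.member_sample_ids)


@dataclass
class ExpressionDataset:
    """A validated genes-by-samples expression matrix with annotations.

    Parameters
    ----------
    dataset_id
        Short label used in provenance columns and criteria headers.
    values
        DataFrame of shape (features, samples); index holds feature ids
        (probe or gene identifiers), columns hold sample ids.  Missing
        values are retained as NaN and handled downstream by excluding
        affected genes from the comparison that touches them.
    annotations
        DataFrame indexed by sample id with a ``condition`` column in
        {"case", "control"} and an optional ``sex`` column in {"M", "F"}.
        Sex may be absent dataset-wide but never for a subset of samples.
    """

    dataset_id: str
    values: pd.DataFrame
    annotations: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValidationError(
                f"{self.dataset_id}: duplicate feature ids: {list(dupes[:5])!r}"
            )
        if self.values.columns.has_duplicates:
            dupes = self.values.columns[self.values.columns.duplicated()].unique()
            raise ValidationError(
                f"{self.dataset_id}: duplicate sample ids: {list(dupes[:5])!r}"
            )
        if "condition" not in self.annotations.columns:
            raise ValidationError(f"{self.dataset_id}: sheet lacks a 'condition' column")
        matrix_samples = set(self.values.columns)
        sheet_samples = set(self.annotations.index)
        missing = sorted(matrix_samples - sheet_samples)
        if missing:
            raise ValidationError(
                f"{self.dataset_id}: samples in matrix but not in sheet: {missing}"
            )
        extra = sorted(sheet_samples - matrix_samples)
        if extra:
            raise ValidationError(
                f"{self.dataset_id}: samples in sheet but not in matrix: {extra}"
            )
        self.annotations = self.annotations.loc[self.values.columns]
        bad = ~self.annotations["condition"].isin(CONDITIONS)
        if bad.any():
            raise ValidationError(
                f"{self.dataset_id}: unrecognised condition labels "
                f"{sorted(self.annotations.loc[bad, 'condition'].unique())}; "
                "map them to 'case'/'control' via a label map"
            )
        if self.has_sex:
            sex = self.annotations["sex"]
            if sex.isna().any():
                missing_sex = sorted(self.annotations.index[sex.isna()])
                raise ValidationError(
                    f"{self.dataset_id}: sex annotated for some samples but "
                    f"missing for {missing_sex}"
                )
            bad = ~sex.isin(SEXES)
            if bad.any():
                raise ValidationError(
                    f"{self.dataset_id}: sex labels must be in {SEXES}, got "
                    f"{sorted(sex[bad].unique())}"
                )

    # -- basic accessors ---------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def has_sex(self) -> bool:
        return "sex" in self.annotations.columns

    def group_values(self, group: SampleGroup) -> pd.DataFrame:
        """Sub-matrix restricted to the samples of one group."""
        return self.values[list(group.member_sample_ids)]


def _normalise_labels(
    series: pd.Series, label_map: dict[str, str] | None
) -> pd.Series:
    """Lower-case condition labels, then apply the user's label map.

    Only an explicit map can fold study-specific labels (``PD``,
    ``disease`` ...) into ``case``/``control``; nothing is guessed.
    """
    out = series.astype(str).str.strip().str.lower()
    if label_map:
        lowered = {k.strip().lower(): v.strip().lower() for k, v in label_map.items()}
        out = out.map(lambda x: lowered.get(x, x))
    return out


def read_expression(
    matrix_path,
    sheet_path,
    dataset_id: str | None = None,
    label_map: dict[str, str] | None = None,
) -> ExpressionDataset:
    """Read a TSV expression matrix and its sample sheet.

    The matrix is tab-separated with a header row of sample ids and a first
    column of feature ids.  The sheet is tab-separated with columns
    ``sample``, ``condition`` and optionally ``sex``.  Cells that are empty
    or ``NA`` become missing values; any other non-numeric cell is an error
    naming the offending feature and sample.
    """
    try:
        matrix = pd.read_csv(
            matrix_path, sep="\t", index_col=0, dtype=str, keep_default_na=False
        )
    except pd.errors.ParserError as exc:
        raise ValidationError(f"malformed matrix TSV {matrix_path}: {exc}") from exc
    try:
        sheet = pd.read_csv(sheet_path, sep="\t", dtype=str)
    except pd.errors.ParserError as exc:
        raise ValidationError(f"malformed sheet TSV {sheet_path}: {exc}") from exc

    matrix.index = matrix.index.astype(str)
    matrix.columns = matrix.columns.astype(str)
    values = matrix.replace({"": np.nan, "NA": np.nan, "NaN": np.nan, "nan": np.nan})
    probe = values.apply(pd.to_numeric, errors="coerce")
    bad = probe.isna() & values.notna()
    if bad.to_numpy().any():
        gene_idx, samp_idx = np.argwhere(bad.to_numpy())[0]
        raise ValidationError(
            f"non-numeric value {values.iat[gene_idx, samp_idx]!r} for feature "
            f"{values.index[gene_idx]!r}, sample {values.columns[samp_idx]!r}"
        )
    # exact (correctly rounded) parse so write-then-read is bit-identical
    numeric = values.apply(
        lambda col: col.map(lambda x: np.nan if pd.isna(x) else float(x))
    )

    if "sample" not in sheet.columns or "condition" not in sheet.columns:
        raise ValidationError(
            f"sheet {sheet_path} must have columns 'sample' and 'condition'"
        )
    if sheet["sample"].duplicated().any():
        dupes = sorted(sheet.loc[sheet["sample"].duplicated(), "sample"].unique())
        raise ValidationError(f"duplicate sample ids in sheet: {dupes}")
    ann = sheet.set_index("sample")
    ann["condition"] = _normalise_labels(ann["condition"], label_map)
    if "sex" in ann.columns:
        ann["sex"] = ann["sex"].astype(str).str.strip().str.upper().replace(
            {"MALE": "M", "FEMALE": "F", "NAN": np.nan, "": np.nan}
        )
        if ann["sex"].isna().all():
            ann = ann.drop(columns="sex")

    if dataset_id is None:
        dataset_id = str(matrix_path)
    return ExpressionDataset(dataset_id=dataset_id, values=numeric, annotations=ann)


def write_expression(ds: ExpressionDataset, matrix_path, sheet_path) -> None:
    """Write the matrix and sheet back to the TSV dialect ``read_expression`` reads."""
    out = ds.values.copy()
    out.index.name = "feature"
    out.to_csv(matrix_path, sep="\t", na_rep="NA", float_format="%.17g")
    ann = ds.annotations.reset_index().rename(columns={"index": "sample"})
    if ann.columns[0] != "sample":
        ann = ann.rename(columns={ann.columns[0]: "sample"})
    ann.to_csv(sheet_path, sep="\t", index=False)


COLLAPSE_METHODS = ("median", "mean", "max_variance")


def collapse_probes(
    ds: ExpressionDataset,
    mapping: dict[str, str],
    method: str = "median",
) -> ExpressionDataset:
    """Collapse probe-level rows to one row per gene symbol.

    ``mapping`` sends probe ids to gene symbols; probes without a mapping are
    dropped.  With ``median``/``mean`` the gene row is the per-sample
    statistic over that gene's probes; ``max_variance`` keeps the single
    probe with the largest across-sample variance.
    """
    if not mapping:
        raise ValidationError("probe-to-gene mapping is empty")
    if method not in COLLAPSE_METHODS:
        raise ValidationError(
            f"unknown collapse method {method!r}; expected one of {COLLAPSE_METHODS}"
        )
    mapped = [p for p in ds.feature_ids if p in mapping]
    if not mapped:
        raise ValidationError("mapping covers none of the dataset's features")
    sub = ds.values.loc[mapped]
    symbols = pd.Series([mapping[p] for p in mapped], index=sub.index, name="symbol")
    if method == "max_variance":
        variances = sub.var(axis=1, ddof=1)
        best = variances.groupby(symbols).idxmax()
        collapsed = sub.loc[best.to_numpy()]
        collapsed.index = best.index
    else:
        grouped = sub.groupby(symbols)
        collapsed = grouped.median() if method == "median" else grouped.mean()
    collapsed = collapsed.sort_index()
    dropped = ds.n_features - len(mapped)
    if dropped:
        logger.info(
            "%s: dropped %d unmapped features while collapsing", ds.dataset_id, dropped
        )
    return ExpressionDataset(
        dataset_id=ds.dataset_id, values=collapsed, annotations=ds.annotations.copy()
    )


def build_groups(
    ds: ExpressionDataset, stratify_by_sex: bool = False
) -> dict[str, SampleGroup]:
    """Partition the samples into condition (optionally sex-stratified) groups.

    Without stratification returns ``{Control, Case}``; with it the four
    groups MaleControl, MaleCase, FemaleControl, FemaleCase.  Every group of
    the requested partition must be non-empty.
    """
    ann = ds.annotations
    if stratify_by_sex:
        if not ds.has_sex:
            raise ValidationError(
                f"{ds.dataset_id}: sex-stratified groups requested but the sheet "
                "has no sex annotations"
            )
        spec = [
            ("MaleControl", "M", "control"),
            ("MaleCase", "M", "case"),
            ("FemaleControl", "F", "control"),
            ("FemaleCase", "F", "case"),
        ]
        groups = {}
        for name, sex, cond in spec:
            members = ann.index[(ann["sex"] == sex) & (ann["condition"] == cond)]
            if len(members) == 0:
                raise ValidationError(f"{ds.dataset_id}: group {name} is empty")
            groups[name] = SampleGroup(name, tuple(members))
        return groups
    groups = {}
    for name, cond in (("Control", "control"), ("Case", "case")):
        members = ann.index[ann["condition"] == cond]
        if len(members) == 0:
            raise ValidationError(f"{ds.dataset_id}: group {name} is empty")
        groups[name] = SampleGroup(name, tuple(members))
    return groups


def resolve_groups(
    ds: ExpressionDataset, group_a: str, group_b: str
) -> tuple[SampleGroup, SampleGroup]:
    """Build the grouping a comparison needs and return its two groups."""
    a, b = canonical_group_name(group_a), canonical_group_name(group_b)
    stratified = a not in ("Control", "Case") or b not in ("Control", "Case")
    groups = build_groups(ds, stratify_by_sex=stratified)
    if a not in groups or b not in groups:
        raise ValidationError(
            f"comparison ({a}, {b}) mixes stratified and unstratified group names"
        )
    if a == b:
        raise ValidationError("a comparison needs two distinct groups")
    return groups[a], groups[b]
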