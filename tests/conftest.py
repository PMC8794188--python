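import numpy as np
import pandas as pd
import pytest

from mcoselect import ExpressionDataset


def make_dataset(
    rows: dict[str, list[float]],
    conditions: list[str],
    sexes: list[str] | None = None,
    dataset_id: str = "toy",
) -> ExpressionDataset:
    """Build a small in-memory dataset from literal per-gene sample values."""
    n_samples = len(conditions)
    sample_ids = [f"s{i + 1}" for i in range(n_samples)]
    values = pd.DataFrame(rows, index=sample_ids).T
    ann = {"condition": conditions}
    if sexes is not None:
        ann["sex"] = sexes
    annotations = pd.DataFrame(ann, index=pd.Index(sample_ids, name="sample"))
    return ExpressionDataset(dataset_id=dataset_id, values=values, annotations=annotations)


@pytest.fixture
def toy_dataset() -> ExpressionDataset:
    """3 genes x 4 samples, 2 case / 2 control, no sex annotations."""
    return make_dataset(
        {
            "gA": [1.0, 2.0, 5.0, 7.0],
            "gB": [4.0, 4.0, 4.0, 4.0],
            "gC": [2.0, 3.0, 3.0, 2.0],
        },
        conditions=["control", "control", "case", "case"],
    )


@pytest.fixture
def stratified_dataset() -> ExpressionDataset:
    """2 genes x 8 samples covering all four sex-by-condition groups."""
    return make_dataset(
        {
            "gA": [1.0, 2.0, 5.0, 6.0, 1.5, 2.5, 5.5, 6.5],
            "gB": [3.0, 3.0, 3.0, 3.0, 3.0, 3.0, 3.0, 3.0],
        },
        conditions=["control", "control", "case", "case"] * 2,
        sexes=["M"] * 4 + ["F"] * 4,
    )


def random_criteria(rng: np.random.Generator, n: int, C: int, ties: bool = False):
    """Random nonnegative criteria rows; optionally discretised to force ties."""
    X = rng.random((n, C))
    if ties:
        X = np.round(X, 1)
    genes = np.array([f"g{i:05d}" for i in range(n)], dtype=object)
    return genes, X
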