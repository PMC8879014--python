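"""Min-max normalization to [-1, +1] and the 70/15/15 partition.

Normalization is the affine map y = (ymax - ymin)(x - xmin)/(xmax - xmin)
+ ymin with ymin = -1, ymax = +1; values outside the fitted range map
outside [-1, 1] without clipping so the transform stays invertible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "NormalizationSpec",
    "SplitIndices",
    "fit_normalizer",
    "normalize",
    "denormalize",
    "normalize_frame",
    "split_dataset",
]


@dataclass(frozen=True)
class NormalizationSpec:
    xmin: float
    xmax: float
    ymin: float = -1.0
    ymax: float = 1.0

    def __post_init__(self) -> None:
        if not self.xmin < self.xmax:
            raise ValueError("xmin must be < xmax (constant column?)")
        if not self.ymin < self.ymax:
            raise ValueError("ymin must be < ymax")


@dataclass(frozen=True)
class SplitIndices:
    """Disjoint train/validation/test row indices covering 0..n-1."""

    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray
    seed: int

    @property
    def n(self) -> int:
        return len(self.train) + len(self.validation) + len(self.test)

    def as_dict(self) -> dict[str, list[int]]:
        return {
            "train": self.train.tolist(),
            "validation": self.validation.tolist(),
            "test": self.test.tolist(),
            "seed": self.seed,
        }


def fit_normalizer(
    data: pd.DataFrame,
    scope: str = "whole_dataset",
    train_indices: np.ndarray | None = None,
) -> dict[str, NormalizationSpec]:
    """Fit one NormalizationSpec per column.

    scope="whole_dataset" uses every row; scope="train_only" restricts the
    min/max to the given training rows (leakage-safe variant).
    """
    if len(data) == 0:
        raise ValueError("cannot fit a normalizer on an empty dataset")
    if scope == "whole_dataset":
        rows = data
    elif scope == "train_only":
        if train_indices is None:
            raise ValueError("train_only scope requires train_indices")
        rows = data.iloc[train_indices]
    else:
        raise ValueError(f"unknown scope {scope!r}")
    return {
        col: NormalizationSpec(float(rows[col].min()), float(rows[col].max()))
        for col in data.columns
    }


def normalize(x, spec: NormalizationSpec):
    x = np.asarray(x, dtype=float)
    y = (spec.ymax - spec.ymin) * (x - spec.xmin) / (spec.xmax - spec.xmin) + spec.ymin
    return y if y.ndim else float(y)


def denormalize(y, spec: NormalizationSpec):
    y = np.asarray(y, dtype=float)
    x = (y - spec.ymin) * (spec.xmax - spec.xmin) / (spec.ymax - spec.ymin) + spec.xmin
    return x if x.ndim else float(x)


def normalize_frame(
    data: pd.DataFrame, specs: dict[str, NormalizationSpec]
) -> pd.DataFrame:
    out = {col: normalize(data[col].to_numpy(), specs[col]) for col in data.columns}
    return pd.DataFrame(out, index=data.index, columns=data.columns)


def split_dataset(
    n: int,
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
) -> SplitIndices:
    """Random 70/15/15 partition: floor rounding for train and validation,
    remainder to test (56/12/12 at n = 80)."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n_train = int(np.floor(fractions[0] * n))
    n_val = int(np.floor(fractions[1] * n))
    n_test = n - n_train - n_val
    if min(n_train, n_val, n_test) < 1:
        raise ValueError(f"n = {n} too small for a {fractions} split")
    perm = np.random.default_rng(seed).permutation(n)
    return SplitIndices(
        train=np.sort(perm[:n_train]),
        validation=np.sort(perm[n_train:n_train + n_val]),
        test=np.sort(perm[n_train + n_val:]),
        seed=seed,
    )
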