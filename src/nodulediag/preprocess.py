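"""Feature construction: z-normalized continuous blocks, one-hot discrete blocks.

The seven marker concentrations are z-normalized per marker,
``x -> (x - mu) / sigma``, and concatenated into one 7-dimensional
continuous feature; lesion diameter is z-normalized the same way as its own
1-dimensional feature.  Every discrete clinical/imaging feature becomes a
one-hot vector over its fixed category list.  Normalization statistics are
fitted on the training split only and persisted next to trained models.

Conventions: sigma is the population SD (divide by n).  An unseen category
at transform time is an error, never a silent extra column; missing values
are never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from nodulediag.cohort import COMPOSITIONS, MARKERS, SIGN_COLUMNS


class NormalizationError(ValueError):
    """Degenerate statistics (zero variance) or unfitted/unseen input."""


@dataclass(frozen=True)
class FeatureSpec:
    """One model input feature.

    ``kind`` is ``continuous`` (columns taken as-is after z-normalization;
    the input dimension is the number of columns) or ``discrete`` (a single
    column one-hot encoded over ``categories``).
    """

    name: str
    kind: str
    columns: tuple[str, ...]
    categories: tuple = ()

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "discrete"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.kind == "discrete" and (len(self.columns) != 1 or not self.categories):
            raise ValueError(f"{self.name}: discrete feature needs 1 column + categories")
        if not self.columns:
            raise ValueError(f"{self.name}: needs at least one column")

    @property
    def dim(self) -> int:
        return len(self.categories) if self.kind == "discrete" else len(self.columns)

    def to_dict(self) -> dict:
        return {"name": self.name, "kind": self.kind,
                "columns": list(self.columns), "categories": list(self.categories)}

    @classmethod
    def from_dict(cls, d) -> "FeatureSpec":
        return cls(name=d["name"], kind=d["kind"],
                   columns=tuple(d["columns"]), categories=tuple(d["categories"]))


def default_feature_specs(include_imaging: bool = True) -> list[FeatureSpec]:
    """The standard input features: the 7-marker vector, diameter, clinical
    history, and (optionally) nodule/CT features."""
    specs = [
        FeatureSpec("aab", "continuous", MARKERS),
        FeatureSpec("diameter", "continuous", ("diameter_mm",)),
        FeatureSpec("gender", "discrete", ("gender",), ("male", "female")),
        FeatureSpec("age_band", "discrete", ("age_band",), ("le60", "gt60")),
        FeatureSpec("smoking", "discrete", ("smoking",), ("ever", "never")),
    ]
    if include_imaging:
        specs.append(FeatureSpec("n_nodules", "discrete", ("n_nodules",),
                                 ("single", "multiple")))
        specs.append(FeatureSpec("composition", "discrete", ("composition",),
                                 COMPOSITIONS))
        for col in SIGN_COLUMNS:
            specs.append(FeatureSpec(col, "discrete", (col,), (1, 0)))
    return specs


@dataclass(frozen=True)
class NormalizationStats:
    """Per-column mean and population SD of the continuous features."""

    mean: dict[str, float]
    sd: dict[str, float]
    fitted_on: str = ""

    def to_dict(self) -> dict:
        return {"mean": dict(self.mean), "sd": dict(self.sd),
                "fitted_on": self.fitted_on}

    @classmethod
    def from_dict(cls, d) -> "NormalizationStats":
        return cls(mean=dict(d["mean"]), sd=dict(d["sd"]),
                   fitted_on=d.get("fitted_on", ""))


def fit_normalization(
    cohort: pd.DataFrame,
    specs: Sequence[FeatureSpec] | None = None,
    fitted_on: str = "",
) -> NormalizationStats:
    """Mean and population SD of every continuous column over the given split."""
    if len(cohort) == 0:
        raise NormalizationError("cannot fit normalization on an empty cohort")
    if specs is None:
        specs = default_feature_specs()
    mean: dict[str, float] = {}
    sd: dict[str, float] = {}
    for spec in specs:
        if spec.kind != "continuous":
            continue
        for col in spec.columns:
            x = cohort[col].to_numpy(dtype=float)
            m, s = float(x.mean()), float(x.std(ddof=0))
            if s <= 0:
                raise NormalizationError(f"{col}: zero variance, cannot normalize")
            mean[col], sd[col] = m, s
    return NormalizationStats(mean=mean, sd=sd, fitted_on=fitted_on)


def transform(
    cohort: pd.DataFrame,
    stats: NormalizationStats,
    specs: Sequence[FeatureSpec] | None = None,
) -> list[np.ndarray]:
    """Feature matrices, one (n_patients, dim_i) array per spec, in spec order."""
    if specs is None:
        specs = default_feature_specs()
    out: list[np.ndarray] = []
    n = len(cohort)
    for spec in specs:
        if spec.kind == "continuous":
            block = np.empty((n, spec.dim), dtype=float)
            for j, col in enumerate(spec.columns):
                if col not in stats.mean:
                    raise NormalizationError(f"{col}: no fitted statistics")
                x = cohort[col].to_numpy(dtype=float)
                block[:, j] = (x - stats.mean[col]) / stats.sd[col]
            out.append(block)
        else:
            col = spec.columns[0]
            values = cohort[col].to_numpy()
            cats = list(spec.categories)
            block = np.zeros((n, spec.dim), dtype=float)
            hit = np.zeros(n, dtype=bool)
            for j, cat in enumerate(cats):
                mask = values == cat
                block[mask, j] = 1.0
                hit |= mask
            if not hit.all():
                bad = sorted({str(v) for v in values[~hit]})
                raise NormalizationError(f"{col}: unseen categories {bad}")
            out.append(block)
    return out


def inverse_transform_continuous(
    block: np.ndarray, spec: FeatureSpec, stats: NormalizationStats
) -> np.ndarray:
    """Undo z-normalization of one continuous block (algebraic inverse)."""
    if spec.kind != "continuous":
        raise ValueError("inverse transform applies to continuous features only")
    z = np.asarray(block, dtype=float)
    mu = np.array([stats.mean[c] for c in spec.columns])
    sigma = np.array([stats.sd[c] for c in spec.columns])
    return z * sigma + mu
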