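"""Synthetic patient cohort generation for lung-nodule diagnostics.

Real patient-level data behind the 7-autoantibody (7-AAB) panel studies are
not publicly deposited; what is published are class-conditional summary
statistics — per-marker concentration means and SDs, per-marker positivity
rates, and category frequencies for clinical and CT features, separately for
the malignant and benign groups.  This module turns those printed summaries
into a generative model:

* each marker concentration is drawn from a class-conditional log-normal
  whose arithmetic mean and SD are moment-matched to the printed values
  (log-normals are nonnegative and right-skewed; the printed SDs exceed the
  means, which rules out anything symmetric);
* categorical clinical/imaging features are drawn from the printed
  class-conditional frequency tables;
* lesion diameter is drawn from a class-conditional log-normal matched to
  the printed mean/SD, and size-bin membership is derived from the sampled
  value rather than sampled separately;
* tumour stage is assigned to malignant records only.

Markers are independent within a patient by default (no correlation
structure is published); a Gaussian-copula hook accepts an optional 7x7
correlation matrix.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtri

MARKERS: tuple[str, ...] = (
    "P53", "PGP9_5", "SOX2", "GAGE7", "GBU4_5", "MAGEA1", "CAGE",
)
SIGNS: tuple[str, ...] = (
    "vessel", "spiculation", "lobulated", "pleural_indentation", "bubble_like",
)
SIGN_COLUMNS: tuple[str, ...] = tuple(f"sign_{s}" for s in SIGNS)
STAGES: tuple[str, ...] = ("AIS", "I", "II", "III", "IV")
COMPOSITIONS: tuple[str, ...] = ("GGO", "pGGN", "mGGN", "solid")
SIZE_BINS: tuple[str, ...] = ("<=8", "8-20", "20-30", ">30")

#: fixed cohort CSV column order
COHORT_COLUMNS: tuple[str, ...] = (
    ("patient_id", "label")
    + MARKERS
    + ("gender", "age_band", "smoking", "n_nodules", "composition",
       "diameter_mm", "size_bin")
    + SIGN_COLUMNS
    + ("stage",)
)


class ConfigError(ValueError):
    """Raised for invalid generator configuration (bad moments, probabilities)."""


def lognormal_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Parameters (location, scale) of the log-normal with given arithmetic
    mean and SD.

    Closed form: ``scale^2 = ln(1 + sd^2/mean^2)``,
    ``location = ln(mean) - scale^2/2``.  Both arguments are in the units of
    the measurement (U/ml for concentrations, mm for diameters).
    """
    if not (mean > 0) or not (sd > 0):
        raise ConfigError(f"mean and sd must be positive, got {mean}, {sd}")
    scale2 = math.log1p((sd / mean) ** 2)
    return math.log(mean) - scale2 / 2.0, math.sqrt(scale2)


def lognormal_mean_sd(location: float, scale: float) -> tuple[float, float]:
    """Arithmetic mean and SD implied by log-normal parameters (round-trip
    inverse of :func:`lognormal_from_moments`)."""
    mean = math.exp(location + scale**2 / 2.0)
    sd = mean * math.sqrt(math.expm1(scale**2))
    return mean, sd


@dataclass(frozen=True)
class MarkerMoments:
    """Published class-conditional summary of one autoantibody.

    Means/SDs are in U/ml; rates are the published positivity fractions
    (positives over class size) in [0, 1].
    """

    marker: str
    mean_malignant: float
    sd_malignant: float
    mean_benign: float
    sd_benign: float
    rate_malignant: float
    rate_benign: float

    def __post_init__(self) -> None:
        for name in ("mean_malignant", "sd_malignant", "mean_benign", "sd_benign"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"{self.marker}: {name} must be > 0")
        for name in ("rate_malignant", "rate_benign"):
            r = getattr(self, name)
            if not 0.0 <= r <= 1.0:
                raise ConfigError(f"{self.marker}: {name} must be in [0, 1]")
        if not self.mean_malignant > self.mean_benign:
            raise ConfigError(
                f"{self.marker}: malignant mean must exceed benign mean"
            )

    def law(self, label: str) -> tuple[float, float]:
        """Moment-matched log-normal (location, scale) for one class."""
        if label == "malignant":
            return lognormal_from_moments(self.mean_malignant, self.sd_malignant)
        return lognormal_from_moments(self.mean_benign, self.sd_benign)


@dataclass(frozen=True)
class DiscreteFeature:
    """Class-conditional category probabilities for one discrete feature."""

    name: str
    categories: tuple
    p_malignant: tuple[float, ...]
    p_benign: tuple[float, ...]

    def __post_init__(self) -> None:
        k = len(self.categories)
        for attr in ("p_malignant", "p_benign"):
            p = getattr(self, attr)
            if len(p) != k:
                raise ConfigError(f"{self.name}: {attr} length != category count")
            if any(q < 0 for q in p):
                raise ConfigError(f"{self.name}: negative probability in {attr}")
            if abs(sum(p) - 1.0) > 1e-9:
                raise ConfigError(f"{self.name}: {attr} must sum to 1")

    def probs(self, label: str) -> tuple[float, ...]:
        return self.p_malignant if label == "malignant" else self.p_benign


@dataclass
class CohortConfig:
    """Everything needed to simulate one cohort reproducibly."""

    n_malignant: int
    n_benign: int
    moments: dict[str, MarkerMoments]
    discrete: dict[str, DiscreteFeature]
    stage_probs: dict[str, float]
    diameter_malignant: tuple[float, float]  # (mean, sd) in mm
    diameter_benign: tuple[float, float]
    seed: int = 0
    marker_correlation: np.ndarray | None = None  # Gaussian copula hook

    def __post_init__(self) -> None:
        if self.n_malignant < 0 or self.n_benign < 0:
            raise ConfigError("class sizes must be nonnegative")
        if self.n_malignant + self.n_benign == 0:
            raise ConfigError("cohort must contain at least one patient")
        if set(self.moments) != set(MARKERS):
            raise ConfigError("moments must cover exactly the 7 panel markers")
        if abs(sum(self.stage_probs.values()) - 1.0) > 1e-9:
            raise ConfigError("stage probabilities must sum to 1")
        if set(self.stage_probs) != set(STAGES):
            raise ConfigError(f"stage probabilities must cover {STAGES}")
        for dia in (self.diameter_malignant, self.diameter_benign):
            if not (dia[0] > 0 and dia[1] > 0):
                raise ConfigError("diameter mean/sd must be positive")
        if self.marker_correlation is not None:
            c = np.asarray(self.marker_correlation, dtype=float)
            if c.shape != (7, 7) or not np.allclose(c, c.T):
                raise ConfigError("marker correlation must be symmetric 7x7")
            self.marker_correlation = c

    def to_dict(self) -> dict:
        """JSON/YAML-serializable representation."""
        d = {
            "n_malignant": self.n_malignant,
            "n_benign": self.n_benign,
            "seed": self.seed,
            "moments": {m: dataclasses.asdict(v) for m, v in self.moments.items()},
            "discrete": {
                k: {
                    "categories": list(v.categories),
                    "p_malignant": list(v.p_malignant),
                    "p_benign": list(v.p_benign),
                }
                for k, v in self.discrete.items()
            },
            "stage_probs": dict(self.stage_probs),
            "diameter_malignant": list(self.diameter_malignant),
            "diameter_benign": list(self.diameter_benign),
        }
        if self.marker_correlation is not None:
            d["marker_correlation"] = self.marker_correlation.tolist()
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        corr = d.get("marker_correlation")
        return cls(
            n_malignant=int(d["n_malignant"]),
            n_benign=int(d["n_benign"]),
            moments={
                m: MarkerMoments(**v) for m, v in d["moments"].items()
            },
            discrete={
                k: DiscreteFeature(
                    name=k,
                    categories=tuple(v["categories"]),
                    p_malignant=tuple(v["p_malignant"]),
                    p_benign=tuple(v["p_benign"]),
                )
                for k, v in d["discrete"].items()
            },
            stage_probs=dict(d["stage_probs"]),
            diameter_malignant=tuple(d["diameter_malignant"]),
            diameter_benign=tuple(d["diameter_benign"]),
            seed=int(d.get("seed", 0)),
            marker_correlation=None if corr is None else np.asarray(corr, float),
        )


def assign_size_bin(diameter_mm) -> np.ndarray:
    """Lesion size bin from diameter: <=8, 8-20, 20-30, >30 mm."""
    d = np.asarray(diameter_mm, dtype=float)
    bins = np.empty(d.shape, dtype=object)
    bins[d <= 8] = "<=8"
    bins[(d > 8) & (d <= 20)] = "8-20"
    bins[(d > 20) & (d <= 30)] = "20-30"
    bins[d > 30] = ">30"
    return bins


def _sample_class(
    label: str, n: int, config: CohortConfig, rng: np.random.Generator
) -> pd.DataFrame:
    prefix = "M" if label == "malignant" else "B"
    out: dict[str, np.ndarray] = {
        "patient_id": np.array([f"{prefix}{i:05d}" for i in range(n)], dtype=object),
        "label": np.full(n, label, dtype=object),
    }
    # marker concentrations: independent standard normals, or a Gaussian
    # copula when a correlation matrix is configured, pushed through the
    # per-marker moment-matched log-normal
    if config.marker_correlation is None:
        z = rng.standard_normal((n, 7))
    else:
        chol = np.linalg.cholesky(config.marker_correlation)
        z = rng.standard_normal((n, 7)) @ chol.T
    for j, marker in enumerate(MARKERS):
        loc, scale = config.moments[marker].law(label)
        out[marker] = np.exp(loc + scale * z[:, j])
    for name, feat in config.discrete.items():
        cats = np.asarray(feat.categories, dtype=object)
        idx = rng.choice(len(cats), size=n, p=np.asarray(feat.probs(label)))
        out[name] = cats[idx]
    mean, sd = (
        config.diameter_malignant if label == "malignant" else config.diameter_benign
    )
    loc, scale = lognormal_from_moments(mean, sd)
    out["diameter_mm"] = np.exp(loc + scale * rng.standard_normal(n))
    out["size_bin"] = assign_size_bin(out["diameter_mm"])
    if label == "malignant":
        stages = np.asarray(STAGES, dtype=object)
        p = np.asarray([config.stage_probs[s] for s in STAGES])
        out["stage"] = stages[rng.choice(len(stages), size=n, p=p)]
    else:
        out["stage"] = np.full(n, "", dtype=object)
    return pd.DataFrame(out)


def sample_cohort(config: CohortConfig) -> pd.DataFrame:
    """Draw a full synthetic cohort (malignant rows first, then benign).

    The same seed always yields the identical cohort.
    """
    rng = np.random.default_rng(config.seed)
    parts = []
    for label, n in (("malignant", config.n_malignant), ("benign", config.n_benign)):
        if n > 0:
            parts.append(_sample_class(label, n, config, rng))
    df = pd.concat(parts, ignore_index=True)
    return df[list(COHORT_COLUMNS)]


def fit_default_cutoffs(moments: Mapping[str, MarkerMoments]) -> dict[str, float]:
    """Positivity cutoffs (U/ml) reproducing the published malignant-class
    positivity rates by construction.

    The assay kit's true cutoffs are not published.  Each default cutoff is
    the ``1 - rate_malignant`` quantile of the malignant-class moment-matched
    log-normal, so that simulated malignant patients exceed it at exactly the
    published per-marker rate.  Benign-class rates then emerge from the
    benign law and land near (not exactly at) the published values.
    """
    cutoffs = {}
    for marker, mm in moments.items():
        r = mm.rate_malignant
        if not 0.0 < r < 1.0:
            raise ConfigError(f"{marker}: cutoff undefined for rate {r}")
        loc, scale = mm.law("malignant")
        cutoffs[marker] = float(math.exp(loc + scale * ndtri(1.0 - r)))
    return cutoffs


# ---------------------------------------------------------------------------
# Preset configurations calibrated to the published class-conditional tables.
# Probabilities are stored as count ratios so they sum to 1 exactly.
# ---------------------------------------------------------------------------

# full cohort (571 malignant / 362 benign): marker mean (SD) and
# positive counts per class
_FULL_MOMENTS = {
    # marker: (mean_mal, sd_mal, mean_ben, sd_ben, k_mal/571, k_ben/362)
    "P53":    (8.87, 15.09, 3.25, 5.11, 116, 18),
    "PGP9_5": (6.17, 10.67, 3.11, 4.80, 76, 13),
    "SOX2":   (7.46, 12.14, 3.40, 5.92, 110, 21),
    "GAGE7":  (9.59, 18.01, 4.08, 7.35, 98, 13),
    "GBU4_5": (3.46, 5.45, 1.87, 3.57, 97, 19),
    "MAGEA1": (6.36, 12.08, 3.15, 7.19, 76, 16),
    "CAGE":   (3.44, 8.06, 1.75, 2.54, 53, 11),
}

# lung-nodule subcohort (459 malignant / 285 benign)
_NODULE_MOMENTS = {
    "P53":    (8.208, 14.65, 3.316, 5.128, 92, 9),
    "PGP9_5": (6.569, 10.44, 3.025, 3.936, 64, 10),
    "SOX2":   (7.739, 12.67, 3.127, 4.971, 83, 14),
    "GAGE7":  (9.34, 17.36, 4.405, 8.020, 81, 12),
    "GBU4_5": (3.542, 5.693, 1.954, 3.822, 78, 17),
    "MAGEA1": (6.098, 11.44, 3.334, 7.892, 58, 13),
    "CAGE":   (3.397, 7.891, 1.766, 2.653, 42, 8),
}

_FULL_N = (571, 362)
_NODULE_N = (459, 285)

# demographics (full-cohort counts)
_FULL_DEMOGRAPHICS = {
    "gender": (("male", "female"), (282, 289), (208, 154)),
    "age_band": (("le60", "gt60"), (316, 255), (258, 104)),
    "smoking": (("ever", "never"), (236, 335), (154, 208)),
}

# nodule-table counts: nodule count, CT composition, imaging sign positives
_NODULE_FEATURES = {
    "n_nodules": (("single", "multiple"), (260, 199), (144, 141)),
    "composition": (COMPOSITIONS, (41, 103, 214, 101), (26, 21, 15, 223)),
}
_SIGN_COUNTS = {
    # sign: (k_malignant/459, k_benign/285)
    "vessel": (361, 24),
    "spiculation": (179, 42),
    "lobulated": (207, 51),
    "pleural_indentation": (154, 37),
    "bubble_like": (93, 26),
}
_STAGE_COUNTS = {"AIS": 43, "I": 302, "II": 51, "III": 31, "IV": 32}  # /459

_DIAMETER = {"malignant": (16.5, 9.0), "benign": (12.4, 5.7)}  # mm


def _ratios(counts: Sequence[int], total: int) -> tuple[float, ...]:
    return tuple(c / total for c in counts)


def _moments_from_table(table: Mapping, n_mal: int, n_ben: int) -> dict[str, MarkerMoments]:
    return {
        m: MarkerMoments(
            marker=m,
            mean_malignant=v[0], sd_malignant=v[1],
            mean_benign=v[2], sd_benign=v[3],
            rate_malignant=v[4] / n_mal, rate_benign=v[5] / n_ben,
        )
        for m, v in table.items()
    }


def _discrete_features(n_mal: int, n_ben: int) -> dict[str, DiscreteFeature]:
    feats: dict[str, DiscreteFeature] = {}
    for name, (cats, k_mal, k_ben) in _FULL_DEMOGRAPHICS.items():
        feats[name] = DiscreteFeature(
            name, tuple(cats), _ratios(k_mal, _FULL_N[0]), _ratios(k_ben, _FULL_N[1])
        )
    for name, (cats, k_mal, k_ben) in _NODULE_FEATURES.items():
        feats[name] = DiscreteFeature(
            name, tuple(cats),
            _ratios(k_mal, _NODULE_N[0]), _ratios(k_ben, _NODULE_N[1]),
        )
    for sign, (k_mal, k_ben) in _SIGN_COUNTS.items():
        p_mal = k_mal / _NODULE_N[0]
        p_ben = k_ben / _NODULE_N[1]
        feats[f"sign_{sign}"] = DiscreteFeature(
            f"sign_{sign}", (1, 0), (p_mal, 1 - p_mal), (p_ben, 1 - p_ben)
        )
    return feats


def _stage_probs() -> dict[str, float]:
    return {s: k / _NODULE_N[0] for s, k in _STAGE_COUNTS.items()}


def full_cohort_config(seed: int = 0, n_malignant: int | None = None,
                       n_benign: int | None = None) -> CohortConfig:
    """Preset emulating the full lung-disease cohort (571 malignant / 362
    benign by default).

    Marker moments and demographics come from the full-cohort tables;
    nodule-specific features (count, composition, imaging signs, stage) are
    only published for the nodule subcohort and are reused here so every
    record carries the complete feature schema.
    """
    return CohortConfig(
        n_malignant=_FULL_N[0] if n_malignant is None else n_malignant,
        n_benign=_FULL_N[1] if n_benign is None else n_benign,
        moments=_moments_from_table(_FULL_MOMENTS, *_FULL_N),
        discrete=_discrete_features(*_FULL_N),
        stage_probs=_stage_probs(),
        diameter_malignant=_DIAMETER["malignant"],
        diameter_benign=_DIAMETER["benign"],
        seed=seed,
    )


def nodule_cohort_config(seed: int = 0, n_malignant: int | None = None,
                         n_benign: int | None = None) -> CohortConfig:
    """Preset emulating the early lung-nodule subcohort (459 malignant /
    285 benign by default); the default input for the network model."""
    return CohortConfig(
        n_malignant=_NODULE_N[0] if n_malignant is None else n_malignant,
        n_benign=_NODULE_N[1] if n_benign is None else n_benign,
        moments=_moments_from_table(_NODULE_MOMENTS, *_NODULE_N),
        discrete=_discrete_features(*_NODULE_N),
        stage_probs=_stage_probs(),
        diameter_malignant=_DIAMETER["malignant"],
        diameter_benign=_DIAMETER["benign"],
        seed=seed,
    )


def cohort_to_csv(df: pd.DataFrame, path) -> None:
    """Write a cohort with the fixed column order (deterministic bytes)."""
    df[list(COHORT_COLUMNS)].to_csv(path, index=False, lineterminator="\n")


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False, dtype={"stage": str})
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigError(f"cohort file lacks columns: {missing}")
    return df[list(COHORT_COLUMNS)]
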