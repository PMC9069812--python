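"""The 7-autoantibody combined positivity rule and diagnostic statistics.

A patient's panel result is positive when at least one of the seven markers
exceeds its cutoff (strictly above; a concentration exactly at the threshold
is negative).  Performance is summarized by sensitivity/specificity/accuracy
with exact (Clopper-Pearson) binomial confidence intervals, group
differences by Mann-Whitney U and 2x2 chi-square tests, and ranking quality
by ROC curves with trapezoidal AUC.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from nodulediag.cohort import MARKERS


class MissingDataError(ValueError):
    """A required concentration is absent; the panel call refuses to impute."""


def _validate_cutoffs(cutoffs: Mapping[str, float]) -> None:
    missing = [m for m in MARKERS if m not in cutoffs]
    if missing:
        raise ValueError(f"cutoffs missing markers: {missing}")
    bad = [m for m in MARKERS if not cutoffs[m] > 0]
    if bad:
        raise ValueError(f"cutoffs must be positive: {bad}")


def call_panel(cohort: pd.DataFrame, cutoffs: Mapping[str, float]) -> pd.DataFrame:
    """Per-marker and combined positivity calls for every patient.

    Returns a frame with one boolean column ``pos_<marker>`` per marker and
    a ``panel_positive`` column that is their disjunction.  A marker is
    positive iff its concentration is strictly above the cutoff.
    """
    _validate_cutoffs(cutoffs)
    conc = cohort[list(MARKERS)].to_numpy(dtype=float)
    if not np.isfinite(conc).all():
        raise MissingDataError("non-finite marker concentration in cohort")
    calls = pd.DataFrame(index=cohort.index)
    for j, m in enumerate(MARKERS):
        calls[f"pos_{m}"] = conc[:, j] > cutoffs[m]
    calls["panel_positive"] = calls[[f"pos_{m}" for m in MARKERS]].any(axis=1)
    return calls


def marker_count_score(calls: pd.DataFrame) -> pd.Series:
    """Number of positive markers (0-7); the documented continuous surrogate
    score for ranking a binary panel on a ROC curve."""
    return calls[[f"pos_{m}" for m in MARKERS]].sum(axis=1).rename("n_positive")


def clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact equal-tailed binomial confidence interval via Beta quantiles.

    Lower bound is 0 when k = 0 and upper bound is 1 when k = n.
    """
    if not 0 <= k <= n or n < 1:
        raise ValueError(f"need 0 <= k <= n, n >= 1; got k={k}, n={n}")
    alpha = 1.0 - level
    low = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    high = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return low, high


@dataclass(frozen=True)
class DiagnosticPerformance:
    """Confusion counts and proportion estimates with 95% exact CIs."""

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    accuracy: float
    sensitivity_ci: tuple[float, float]
    specificity_ci: tuple[float, float]
    accuracy_ci: tuple[float, float]

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in ("tp", "fp", "tn", "fn",
                                           "sensitivity", "specificity", "accuracy")}
        d["sensitivity_ci"] = list(self.sensitivity_ci)
        d["specificity_ci"] = list(self.specificity_ci)
        d["accuracy_ci"] = list(self.accuracy_ci)
        return d


def diagnostic_performance(
    labels: Sequence, calls: Sequence, level: float = 0.95
) -> DiagnosticPerformance:
    """Sensitivity/specificity/accuracy of binary calls against truth.

    ``labels`` is truth (True/"malignant" = diseased), ``calls`` the test
    result (True = positive).  Both classes must be represented.
    """
    y = _as_bool_labels(labels)
    c = np.asarray(calls, dtype=bool)
    if y.shape != c.shape:
        raise ValueError("labels and calls must have equal length")
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be nonempty")
    tp = int((y & c).sum())
    fn = n_pos - tp
    tn = int((~y & ~c).sum())
    fp = n_neg - tn
    n = n_pos + n_neg
    return DiagnosticPerformance(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=tp / n_pos,
        specificity=tn / n_neg,
        accuracy=(tp + tn) / n,
        sensitivity_ci=clopper_pearson(tp, n_pos, level),
        specificity_ci=clopper_pearson(tn, n_neg, level),
        accuracy_ci=clopper_pearson(tp + tn, n, level),
    )


def _as_bool_labels(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype == bool:
        return arr
    if arr.dtype.kind in "iuf":
        return arr.astype(bool)
    return arr == "malignant"


def mann_whitney_u(
    x: Iterable[float], y: Iterable[float], exact_max: int = 8
) -> tuple[float, float]:
    """Mann-Whitney U (for the first group) with a two-sided p value.

    Midranks handle ties.  When both groups have at most ``exact_max``
    observations the p value is computed by full enumeration of the
    ``C(n1+n2, n1)`` rank assignments (exact even under ties); otherwise a
    normal approximation with tie correction is used.  Two degenerate groups
    with all values identical give p = 1.
    """
    xa = np.asarray(list(x), dtype=float)
    ya = np.asarray(list(y), dtype=float)
    n1, n2 = len(xa), len(ya)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([xa, ya])
    ranks = stats.rankdata(pooled)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    mu = n1 * n2 / 2.0
    if n1 <= exact_max and n2 <= exact_max:
        obs = abs(u1 - mu)
        hits = total = 0
        base = n1 * (n1 + 1) / 2.0
        for combo in itertools.combinations(range(n1 + n2), n1):
            u = ranks[list(combo)].sum() - base
            total += 1
            if abs(u - mu) >= obs - 1e-12:
                hits += 1
        return u1, hits / total
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float((counts**3 - counts).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # every value identical
        return u1, 1.0
    z = (u1 - mu) / math.sqrt(var)
    return u1, float(2.0 * stats.norm.sf(abs(z)))


def chi_square_2x2(table, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square test on a 2x2 count table (df = 1).

    No continuity correction by default; set ``yates=True`` to apply it.
    All row and column margins must be positive.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with nonnegative counts")
    rows, cols, n = t.sum(axis=1), t.sum(axis=0), t.sum()
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("all margins must be positive")
    expected = np.outer(rows, cols) / n
    diff = np.abs(t - expected)
    if yates:
        diff = np.maximum(diff - 0.5, 0.0)
    stat = float((diff**2 / expected).sum())
    return stat, float(stats.chi2.sf(stat, df=1))


def roc_curve(scores: Sequence[float], labels: Sequence) -> tuple[np.ndarray, float]:
    """ROC points (FPR, TPR) over all distinct thresholds and trapezoidal AUC.

    Tied scores are grouped at a single threshold, which makes the AUC equal
    to the pairwise concordance probability with ties counted 1/2.
    """
    y = _as_bool_labels(labels)
    s = np.asarray(scores, dtype=float)
    if len(s) == 0 or len(s) != len(y):
        raise ValueError("scores and labels must be nonempty and equal length")
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(-s, kind="mergesort")
    s_sorted, y_sorted = s[order], y[order]
    # last index of each distinct-score run
    distinct = np.nonzero(np.diff(s_sorted))[0]
    idx = np.r_[distinct, len(s_sorted) - 1]
    tp = np.cumsum(y_sorted)[idx]
    fp = np.cumsum(~y_sorted)[idx]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    points = np.column_stack([fpr, tpr])
    auc = float(np.trapezoid(tpr, fpr))
    return points, auc


@dataclass(frozen=True)
class StratumPerformance:
    """Panel performance inside one stratum; proportions are None when the
    relevant class is absent (reported as missing, never dropped)."""

    stratum: str
    n_malignant: int
    n_benign: int
    tp: int
    fn: int
    tn: int
    fp: int
    sensitivity: float | None
    sensitivity_ci: tuple[float, float] | None
    specificity: float | None
    specificity_ci: tuple[float, float] | None


def subgroup_report(
    cohort: pd.DataFrame,
    calls: pd.DataFrame,
    stratifier: str,
    level: float = 0.95,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Panel performance per stratum plus pairwise chi-square comparisons.

    ``stratifier`` is one of ``stage``, ``size_bin``, ``composition``.
    Stage is only defined for malignant records, so benign patients are
    excluded from stage strata and only sensitivities are reported there.
    The pairwise table compares malignant positivity (sensitivity) between
    strata with a 2x2 chi-square.
    """
    from nodulediag.cohort import COMPOSITIONS, SIZE_BINS, STAGES

    orders = {"stage": STAGES, "size_bin": SIZE_BINS, "composition": COMPOSITIONS}
    if stratifier not in orders:
        raise ValueError(f"stratifier must be one of {sorted(orders)}")
    is_mal = _as_bool_labels(cohort["label"].to_numpy())
    pos = calls["panel_positive"].to_numpy(dtype=bool)
    strata = cohort[stratifier].to_numpy()

    rows = []
    for value in orders[stratifier]:
        mask = strata == value
        mal = mask & is_mal
        ben = mask & ~is_mal
        tp = int(pos[mal].sum())
        fn = int(mal.sum()) - tp
        tn = int((~pos[ben]).sum())
        fp = int(ben.sum()) - tn
        sens = sens_ci = spec = spec_ci = None
        if mal.any():
            sens = tp / int(mal.sum())
            sens_ci = clopper_pearson(tp, int(mal.sum()), level)
        if ben.any():
            spec = tn / int(ben.sum())
            spec_ci = clopper_pearson(tn, int(ben.sum()), level)
        rows.append(StratumPerformance(
            stratum=str(value), n_malignant=int(mal.sum()), n_benign=int(ben.sum()),
            tp=tp, fn=fn, tn=tn, fp=fp,
            sensitivity=sens, sensitivity_ci=sens_ci,
            specificity=spec, specificity_ci=spec_ci,
        ))
    report = pd.DataFrame([r.__dict__ for r in rows]).set_index("stratum")

    pairs = []
    occupied = [r for r in rows if r.n_malignant > 0]
    for a, b in itertools.combinations(occupied, 2):
        stat, p = chi_square_2x2([[a.tp, a.fn], [b.tp, b.fn]])
        pairs.append({"stratum_a": a.stratum, "stratum_b": b.stratum,
                      "chi2": stat, "p_value": p})
    pairwise = pd.DataFrame(pairs, columns=["stratum_a", "stratum_b", "chi2", "p_value"])
    return report, pairwise
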