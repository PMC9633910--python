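"""Grain-shape phenotype statistics and mutant classification.

Each line carries replicate seed measurements (30 seeds per plant by the
measurement protocol) of grain length and width in millimetres.  Mutant lines
are compared to wild type with a two-sided two-sample test and labelled
long/short (length) or wide/narrow (width) when the shift is significant.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DataError

TRAITS = ("length", "width")
SIGNIFICANCE_LEVELS = ("ns", "*", "**")


@dataclass
class PhenotypeRecord:
    line_id: str
    trait: str
    replicates: np.ndarray

    def __post_init__(self) -> None:
        if self.trait not in TRAITS:
            raise DataError(f"unknown trait {self.trait!r}; expected one of {TRAITS}")
        self.replicates = np.asarray(self.replicates, dtype=float)
        if self.replicates.size < 2:
            raise DataError(f"{self.line_id}/{self.trait}: need >= 2 replicates")
        if np.any(self.replicates <= 0):
            raise DataError(f"{self.line_id}/{self.trait}: non-positive measurement")

    @property
    def mean(self) -> float:
        return float(self.replicates.mean())


@dataclass(frozen=True)
class TraitSummary:
    """min/max/mean/SD (mm) and coefficient of variation (percent)."""

    min: float
    max: float
    mean: float
    sd: float
    cv: float


@dataclass(frozen=True)
class ComparisonResult:
    p_value: float
    significance: str  # "ns", "*", "**"
    mean_difference: float


def summary_stats(values) -> TraitSummary:
    """Five-number summary with sample SD (n−1) and CV in percent."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise DataError(f"summary_stats needs >= 2 values, got {x.size}")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    return TraitSummary(float(x.min()), float(x.max()), mean, sd, 100.0 * sd / mean)


def compare_to_wt(
    mutant: PhenotypeRecord,
    wt: PhenotypeRecord,
    alphas: tuple[float, float] = (0.05, 0.01),
    method: str = "welch",
    n_resamples: int = 9999,
    seed: int | None = None,
) -> ComparisonResult:
    """Two-sided mutant-vs-WT comparison with a significance class.

    ``method='welch'`` runs Welch's unequal-variance t-test; ``'permutation'``
    runs an exact/Monte-Carlo permutation test on the mean difference (and is
    also the fallback when Welch's statistic is undefined, e.g. two constant
    samples).  The class is ``**`` below the smaller alpha, ``*`` below the
    larger, else ``ns``.
    """
    if mutant.trait != wt.trait:
        raise DataError(f"trait mismatch: {mutant.trait} vs {wt.trait}")
    if method not in {"welch", "permutation"}:
        raise DataError(f"unknown method {method!r}")
    a_weak, a_strong = max(alphas), min(alphas)
    x, y = mutant.replicates, wt.replicates
    diff = float(x.mean() - y.mean())

    p = math.nan
    if method == "welch":
        # near-constant samples make the Welch statistic degenerate; the
        # permutation fallback below handles them, so silence the alarms here
        with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            p = float(stats.ttest_ind(x, y, equal_var=False).pvalue)
    if method == "permutation" or math.isnan(p):
        if np.ptp(np.concatenate([x, y])) == 0.0:
            p = 1.0  # all observations identical: no evidence of any shift
        else:
            res = stats.permutation_test(
                (x, y), lambda a, b, axis=-1: a.mean(axis=axis) - b.mean(axis=axis),
                vectorized=True, n_resamples=n_resamples, alternative="two-sided",
                rng=np.random.default_rng(seed),
            )
            p = float(res.pvalue)

    if p < a_strong:
        klass = "**"
    elif p < a_weak:
        klass = "*"
    else:
        klass = "ns"
    return ComparisonResult(p, klass, diff)


def percent_change(mutant_mean: float, wt_mean: float) -> float:
    """Signed percent change of a mutant mean relative to WT, to 2 decimals."""
    if wt_mean <= 0:
        raise DataError(f"wt_mean must be positive, got {wt_mean}")
    return round(100.0 * (mutant_mean - wt_mean) / wt_mean, 2)


_LABELS = {
    ("length", 1): "long",
    ("length", -1): "short",
    ("width", 1): "wide",
    ("width", -1): "narrow",
}


def classify_mutants(table) -> dict[str, tuple[str, ...]]:
    """Label lines by the direction of their significant trait shifts.

    ``table`` is a DataFrame with columns ``line_id, trait, mutant_mean,
    wt_mean, significance`` (one row per line/trait; significance in
    {"ns", "*", "**"}).  A line significant in both traits gets both labels;
    a line with no significant trait is ``('no-change',)``.
    """
    required = {"line_id", "trait", "mutant_mean", "wt_mean", "significance"}
    missing = required - set(table.columns)
    if missing:
        raise DataError(f"classification table lacks columns: {sorted(missing)}")
    bad = set(table["significance"]) - set(SIGNIFICANCE_LEVELS)
    if bad:
        raise DataError(f"unknown significance flags: {sorted(bad)}")
    labels: dict[str, list[str]] = {line: [] for line in table["line_id"].unique()}
    for row in table.itertuples(index=False):
        if row.significance == "ns":
            continue
        direction = 1 if row.mutant_mean > row.wt_mean else -1
        labels[row.line_id].append(_LABELS[(row.trait, direction)])
    return {line: tuple(ls) if ls else ("no-change",) for line, ls in labels.items()}
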