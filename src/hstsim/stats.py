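"""Diagnostic-validity statistics.

Sensitivity, specificity and predictive values of the hearing-scale
screening rule against the pure-tone-average gold standard, each with an
exact (Clopper-Pearson) binomial 95% confidence interval from beta
quantiles; Pearson correlation with the Fisher-z interval
(atanh(r) +/- z_{0.975} / sqrt(n - 3)); classical one-way ANOVA; and the
reconstruction of integer 2x2 tables from published rounded percentages.

The reconstruction searches every non-negative integer table (tp, fn, fp,
tn) summing to the cohort size and returns the unique table whose four
metrics are closest (in max absolute percentage deviation) to the printed
values, requiring the deviation to stay within the printed precision.
Closest-match is used rather than strict re-rounding because published
tables occasionally carry a one-digit rounding slip in a single cell while
all interval bounds still identify the underlying counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class ConfusionTable:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def gold_positives(self) -> int:
        return self.tp + self.fn


@dataclass(frozen=True)
class MetricEstimate:
    estimate: float
    ci_low: float
    ci_high: float

    def as_percent(self, ndigits: int = 1) -> tuple[float, float, float]:
        return tuple(round(100 * v, ndigits) for v in (self.estimate, self.ci_low, self.ci_high))


@dataclass(frozen=True)
class DiagnosticSummary:
    sensitivity: MetricEstimate | None
    specificity: MetricEstimate | None
    ppv: MetricEstimate | None
    npv: MetricEstimate | None

    def as_dict(self) -> dict[str, MetricEstimate | None]:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
        }


def clopper_pearson_ci(successes, n, level: float = 0.95):
    """Exact two-sided binomial CI from beta quantiles.

    Vectorizes over array inputs; the lower bound is 0 when successes = 0
    and the upper bound is 1 when successes = n.
    """
    k = np.asarray(successes)
    m = np.asarray(n)
    if np.any(m <= 0):
        raise ValueError("n must be positive")
    if np.any((k < 0) | (k > m)):
        raise ValueError("successes must lie in [0, n]")
    alpha = 1.0 - level
    with np.errstate(invalid="ignore"):
        low = np.where(k == 0, 0.0, sps.beta.ppf(alpha / 2, k, m - k + 1))
        high = np.where(k == m, 1.0, sps.beta.ppf(1 - alpha / 2, k + 1, m - k))
    if np.ndim(successes) == 0 and np.ndim(n) == 0:
        return float(low), float(high)
    return low, high


def _metric(successes: int, n: int, level: float) -> MetricEstimate | None:
    if n == 0:
        return None
    lo, hi = clopper_pearson_ci(successes, n, level)
    return MetricEstimate(successes / n, lo, hi)


def diagnostic_metrics(table: ConfusionTable, level: float = 0.95) -> DiagnosticSummary:
    """Sensitivity/specificity/PPV/NPV with exact CIs; zero-denominator
    metrics come back as None (undefined) rather than raising."""
    return DiagnosticSummary(
        sensitivity=_metric(table.tp, table.tp + table.fn, level),
        specificity=_metric(table.tn, table.tn + table.fp, level),
        ppv=_metric(table.tp, table.tp + table.fp, level),
        npv=_metric(table.tn, table.tn + table.fn, level),
    )


def confusion_from_calls(screen: Sequence[bool], gold: Sequence[bool]) -> ConfusionTable:
    """Cross-tabulate paired screen/gold calls."""
    if len(screen) != len(gold):
        raise ValueError("screen and gold call sequences differ in length")
    if len(screen) == 0:
        raise ValueError("no records to tabulate")
    s = np.asarray(screen, dtype=bool)
    g = np.asarray(gold, dtype=bool)
    return ConfusionTable(
        tp=int(np.sum(s & g)),
        fn=int(np.sum(~s & g)),
        fp=int(np.sum(s & ~g)),
        tn=int(np.sum(~s & ~g)),
    )


def fisher_ci_from_r(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Fisher-z confidence interval for a Pearson correlation given r and n."""
    if not (-1 < r < 1):
        raise ValueError("Fisher CI requires |r| < 1")
    if n <= 3:
        raise ValueError("Fisher CI requires n > 3")
    z = np.arctanh(r)
    half = sps.norm.ppf(0.5 + level / 2) / np.sqrt(n - 3)
    return float(np.tanh(z - half)), float(np.tanh(z + half))


def pearson_r_with_ci(
    x: Sequence[float], y: Sequence[float], level: float = 0.95
) -> tuple[float, float, float]:
    """Sample Pearson r with its Fisher-z interval."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    if len(x) < 4:
        raise ValueError("need at least 4 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in input")
    r = float(sps.pearsonr(x, y).statistic)
    if 1.0 - abs(r) < 1e-12:
        # perfectly linear data: point estimate exact, interval degenerate
        r = 1.0 if r > 0 else -1.0
        return r, r, r
    lo, hi = fisher_ci_from_r(r, len(x), level)
    return r, lo, hi


def anova_oneway(groups: Iterable[Sequence[float]]) -> tuple[float, float]:
    """Classical fixed-effects one-way ANOVA (F, p)."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 2 for g in arrays):
        raise ValueError("every group needs at least 2 values")
    if all(np.ptp(g) == 0 for g in arrays) and len({g[0] for g in arrays}) == 1:
        # zero variance everywhere: no evidence of any difference
        return 0.0, 1.0
    res = sps.f_oneway(*arrays)
    return float(res.statistic), float(res.pvalue)


def _table_metrics_percent(t: ConfusionTable) -> tuple[float, float, float, float]:
    return (
        100 * t.tp / (t.tp + t.fn),
        100 * t.tn / (t.tn + t.fp),
        100 * t.tp / (t.tp + t.fp),
        100 * t.tn / (t.tn + t.fn),
    )


def reconstruct_counts(
    printed_percent: Mapping[str, float],
    n_total: int,
    tolerance: float = 0.1,
) -> ConfusionTable:
    """Recover the integer 2x2 table behind published rounded percentages.

    ``printed_percent`` maps 'sensitivity', 'specificity', 'ppv', 'npv' to
    percentages printed at 1 decimal.  Exhaustively scores every table with
    all four margins non-empty by its maximum absolute deviation from the
    printed values; the unique minimizer within ``tolerance`` percentage
    points is returned.  Raises if no table fits or the minimizer ties.
    """
    try:
        target = tuple(
            float(printed_percent[k]) for k in ("sensitivity", "specificity", "ppv", "npv")
        )
    except KeyError as exc:
        raise ValueError(f"printed_percent missing metric {exc}") from None
    if n_total < 4:
        raise ValueError("n_total too small for a full 2x2 table")

    best: list[tuple[float, ConfusionTable]] = []
    for pos in range(1, n_total):          # gold positives = tp + fn
        neg = n_total - pos
        for tp in range(pos + 1):
            fn = pos - tp
            for tn in range(neg + 1):
                fp = neg - tn
                if tp + fp == 0 or tn + fn == 0:
                    continue
                t = ConfusionTable(tp, fn, fp, tn)
                dev = max(abs(a - b) for a, b in zip(_table_metrics_percent(t), target))
                if not best or dev < best[0][0] - 1e-12:
                    best = [(dev, t)]
                elif abs(dev - best[0][0]) <= 1e-12:
                    best.append((dev, t))

    if not best or best[0][0] > tolerance:
        raise ValueError(
            f"no integer table at n={n_total} reproduces {target} within "
            f"{tolerance} percentage points"
        )
    if len(best) > 1:
        raise ValueError(
            "printed percentages are consistent with multiple tables: "
            + ", ".join(str(t) for _, t in best)
        )
    return best[0][1]


def summary_frame(summaries: Mapping[int, DiagnosticSummary]) -> pd.DataFrame:
    """Validity table shaped like a published cutoff-by-metric report:
    one row per scale-difference cutoff, point estimates and CI bounds in
    percent."""
    rows = []
    for cutoff in sorted(summaries):
        row: dict[str, float | int | None] = {"cutoff_scales": cutoff, "cutoff_db": 5 * cutoff}
        for name, m in summaries[cutoff].as_dict().items():
            if m is None:
                row[name], row[f"{name}_lo"], row[f"{name}_hi"] = None, None, None
            else:
                row[name], row[f"{name}_lo"], row[f"{name}_hi"] = m.as_percent()
        rows.append(row)
    return pd.DataFrame(rows)
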