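"""Score-vs-sensitivity and score-vs-outcome association.

Pearson correlation with OLS line, mutation-stratified regression with an
intercept-offset comparison at the pooled mean, median/quantile
dichotomization, and two-group log-rank survival comparison with
Kaplan-Meier curves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .errors import AnalysisError
from .geneset_scoring import ScoreVector

logger = logging.getLogger(__name__)


@dataclass
class AssociationResult:
    x_name: str
    y_name: str
    n: int
    pearson_r: float
    r_p: float
    slope: float
    intercept: float
    stratum: Optional[str] = None

    def __post_init__(self) -> None:
        if self.n < 3:
            raise AnalysisError("association needs >= 3 paired values")
        if not -1.0 - 1e-12 <= self.pearson_r <= 1.0 + 1e-12:
            raise AnalysisError(f"pearson r {self.pearson_r} outside [-1, 1]")

    def predict(self, x: float) -> float:
        return self.intercept + self.slope * x


@dataclass
class SurvivalRecord:
    time: float
    event: int
    group: str

    def __post_init__(self) -> None:
        if self.time < 0:
            raise AnalysisError("negative survival time")
        if self.event not in (0, 1):
            raise AnalysisError("event indicator must be 0/1")


@dataclass
class SurvivalComparison:
    cutpoint_rule: str
    n_high: int
    n_low: int
    logrank_chi2: float
    logrank_p: float
    km_curves: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)


def _pairs(
    x, y, x_name: str = "x", y_name: str = "y"
) -> tuple[np.ndarray, np.ndarray, str, str, int]:
    """Align x and y into paired finite arrays; count dropped pairs.

    Accepts ScoreVector / pandas Series (aligned on sample ids) or plain
    equal-length arrays.
    """
    if isinstance(x, ScoreVector):
        x_name = x.score_name
        x = x.as_series()
    if isinstance(y, ScoreVector):
        y_name = y.score_name
        y = y.as_series()
    if isinstance(y, Mapping):
        y = pd.Series(y)
    if isinstance(x, pd.Series) and isinstance(y, pd.Series):
        common = [s for s in x.index if s in y.index]
        xv = x.loc[common].to_numpy(dtype=float)
        yv = y.loc[common].to_numpy(dtype=float)
    else:
        xv = np.asarray(x, dtype=float)
        yv = np.asarray(y, dtype=float)
        if xv.shape != yv.shape:
            raise AnalysisError("x and y lengths differ and cannot be aligned")
    mask = np.isfinite(xv) & np.isfinite(yv)
    dropped = int((~mask).sum())
    if dropped:
        logger.info("dropped %d pairs with missing values", dropped)
    return xv[mask], yv[mask], x_name, y_name, dropped


def correlate(x, y, x_name: str = "x", y_name: str = "y") -> AssociationResult:
    """Pearson correlation with two-sided t-transform p and an OLS line.

    Pairs with a missing value on either side are dropped (pairwise-complete
    deletion) and counted in the log.
    """
    xv, yv, x_name, y_name, _ = _pairs(x, y, x_name, y_name)
    if len(xv) < 3:
        raise AnalysisError("correlation needs >= 3 paired finite values")
    if np.std(xv) == 0 or np.std(yv) == 0:
        raise AnalysisError("degenerate correlation: zero variance in x or y")
    r, p = stats.pearsonr(xv, yv)
    fit = stats.linregress(xv, yv)
    return AssociationResult(
        x_name=x_name,
        y_name=y_name,
        n=len(xv),
        pearson_r=float(r),
        r_p=float(p),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
    )


def stratified_regression(
    x,
    y,
    strata: Mapping[str, str] | Sequence[str],
    min_n: int = 3,
    x_name: str = "x",
    y_name: str = "y",
) -> tuple[dict[str, AssociationResult], Optional[float]]:
    """Independent OLS per mutation stratum plus the vertical line offset.

    ``strata`` maps sample id (or position) to ``wild_type``/``mutant``/
    ``unknown``. Unknown-status samples are excluded and counted. The second
    return value is the mutant-minus-wild-type fitted difference evaluated at
    the pooled mean of x (None unless both strata were fit), which
    operationalizes a shift in sensitivity at comparable expression.
    """
    if isinstance(x, ScoreVector):
        x_name = x.score_name
        x = x.as_series()
    if isinstance(y, ScoreVector):
        y_name = y.score_name
        y = y.as_series()
    if isinstance(y, Mapping) and not isinstance(y, pd.Series):
        y = pd.Series(y)
    if isinstance(x, pd.Series):
        ids = list(x.index)
    else:
        x = pd.Series(np.asarray(x, dtype=float))
        ids = list(x.index)
    if not isinstance(y, pd.Series):
        y = pd.Series(np.asarray(y, dtype=float), index=ids)
    if not isinstance(strata, Mapping):
        strata = {i: s for i, s in zip(ids, strata)}

    unknown = [s for s in ids if strata.get(s, "unknown") == "unknown"]
    if unknown:
        logger.info("excluded %d samples with unknown mutation status", len(unknown))

    results: dict[str, AssociationResult] = {}
    pooled_x: list[float] = []
    for label in ("wild_type", "mutant"):
        members = [s for s in ids if strata.get(s, "unknown") == label and s in y.index]
        xv = x.loc[members].to_numpy(dtype=float)
        yv = y.loc[members].to_numpy(dtype=float)
        mask = np.isfinite(xv) & np.isfinite(yv)
        xv, yv = xv[mask], yv[mask]
        if len(xv) < min_n:
            logger.warning("stratum %s skipped: only %d usable pairs", label, len(xv))
            continue
        fit = stats.linregress(xv, yv)
        r, p = stats.pearsonr(xv, yv) if np.std(yv) > 0 else (0.0, 1.0)
        results[label] = AssociationResult(
            x_name=x_name,
            y_name=y_name,
            n=len(xv),
            pearson_r=float(r),
            r_p=float(p),
            slope=float(fit.slope),
            intercept=float(fit.intercept),
            stratum=label,
        )
        pooled_x.extend(xv.tolist())

    offset = None
    if "wild_type" in results and "mutant" in results:
        xbar = float(np.mean(pooled_x))
        offset = results["mutant"].predict(xbar) - results["wild_type"].predict(xbar)
    return results, offset


def dichotomize(
    scores, rule: str = "median", q: Optional[float] = None
) -> np.ndarray:
    """Split values into ``high`` (strictly above cutpoint) / ``low`` groups.

    Default cutpoint is the median; ``rule='quantile'`` with ``q`` uses that
    quantile. Ties at the cutpoint go to ``low`` and are logged.
    """
    if isinstance(scores, ScoreVector):
        values = np.asarray(scores.values, dtype=float)
    else:
        values = np.asarray(scores, dtype=float)
    if len(values) < 4:
        raise AnalysisError("dichotomization needs >= 4 samples")
    if np.all(values == values[0]):
        raise AnalysisError("all values identical; cannot dichotomize")
    if rule == "median":
        cut = float(np.median(values))
    elif rule == "quantile":
        if q is None or not 0 < q < 1:
            raise AnalysisError("quantile rule needs 0 < q < 1")
        cut = float(np.quantile(values, q))
    else:
        raise AnalysisError(f"unknown dichotomization rule {rule!r}")
    labels = np.where(values > cut, "high", "low")
    ties = int(np.sum(values == cut))
    if ties:
        logger.info("%d values tied at cutpoint %.6g assigned to 'low'", ties, cut)
    return labels


def logrank_test(records: Sequence[SurvivalRecord]) -> SurvivalComparison:
    """Two-group log-rank chi-square (1 df) with per-group Kaplan-Meier curves."""
    groups = sorted({r.group for r in records})
    if len(groups) != 2:
        raise AnalysisError(f"log-rank needs exactly 2 groups, got {groups}")
    if sum(r.event for r in records) < 1:
        raise AnalysisError("log-rank needs >= 1 event")
    by_group = {
        g: ([r.time for r in records if r.group == g],
            [r.event for r in records if r.group == g])
        for g in groups
    }
    (t1, e1), (t2, e2) = by_group[groups[0]], by_group[groups[1]]
    res = _ll_logrank(t1, t2, event_observed_A=e1, event_observed_B=e2)

    curves = {}
    kmf = KaplanMeierFitter()
    for g in groups:
        times, events = by_group[g]
        kmf.fit(times, events)
        sf = kmf.survival_function_
        curves[g] = (
            sf.index.to_numpy(dtype=float),
            sf.iloc[:, 0].to_numpy(dtype=float),
        )

    n_by_group = {g: len(by_group[g][0]) for g in groups}
    if set(groups) == {"high", "low"}:
        n_high, n_low = n_by_group["high"], n_by_group["low"]
    else:  # arbitrary labels: report in sorted order (first=low, second=high)
        n_low, n_high = n_by_group[groups[0]], n_by_group[groups[1]]
    return SurvivalComparison(
        cutpoint_rule="external",
        n_high=n_high,
        n_low=n_low,
        logrank_chi2=float(res.test_statistic),
        logrank_p=float(res.p_value),
        km_curves=curves,
    )


def survival_by_dichotomized_score(
    scores: ScoreVector,
    survival: Mapping[str, tuple[float, int]],
    rule: str = "median",
    q: Optional[float] = None,
) -> SurvivalComparison:
    """Dichotomize a score vector and log-rank-compare survival of the halves.

    ``survival`` maps sample id to (time, event). Samples without survival
    data are dropped before the split. The cutpoint choice is a known
    reproducibility gap versus external plotters and is logged prominently.
    """
    ids = [s for s in scores.sample_ids if s in survival]
    values = np.asarray(
        [scores.values[scores.sample_ids.index(s)] for s in ids], dtype=float
    )
    if len(ids) < 4:
        raise AnalysisError("too few samples with survival data")
    labels = dichotomize(values, rule=rule, q=q)
    logger.warning(
        "survival split uses %s cutpoint; external tools may optimize the "
        "cutoff and yield different p-values", rule,
    )
    records = [
        SurvivalRecord(time=survival[s][0], event=survival[s][1], group=lab)
        for s, lab in zip(ids, labels)
    ]
    out = logrank_test(records)
    out.cutpoint_rule = rule if rule != "quantile" else f"quantile {q}"
    return out
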