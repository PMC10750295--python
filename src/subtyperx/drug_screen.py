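"""Subtype-stratified drug-specificity screen.

Per drug: one-way ANOVA across subtypes on IC50 z-scores, Tukey HSD post-hoc
for all subtype pairs, and a symmetric specificity rule — a drug is
``<S>_specific`` when subtype S has the strictly lowest mean z-score and its
Tukey-adjusted p-value against *every* other subtype is below alpha.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError, ConfigError
from .io_formats import DrugResponseMatrix, SampleAnnotation

logger = logging.getLogger(__name__)

LABEL_NONE = "none"
LABEL_INSUFFICIENT = "insufficient_data"


@dataclass
class PairwiseComparison:
    """One Tukey HSD record; pair stored in canonical (alphabetical) order."""

    subtype_a: str
    subtype_b: str
    mean_diff: float  # mean_a - mean_b, z units
    p_adj: float

    def __post_init__(self) -> None:
        if self.subtype_a > self.subtype_b:
            self.subtype_a, self.subtype_b = self.subtype_b, self.subtype_a
            self.mean_diff = -self.mean_diff
        if not 0.0 <= self.p_adj <= 1.0:
            raise AnalysisError(f"adjusted p {self.p_adj} outside [0, 1]")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.subtype_a, self.subtype_b)


@dataclass
class ScreenResult:
    drug_id: str
    group_ns: dict[str, int]
    anova_p: float
    pairwise: list[PairwiseComparison] = field(default_factory=list)
    label: str = LABEL_NONE


def _clean_groups(groups: Sequence[Sequence[float]]) -> list[np.ndarray]:
    cleaned = [np.asarray(g, dtype=float) for g in groups]
    cleaned = [g[np.isfinite(g)] for g in cleaned]
    if len(cleaned) < 2:
        raise AnalysisError("need >= 2 groups")
    if any(len(g) < 2 for g in cleaned):
        raise AnalysisError("every group needs >= 2 finite values")
    if all(np.var(g) == 0 for g in cleaned):
        raise AnalysisError("degenerate ANOVA: all within-group variances are zero")
    return cleaned


def one_way_anova(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Classical fixed-effects one-way ANOVA.

    Returns the F statistic and the upper-tail p from F(k-1, N-k).
    """
    cleaned = _clean_groups(groups)
    f, p = stats.f_oneway(*cleaned)
    return float(f), float(p)


def tukey_hsd(
    groups: Sequence[Sequence[float]], names: Optional[Sequence[str]] = None
) -> list[PairwiseComparison]:
    """Tukey HSD over all unordered group pairs (Tukey-Kramer when unbalanced).

    Adjusted p-values come from the studentized-range distribution with the
    pooled within-group variance.
    """
    cleaned = _clean_groups(groups)
    if names is None:
        names = [f"group{i}" for i in range(len(cleaned))]
    if len(names) != len(cleaned):
        raise AnalysisError("names and groups length mismatch")
    res = stats.tukey_hsd(*cleaned)
    means = [float(np.mean(g)) for g in cleaned]
    out = []
    for i in range(len(cleaned)):
        for j in range(i + 1, len(cleaned)):
            out.append(
                PairwiseComparison(
                    subtype_a=str(names[i]),
                    subtype_b=str(names[j]),
                    mean_diff=means[i] - means[j],
                    p_adj=float(min(1.0, res.pvalue[i, j])),
                )
            )
    return out


def classify_specificity(
    pairwise: Sequence[PairwiseComparison],
    group_means: Mapping[str, float],
    alpha: float = 0.05,
) -> str:
    """Apply the subtype-specificity rule symmetrically to every subtype.

    ``S_specific`` iff mean(S) is strictly lowest and every Tukey-adjusted p
    for (S, T) is below alpha. Ties at the minimum mean yield ``none``;
    a missing pair yields ``insufficient_data``.
    """
    subtypes = sorted(group_means)
    if len(subtypes) < 2:
        raise AnalysisError("specificity rule needs >= 2 subtypes")
    p_lookup = {pc.pair: pc.p_adj for pc in pairwise}
    for s in subtypes:
        for t in subtypes:
            if s < t and (s, t) not in p_lookup:
                return LABEL_INSUFFICIENT
    for s in subtypes:
        others = [t for t in subtypes if t != s]
        if not all(group_means[s] < group_means[t] for t in others):
            continue
        if all(p_lookup[tuple(sorted((s, t)))] < alpha for t in others):
            return f"{s}_specific"
        return LABEL_NONE  # unique minimum but not significant vs all others
    return LABEL_NONE


def standardize(resp: DrugResponseMatrix) -> DrugResponseMatrix:
    """Re-standardize each drug column to mean 0 / sample sd 1 (n-1), NaN-aware."""
    z = resp.z_ic50.copy()
    for j in range(z.shape[1]):
        col = z[:, j]
        mask = np.isfinite(col)
        if mask.sum() < 2:
            continue
        sd = np.std(col[mask], ddof=1)
        if sd == 0:
            raise AnalysisError(f"drug {resp.drug_ids[j]!r} has zero variance")
        z[mask, j] = (col[mask] - np.mean(col[mask])) / sd
    return DrugResponseMatrix(list(resp.line_ids), list(resp.drug_ids), z)


def run_screen(
    resp: DrugResponseMatrix,
    annotations: Sequence[SampleAnnotation],
    alpha: float = 0.05,
    min_n: int = 3,
    adjust_across_drugs: bool = False,
) -> list[ScreenResult]:
    """Screen every drug for subtype specificity.

    Drugs pass to Tukey + classification only when the ANOVA p clears
    ``alpha`` (raw by default; Benjamini-Hochberg across drugs when
    ``adjust_across_drugs``). Drugs with any subtype below ``min_n``
    non-missing lines are labelled ``insufficient_data`` and logged, never
    dropped. Results are sorted by ANOVA p (missing last).
    """
    subtype_of = {a.sample_id: a.subtype for a in annotations}
    missing = [l for l in resp.line_ids if l not in subtype_of]
    if missing:
        raise ConfigError(f"lines without subtype annotation: {missing[:5]}")
    subtypes = sorted({subtype_of[l] for l in resp.line_ids})
    if len(subtypes) < 2:
        raise ConfigError("screen needs >= 2 subtypes in the panel")

    line_groups: dict[str, list[int]] = {s: [] for s in subtypes}
    for i, line in enumerate(resp.line_ids):
        line_groups[subtype_of[line]].append(i)

    results: list[ScreenResult] = []
    for j, drug in enumerate(resp.drug_ids):
        col = resp.z_ic50[:, j]
        groups, names = [], []
        group_ns = {}
        for s in subtypes:
            vals = col[line_groups[s]]
            vals = vals[np.isfinite(vals)]
            group_ns[s] = int(len(vals))
            groups.append(vals)
            names.append(s)
        if any(n < min_n for n in group_ns.values()):
            logger.warning(
                "drug %s: insufficient data (group sizes %s, min_n=%d)",
                drug, group_ns, min_n,
            )
            results.append(
                ScreenResult(drug, group_ns, anova_p=float("nan"), label=LABEL_INSUFFICIENT)
            )
            continue
        _, p = one_way_anova(groups)
        results.append(ScreenResult(drug, group_ns, anova_p=p))

    gate_ps = {r.drug_id: r.anova_p for r in results}
    if adjust_across_drugs:
        tested = [r for r in results if np.isfinite(r.anova_p)]
        adj = _benjamini_hochberg([r.anova_p for r in tested])
        gate_ps.update({r.drug_id: q for r, q in zip(tested, adj)})

    for r in results:
        if r.label == LABEL_INSUFFICIENT or not gate_ps[r.drug_id] < alpha:
            continue
        j = resp.drug_ids.index(r.drug_id)
        col = resp.z_ic50[:, j]
        groups = []
        means = {}
        for s in subtypes:
            vals = col[line_groups[s]]
            vals = vals[np.isfinite(vals)]
            groups.append(vals)
            means[s] = float(np.mean(vals))
        r.pairwise = tukey_hsd(groups, subtypes)
        r.label = classify_specificity(r.pairwise, means, alpha=alpha)

    results.sort(key=lambda r: (not np.isfinite(r.anova_p), r.anova_p))
    return results


def _benjamini_hochberg(pvals: Sequence[float]) -> np.ndarray:
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def screen_table(results: Sequence[ScreenResult]) -> pd.DataFrame:
    """Flat per-drug summary table of a screen."""
    rows = []
    for r in results:
        row: dict[str, object] = {
            "drug_id": r.drug_id,
            "anova_p": r.anova_p,
            "label": r.label,
        }
        for s, n in r.group_ns.items():
            row[f"n_{s}"] = n
        for pc in r.pairwise:
            row[f"p_{pc.subtype_a}-{pc.subtype_b}"] = pc.p_adj
        rows.append(row)
    return pd.DataFrame(rows)


def pairwise_p_matrix(results: Sequence[ScreenResult]) -> pd.DataFrame:
    """Drug x subtype-pair matrix of Tukey p-values for heat-map rendering."""
    pairs = sorted({pc.pair for r in results for pc in r.pairwise})
    data = {}
    for r in results:
        lookup = {pc.pair: pc.p_adj for pc in r.pairwise}
        data[r.drug_id] = [lookup.get(pair, np.nan) for pair in pairs]
    return pd.DataFrame.from_dict(
        data, orient="index", columns=[f"{a}-{b}" for a, b in pairs]
    )
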