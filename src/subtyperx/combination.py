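"""Chou-Talalay median-effect fitting and combination-index synergy analysis.

The median-effect equation fa/fu = (D/Dm)^m is fit by least squares on its
log-odds linearization; the combination index at an observed combination
effect is CI = D1/Dx1 + D2/Dx2 with Dx the single-agent dose producing that
effect (mutually exclusive, classic two-term form; a third cross-term is
available behind ``exclusive=False``).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError, FormatError

logger = logging.getLogger(__name__)

FA_EPS = 0.01  # boundary clamp for fraction affected before linearization


@dataclass
class DoseResponseGrid:
    """Dose x fraction-affected observations for one or two agents.

    ``table`` columns: one dose column per agent (named after the agent) and
    ``fa``. Rows with a single nonzero dose are single-agent margins; rows
    with all doses zero are controls; rows with every dose nonzero are
    combination cells. Replicate rows at the same dose point are allowed.
    """

    agents: tuple[str, ...]
    table: pd.DataFrame

    def __post_init__(self) -> None:
        if not 1 <= len(self.agents) <= 2:
            raise FormatError("grid supports 1 or 2 agents")
        for a in self.agents:
            if a not in self.table.columns:
                raise FormatError(f"missing dose column {a!r}")
            if (self.table[a] < 0).any():
                raise FormatError("doses must be non-negative")
        if "fa" not in self.table.columns:
            raise FormatError("missing 'fa' column")
        fa = self.table["fa"].to_numpy(dtype=float)
        if ((fa <= 0) | (fa >= 1)).any():
            raise FormatError("fa must lie strictly inside (0, 1); clamp first")

    def single_agent(self, agent: str) -> tuple[np.ndarray, np.ndarray]:
        """Margin rows where only ``agent`` has a nonzero dose."""
        others = [a for a in self.agents if a != agent]
        mask = self.table[agent] > 0
        for o in others:
            mask &= self.table[o] == 0
        sub = self.table[mask]
        return sub[agent].to_numpy(dtype=float), sub["fa"].to_numpy(dtype=float)

    def combination_cells(self) -> pd.DataFrame:
        mask = np.ones(len(self.table), dtype=bool)
        for a in self.agents:
            mask &= (self.table[a] > 0).to_numpy()
        return self.table[mask]


@dataclass
class MedianEffectParams:
    m: float
    Dm: float
    r: float
    n_points: int
    flagged: bool = False

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise AnalysisError("median-effect fit needs >= 2 points")
        if not self.flagged and (self.m <= 0 or self.Dm <= 0):
            raise AnalysisError("m and Dm must be positive for an unflagged fit")


@dataclass
class CIResult:
    effect_level: float
    D1: float
    D2: float
    Dx1: float
    Dx2: float
    CI: float
    call: Literal["synergy", "additive", "antagonism"]


def fa_from_viability(percent_of_control: float, eps: float = FA_EPS) -> float:
    """fa = 1 - percent/100, clamped into (eps, 1-eps); clamps are logged."""
    if percent_of_control < 0:
        raise AnalysisError(f"negative percent-of-control {percent_of_control}")
    fa = 1.0 - percent_of_control / 100.0
    if fa <= eps:
        logger.info("fa %.4f clamped up to %.4f", fa, eps)
        return eps
    if fa >= 1 - eps:
        logger.info("fa %.4f clamped down to %.4f", fa, 1 - eps)
        return 1 - eps
    return fa


def fit_median_effect(
    doses: Sequence[float], fa: Sequence[float]
) -> MedianEffectParams:
    """Fit (m, Dm) by least squares on log(fa/(1-fa)) = m log D - m log Dm.

    Replicate fa values at identical doses are averaged on the fa scale
    before linearization. A non-positive slope is flagged, not fatal.
    """
    doses = np.asarray(doses, dtype=float)
    fa = np.asarray(fa, dtype=float)
    if doses.shape != fa.shape:
        raise AnalysisError("doses and fa length mismatch")
    if (doses <= 0).any():
        raise AnalysisError("doses must be strictly positive")
    if ((fa <= 0) | (fa >= 1)).any():
        raise AnalysisError("fa must be interior; apply fa_from_viability first")
    df = pd.DataFrame({"d": doses, "fa": fa}).groupby("d", sort=True)["fa"].mean()
    if len(df) < 2:
        raise AnalysisError("need >= 2 distinct doses with interior fa")
    log_d = np.log(df.index.to_numpy(dtype=float))
    log_odds = np.log(df.to_numpy() / (1.0 - df.to_numpy()))
    fit = stats.linregress(log_d, log_odds)
    m = float(fit.slope)
    flagged = m <= 0
    if flagged:
        logger.warning("median-effect slope m=%.4f <= 0; fit flagged", m)
        dm = math.nan
    else:
        dm = float(math.exp(-fit.intercept / m))
    return MedianEffectParams(
        m=m, Dm=dm, r=float(fit.rvalue), n_points=int(len(df)), flagged=flagged
    )


def fa_at_dose(params: MedianEffectParams, dose: float) -> float:
    """Effect predicted by the fitted median-effect curve at ``dose``."""
    if dose <= 0:
        raise AnalysisError("dose must be positive")
    if params.flagged:
        raise AnalysisError("cannot evaluate a flagged fit")
    return 1.0 / (1.0 + (params.Dm / dose) ** params.m)


def dose_for_effect(params: MedianEffectParams, fa: float) -> float:
    """Dx = Dm (fa/(1-fa))^(1/m), the single-agent dose giving effect fa."""
    if not 0 < fa < 1:
        raise AnalysisError("fa must be strictly inside (0, 1)")
    if params.flagged:
        raise AnalysisError("cannot invert a flagged fit")
    return params.Dm * (fa / (1.0 - fa)) ** (1.0 / params.m)


def combination_index(
    fit1: MedianEffectParams,
    fit2: MedianEffectParams,
    D1: float,
    D2: float,
    fa_combo: float,
    delta: float = 0.1,
    exclusive: bool = True,
) -> CIResult:
    """CI at the observed combination effect; synergy call with +-delta band.

    The classic mutually-exclusive form CI = D1/Dx1 + D2/Dx2 is the default;
    ``exclusive=False`` adds the cross term (D1 D2)/(Dx1 Dx2).
    """
    if D1 < 0 or D2 < 0 or D1 + D2 == 0:
        raise AnalysisError("need non-negative doses with at least one positive")
    if fit1.flagged or fit2.flagged:
        logger.warning("CI computed from a flagged single-agent fit")
    dx1 = dose_for_effect(fit1, fa_combo)
    dx2 = dose_for_effect(fit2, fa_combo)
    ci = D1 / dx1 + D2 / dx2
    if not exclusive:
        ci += (D1 * D2) / (dx1 * dx2)
    if ci < 1 - delta:
        call = "synergy"
    elif ci > 1 + delta:
        call = "antagonism"
    else:
        call = "additive"
    return CIResult(
        effect_level=fa_combo, D1=D1, D2=D2, Dx1=dx1, Dx2=dx2, CI=float(ci), call=call
    )


def ci_surface(
    grid: DoseResponseGrid, delta: float = 0.1, exclusive: bool = True
) -> list[CIResult]:
    """One CIResult per combination cell, using each cell's observed fa.

    Single-agent fits come from the grid's own margins; replicate combination
    rows are averaged on the fa scale per dose pair.
    """
    if len(grid.agents) != 2:
        raise AnalysisError("CI surface needs a two-agent grid")
    a1, a2 = grid.agents
    fits = {}
    for agent in grid.agents:
        doses, fa = grid.single_agent(agent)
        if len(doses) == 0:
            raise AnalysisError(f"missing single-agent margin for {agent!r}")
        fits[agent] = fit_median_effect(doses, fa)
    cells = grid.combination_cells()
    if cells.empty:
        raise AnalysisError("no combination cells in grid")
    out = []
    grouped = cells.groupby([a1, a2], sort=True)["fa"].mean().reset_index()
    for _, row in grouped.iterrows():
        out.append(
            combination_index(
                fits[a1], fits[a2],
                D1=float(row[a1]), D2=float(row[a2]),
                fa_combo=float(row["fa"]),
                delta=delta, exclusive=exclusive,
            )
        )
    return out


def grid_from_viability(
    df: pd.DataFrame,
    agents: Optional[Sequence[str]] = None,
    eps: float = FA_EPS,
) -> DoseResponseGrid:
    """Build a grid from a table with dose columns + ``percent_of_control``.

    Control rows (all doses zero) are dropped after logging; viability is
    converted to fa with boundary clamping.
    """
    if "percent_of_control" not in df.columns:
        raise FormatError("expected a 'percent_of_control' column")
    if agents is None:
        agents = [c for c in df.columns if c != "percent_of_control"]
    if not 1 <= len(agents) <= 2:
        raise FormatError("expected 1 or 2 dose columns")
    dose_any = np.zeros(len(df), dtype=bool)
    for a in agents:
        dose_any |= (df[a].to_numpy(dtype=float) > 0)
    n_ctrl = int((~dose_any).sum())
    if n_ctrl:
        logger.info("dropped %d control rows (all doses zero)", n_ctrl)
    kept = df[dose_any].copy()
    kept["fa"] = [
        fa_from_viability(float(v), eps=eps) for v in kept["percent_of_control"]
    ]
    return DoseResponseGrid(
        agents=tuple(agents), table=kept[[*agents, "fa"]].reset_index(drop=True)
    )


def ci_table(results: Sequence[CIResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "fa": [r.effect_level for r in results],
            "D1": [r.D1 for r in results],
            "D2": [r.D2 for r in results],
            "Dx1": [r.Dx1 for r in results],
            "Dx2": [r.Dx2 for r in results],
            "CI": [r.CI for r in results],
            "call": [r.call for r in results],
        }
    )
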