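"""Generators for every input shape the pipeline consumes, with planted
ground truth.

Every generator is a pure function of (config, seed): identical inputs give
bit-identical outputs, and each emits a machine-readable truth table
sufficient to score recovery without re-deriving the plant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .combination import DoseResponseGrid, MedianEffectParams, dose_for_effect
from .errors import ConfigError
from .io_formats import (
    DrugResponseMatrix,
    ExpressionMatrix,
    GeneSet,
    SampleAnnotation,
    normalize_gene,
)
from .sensitivity_assoc import SurvivalRecord

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Drug-response screen simulation
# ---------------------------------------------------------------------------


@dataclass
class PlantedDrugEffect:
    drug_id: str
    subtype: str
    shift: float  # z units; negative = more sensitive


@dataclass
class ScreenSimConfig:
    n_lines_per_subtype: dict[str, int]
    n_drugs: int
    planted: list[PlantedDrugEffect] = field(default_factory=list)
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_lines_per_subtype) < 2:
            raise ConfigError("need >= 2 subtypes")
        if any(n <= 0 for n in self.n_lines_per_subtype.values()):
            raise ConfigError("lines per subtype must be positive")
        if self.n_drugs < len({p.drug_id for p in self.planted}):
            raise ConfigError("n_drugs smaller than number of planted drugs")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")
        for p in self.planted:
            if p.subtype not in self.n_lines_per_subtype:
                raise ConfigError(f"planted effect references unknown subtype {p.subtype!r}")


def _drug_name(i: int, width: int) -> str:
    return f"drug_{i:0{width}d}"


def simulate_drug_response(
    cfg: ScreenSimConfig,
) -> tuple[DrugResponseMatrix, list[SampleAnnotation], pd.DataFrame]:
    """Normal(0, noise_sd) z-scores with planted per-(subtype, drug) shifts.

    Planted drug ids may name any of the generated drugs (``drug_0000``...)
    or introduce custom ids, which replace the tail of the generated list.
    """
    rng = np.random.default_rng(cfg.seed)
    subtypes = list(cfg.n_lines_per_subtype)
    lines, ann = [], []
    for s in subtypes:
        for i in range(cfg.n_lines_per_subtype[s]):
            sid = f"{s}_{i:03d}"
            lines.append(sid)
            ann.append(SampleAnnotation(sample_id=sid, subtype=s))
    width = max(4, len(str(cfg.n_drugs - 1)))
    drugs = [_drug_name(i, width) for i in range(cfg.n_drugs)]
    custom = [p.drug_id for p in cfg.planted if p.drug_id not in drugs]
    for k, name in enumerate(dict.fromkeys(custom)):
        drugs[cfg.n_drugs - 1 - k] = name

    z = rng.normal(0.0, cfg.noise_sd, size=(len(lines), len(drugs)))
    line_idx = {l: i for i, l in enumerate(lines)}
    for p in cfg.planted:
        j = drugs.index(p.drug_id)
        rows = [line_idx[l] for l, a in zip(lines, ann) if a.subtype == p.subtype]
        z[rows, j] += p.shift
    truth = pd.DataFrame(
        [(p.drug_id, p.subtype, p.shift) for p in cfg.planted],
        columns=["drug_id", "subtype", "shift"],
    )
    return DrugResponseMatrix(lines, drugs, z), ann, truth


# ---------------------------------------------------------------------------
# Expression simulation
# ---------------------------------------------------------------------------


@dataclass
class ExprSimConfig:
    n_genes: int
    n_samples_per_subtype: dict[str, int]
    gene_sets: list[GeneSet] = field(default_factory=list)
    set_activity: dict[tuple[str, str], float] = field(default_factory=dict)
    baseline_logmean: float = 2.0
    baseline_logsd: float = 0.5
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ConfigError("n_genes must be positive")
        if not self.n_samples_per_subtype:
            raise ConfigError("need >= 1 subtype")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")
        set_names = {gs.name for gs in self.gene_sets}
        for (set_name, subtype) in self.set_activity:
            if set_name not in set_names:
                raise ConfigError(f"set_activity references unknown set {set_name!r}")
            if subtype not in self.n_samples_per_subtype:
                raise ConfigError(f"set_activity references unknown subtype {subtype!r}")


def _simulated_gene_ids(cfg: ExprSimConfig) -> list[str]:
    named = []
    seen: set[str] = set()
    for gs in cfg.gene_sets:
        for g in gs.genes:
            key = normalize_gene(g)
            if key not in seen:
                seen.add(key)
                named.append(g)
    if len(named) > cfg.n_genes:
        raise ConfigError("gene-set genes exceed n_genes; sets must fit the matrix")
    fillers = []
    i = 0
    while len(named) + len(fillers) < cfg.n_genes:
        g = f"gene_{i:05d}"
        if normalize_gene(g) not in seen:
            fillers.append(g)
        i += 1
    return named + fillers


def simulate_expression(
    cfg: ExprSimConfig,
) -> tuple[ExpressionMatrix, list[SampleAnnotation], pd.DataFrame]:
    """Log-normal baseline per gene; set genes get subtype shifts on log scale.

    A gene belonging to two sets with different shifts for the same subtype
    is a contradictory plant and raises ConfigError.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = _simulated_gene_ids(cfg)
    gene_idx = {normalize_gene(g): i for i, g in enumerate(genes)}

    subtypes = list(cfg.n_samples_per_subtype)
    samples, ann = [], []
    for s in subtypes:
        for i in range(cfg.n_samples_per_subtype[s]):
            sid = f"{s}_{i:03d}"
            samples.append(sid)
            ann.append(SampleAnnotation(sample_id=sid, subtype=s))

    # per-(gene, subtype) log-scale shift, contradiction-checked
    shift: dict[tuple[int, str], float] = {}
    sets_by_name = {gs.name: gs for gs in cfg.gene_sets}
    for (set_name, subtype), delta in cfg.set_activity.items():
        for g in sets_by_name[set_name].genes:
            key = (gene_idx[normalize_gene(g)], subtype)
            if key in shift and shift[key] != delta:
                raise ConfigError(
                    f"gene {g!r} receives contradictory shifts for subtype {subtype!r}"
                )
            shift[key] = delta

    base = rng.normal(cfg.baseline_logmean, cfg.baseline_logsd, size=len(genes))
    log_vals = base[:, None] + rng.normal(0.0, cfg.noise_sd, size=(len(genes), len(samples)))
    for (gi, subtype), delta in shift.items():
        cols = [j for j, a in enumerate(ann) if a.subtype == subtype]
        log_vals[gi, cols] += delta
    values = np.exp(log_vals)

    truth = pd.DataFrame(
        [
            (set_name, subtype, delta, len(sets_by_name[set_name]))
            for (set_name, subtype), delta in sorted(cfg.set_activity.items())
        ],
        columns=["set_name", "subtype", "shift", "n_genes"],
    )
    mat = ExpressionMatrix(genes, samples, values, value_kind="normalized")
    return mat, ann, truth


# ---------------------------------------------------------------------------
# Dose-response simulation
# ---------------------------------------------------------------------------

InteractionMode = Literal["sham", "loewe_additive", "synergy_factor"]


def _median_effect_fa(m: float, dm: float, dose: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + (dm / dose) ** m)


def _loewe_fa(params1: MedianEffectParams, params2: MedianEffectParams,
              d1: float, d2: float, factor: float = 1.0) -> float:
    """Effect fa solving factor*(d1/Dx1(fa) + d2/Dx2(fa)) = 1 (Loewe)."""

    def g(fa: float) -> float:
        return factor * (
            d1 / dose_for_effect(params1, fa) + d2 / dose_for_effect(params2, fa)
        ) - 1.0

    lo, hi = 1e-9, 1.0 - 1e-9
    # g is increasing in fa (Dx grows with fa => terms shrink... inverted):
    # d/Dx(fa) decreases as fa increases, so g decreases; bracket and solve.
    if g(lo) < 0:
        return lo
    if g(hi) > 0:
        return hi
    return float(brentq(g, lo, hi, xtol=1e-12))


def simulate_dose_response(
    params: Mapping[str, tuple[float, float] | MedianEffectParams],
    doses: Mapping[str, Sequence[float]],
    interaction: InteractionMode = "loewe_additive",
    synergy_factor: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    eps: float = 1e-6,
) -> DoseResponseGrid:
    """Single-agent margins from the median-effect equation plus a full
    checkerboard of combination cells constructed per interaction mode.

    * ``sham``: the two "agents" are the same drug; the combination effect is
      the single-agent effect at the summed dose (downstream CI = 1).
    * ``loewe_additive``: combination effect satisfies Loewe additivity.
    * ``synergy_factor``: the dose needed for a given effect is scaled by
      1/synergy_factor, i.e. Loewe evaluated at inflated doses (downstream
      CI = 1/synergy_factor).

    Gaussian noise on the fa scale is clipped back into (eps, 1-eps); clips
    are logged.
    """
    agents = list(params)
    if len(agents) not in (1, 2) or set(doses) != set(agents):
        raise ConfigError("params and doses must name the same 1 or 2 agents")
    fits: dict[str, MedianEffectParams] = {}
    for a, p in params.items():
        if not isinstance(p, MedianEffectParams):
            m, dm = float(p[0]), float(p[1])
            if m <= 0 or dm <= 0:
                raise ConfigError(f"agent {a!r}: m and Dm must be positive")
            p = MedianEffectParams(m=m, Dm=dm, r=1.0, n_points=2)
        if p.m <= 0 or p.Dm <= 0:
            raise ConfigError(f"agent {a!r}: m and Dm must be positive")
        fits[a] = p
    for a in agents:
        arr = np.asarray(list(doses[a]), dtype=float)
        if (arr <= 0).any() or arr.size == 0:
            raise ConfigError(f"agent {a!r}: doses must be strictly positive")
    if interaction == "synergy_factor" and synergy_factor <= 0:
        raise ConfigError("synergy_factor must be positive")

    rng = np.random.default_rng(seed)
    rows: list[dict[str, float]] = []

    def emit(point: dict[str, float], fa: float) -> None:
        if noise_sd > 0:
            fa = fa + float(rng.normal(0.0, noise_sd))
        clipped = min(max(fa, eps), 1.0 - eps)
        if clipped != fa:
            logger.info("fa %.4g clipped into (%g, %g)", fa, eps, 1 - eps)
        rows.append({**point, "fa": clipped})

    for a in agents:
        others = {b: 0.0 for b in agents if b != a}
        for d in doses[a]:
            fa = float(_median_effect_fa(fits[a].m, fits[a].Dm, float(d)))
            emit({a: float(d), **others}, fa)

    if len(agents) == 2:
        a1, a2 = agents
        for d1 in doses[a1]:
            for d2 in doses[a2]:
                d1f, d2f = float(d1), float(d2)
                if interaction == "sham":
                    fa = float(_median_effect_fa(fits[a1].m, fits[a1].Dm, d1f + d2f))
                elif interaction == "loewe_additive":
                    fa = _loewe_fa(fits[a1], fits[a2], d1f, d2f)
                elif interaction == "synergy_factor":
                    fa = _loewe_fa(fits[a1], fits[a2], d1f, d2f, factor=synergy_factor)
                else:
                    raise ConfigError(f"unknown interaction mode {interaction!r}")
                emit({a1: d1f, a2: d2f}, fa)

    table = pd.DataFrame(rows)
    for a in agents:
        table[a] = table[a].astype(float)
    return DoseResponseGrid(agents=tuple(agents), table=table)


# ---------------------------------------------------------------------------
# Survival simulation
# ---------------------------------------------------------------------------


def simulate_survival(
    n_per_group: int,
    hazard_ratio: float,
    censor_rate: float = 0.0,
    seed: int = 0,
    baseline_hazard: float = 0.05,
    group_labels: tuple[str, str] = ("low", "high"),
) -> list[SurvivalRecord]:
    """Exponential event times; group 2 hazard = HR x group 1 hazard.

    Each subject is independently censored with probability ``censor_rate``,
    at a uniform time before its event.
    """
    if hazard_ratio <= 0:
        raise ConfigError("hazard_ratio must be positive")
    if not 0 <= censor_rate < 1:
        raise ConfigError("censor_rate must lie in [0, 1)")
    if n_per_group <= 0:
        raise ConfigError("n_per_group must be positive")
    rng = np.random.default_rng(seed)
    records = []
    for label, hazard in zip(group_labels, (baseline_hazard, baseline_hazard * hazard_ratio)):
        times = rng.exponential(1.0 / hazard, size=n_per_group)
        censored = rng.random(n_per_group) < censor_rate
        for t, c in zip(times, censored):
            if c:
                records.append(
                    SurvivalRecord(time=float(t * rng.random()), event=0, group=label)
                )
            else:
                records.append(SurvivalRecord(time=float(t), event=1, group=label))
    return records


def survival_truth(hazard_ratio: float, censor_rate: float, n_per_group: int) -> pd.DataFrame:
    return pd.DataFrame(
        [(hazard_ratio, censor_rate, n_per_group)],
        columns=["hazard_ratio", "censor_rate", "n_per_group"],
    )
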