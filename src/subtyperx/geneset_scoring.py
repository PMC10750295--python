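"""Formula-defined gene-set activity scores on expression matrices.

Two score kinds:

* ``z_sum`` — per-sample sum of per-gene z-scores (gene standardized across
  samples with the sample sd, n-1 denominator) over the set genes present in
  the matrix.
* ``raw_sum`` — per-sample sum of raw expression values over the set genes.

The claudin score is the fixed raw-sum over CLDN3 + CLDN4 + CLDN7 + CDH1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .drug_screen import PairwiseComparison, one_way_anova, tukey_hsd
from .errors import AnalysisError
from .io_formats import ExpressionMatrix, GeneSet, SampleAnnotation, normalize_gene

logger = logging.getLogger(__name__)

CLAUDIN_GENES = ("CLDN3", "CLDN4", "CLDN7", "CDH1")


@dataclass
class ScoreVector:
    score_name: str
    sample_ids: list[str]
    values: np.ndarray
    value_kind: Literal["z_sum", "raw_sum"]
    genes_used: list[str]
    genes_missing: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.sample_ids):
            raise AnalysisError("score length does not match sample_ids")
        used = {normalize_gene(g) for g in self.genes_used}
        miss = {normalize_gene(g) for g in self.genes_missing}
        if used & miss:
            raise AnalysisError("genes_used and genes_missing overlap")

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.sample_ids, name=self.score_name)


def zscore_by_gene(mat: ExpressionMatrix, ddof: int = 1) -> ExpressionMatrix:
    """Standardize each gene row across samples: (x - mean) / sd.

    Zero-variance rows map to all-zero and are logged. Requires >= 2 samples.
    """
    if len(mat.sample_ids) < 2:
        raise AnalysisError("z-standardization needs >= 2 samples")
    values = np.asarray(mat.values, dtype=float)
    means = values.mean(axis=1, keepdims=True)
    sds = values.std(axis=1, ddof=ddof, keepdims=True)
    flat = (sds == 0).ravel()
    if flat.any():
        logger.info(
            "%d zero-variance gene rows mapped to all-zero z-scores", int(flat.sum())
        )
    safe_sds = np.where(sds == 0, 1.0, sds)
    z = (values - means) / safe_sds
    z[flat, :] = 0.0
    return ExpressionMatrix(
        gene_ids=list(mat.gene_ids),
        sample_ids=list(mat.sample_ids),
        values=z,
        value_kind="zscore",
    )


def _match_genes(mat: ExpressionMatrix, genes: Sequence[str]) -> tuple[list[int], list[str], list[str]]:
    index = {normalize_gene(g): i for i, g in enumerate(mat.gene_ids)}
    rows, used, missing = [], [], []
    for g in genes:
        i = index.get(normalize_gene(g))
        if i is None:
            missing.append(g)
        else:
            rows.append(i)
            used.append(g)
    return rows, used, missing


def geneset_score(
    mat: ExpressionMatrix,
    gene_set: GeneSet,
    kind: Literal["z_sum", "raw_sum"] = "z_sum",
    log2_transform: bool = False,
    ddof: int = 1,
) -> ScoreVector:
    """Per-sample gene-set score over the set genes present in the matrix.

    Missing set genes are reported in ``genes_missing`` and never imputed.
    ``log2_transform`` applies log2(x+1) before scoring (off by default).
    """
    rows, used, missing = _match_genes(mat, gene_set.genes)
    if not rows:
        raise AnalysisError(
            f"no gene of set {gene_set.name!r} is present in the matrix"
        )
    if missing:
        logger.info("set %s: %d/%d genes absent", gene_set.name, len(missing), len(gene_set))
    work = mat
    if log2_transform:
        work = ExpressionMatrix(
            list(mat.gene_ids), list(mat.sample_ids),
            np.log2(np.asarray(mat.values, dtype=float) + 1.0),
            value_kind="normalized",
        )
    if kind == "z_sum":
        z = zscore_by_gene(work, ddof=ddof)
        values = z.values[rows].sum(axis=0)
    elif kind == "raw_sum":
        values = np.asarray(work.values, dtype=float)[rows].sum(axis=0)
    else:
        raise AnalysisError(f"unknown score kind {kind!r}")
    return ScoreVector(
        score_name=gene_set.name,
        sample_ids=list(mat.sample_ids),
        values=values,
        value_kind=kind,
        genes_used=used,
        genes_missing=missing,
    )


def cldn_score(mat: ExpressionMatrix, **kwargs) -> ScoreVector:
    """Raw-sum score over the fixed claudin quartet (CLDN3/4/7 + CDH1)."""
    return geneset_score(
        mat, GeneSet(name="CLDN", genes=list(CLAUDIN_GENES)), kind="raw_sum", **kwargs
    )


def filter_expressed(
    mat: ExpressionMatrix,
    candidate_genes: Sequence[str],
    policy: Literal["present", "nonzero_fraction"] = "nonzero_fraction",
    min_fraction: float = 0.5,
    name: str = "expressed",
) -> GeneSet:
    """Narrow a candidate gene list to those passing an expression policy.

    ``present``: gene row exists in the matrix. ``nonzero_fraction``: present
    and nonzero in at least ``min_fraction`` of samples (default 0.5).
    """
    if not candidate_genes:
        raise AnalysisError("empty candidate gene list")
    rows, used, _ = _match_genes(mat, candidate_genes)
    if policy == "present":
        kept = used
    elif policy == "nonzero_fraction":
        kept = []
        values = np.asarray(mat.values, dtype=float)
        for i, g in zip(rows, used):
            frac = float(np.mean(values[i] != 0))
            if frac >= min_fraction:
                kept.append(g)
    else:
        raise AnalysisError(f"unknown expression policy {policy!r}")
    logger.info(
        "filter_expressed(%s): %d/%d candidates retained",
        policy, len(kept), len(candidate_genes),
    )
    if not kept:
        raise AnalysisError("no candidate gene passes the expression policy")
    return GeneSet(name=name, genes=kept)


def subtype_score_comparison(
    scores: ScoreVector,
    annotations: Sequence[SampleAnnotation],
    min_n: int = 2,
) -> tuple[pd.DataFrame, float, list[PairwiseComparison]]:
    """Per-subtype score summary plus ANOVA + Tukey across subtypes.

    Subtypes with fewer than ``min_n`` scored samples are excluded and
    logged. Reuses the screening module's statistical kernels.
    """
    subtype_of = {a.sample_id: a.subtype for a in annotations}
    by_subtype: dict[str, list[float]] = {}
    for sid, v in zip(scores.sample_ids, scores.values):
        if sid in subtype_of and np.isfinite(v):
            by_subtype.setdefault(subtype_of[sid], []).append(float(v))
    groups, names = [], []
    for s in sorted(by_subtype):
        if len(by_subtype[s]) < min_n:
            logger.warning("subtype %s excluded: only %d samples", s, len(by_subtype[s]))
            continue
        groups.append(np.asarray(by_subtype[s]))
        names.append(s)
    if len(groups) < 2:
        raise AnalysisError("need >= 2 subtypes with enough samples")
    summary = pd.DataFrame(
        {
            "subtype": names,
            "n": [len(g) for g in groups],
            "mean": [float(np.mean(g)) for g in groups],
            "median": [float(np.median(g)) for g in groups],
            "iqr": [float(np.subtract(*np.percentile(g, [75, 25]))) for g in groups],
        }
    )
    _, anova_p = one_way_anova(groups)
    pairwise = tukey_hsd(groups, names)
    return summary, anova_p, pairwise
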