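"""Readers/writers for every external representation the pipeline touches.

All downstream modules consume only the in-memory domain types defined here:
:class:`ExpressionMatrix`, :class:`SampleAnnotation`,
:class:`DrugResponseMatrix` and :class:`GeneSet`.

Conventions
-----------
* TSV/CSV matrices carry identifiers in the first column and a header row of
  sample (or drug) identifiers. Input order is preserved on read and write.
* Missing-value tokens accepted on read: ``""``, ``NA``, ``NaN``, ``null``;
  ``NA`` is written.
* Gene identifiers are matched case-insensitively after whitespace trimming;
  no alias or ortholog mapping is attempted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ParseError

logger = logging.getLogger(__name__)

MISSING_TOKENS = frozenset({"", "NA", "NaN", "nan", "null", "NULL"})
MISSING_WRITE_TOKEN = "NA"

DuplicateRule = Literal["error", "sum", "mean", "first"]

SUBTYPES = (
    "Luminal",
    "LuminalA",
    "LuminalB",
    "HER2",
    "Basal",
    "ClaudinLow",
    "Normal",
    "other",
)
IHC_GROUPS = ("ER_PR_pos_HER2_neg", "HER2_pos", "TNBC")
MUTATION_STATES = ("wild_type", "mutant", "unknown")


def normalize_gene(gene: str) -> str:
    """Canonical key for case-insensitive, whitespace-trimmed gene matching."""
    return gene.strip().upper()


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Dense gene x sample matrix of expression values.

    ``value_kind`` is one of ``counts``/``normalized``/``zscore``. Unless the
    matrix holds z-scores, all finite entries must be non-negative.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    value_kind: Literal["counts", "normalized", "zscore"] = "normalized"

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise FormatError("gene identifiers must be unique")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("sample identifiers must be unique")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if self.value_kind != "zscore":
            finite = self.values[np.isfinite(self.values)]
            if finite.size and finite.min() < 0:
                raise FormatError(
                    f"negative entries not allowed for value_kind={self.value_kind!r}"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def gene_row(self, gene: str) -> Optional[np.ndarray]:
        """Row for ``gene`` under case-insensitive matching, or None."""
        key = normalize_gene(gene)
        for i, g in enumerate(self.gene_ids):
            if normalize_gene(g) == key:
                return self.values[i]
        return None


@dataclass
class SampleAnnotation:
    """Per-sample metadata: subtype, receptor group, mutations, survival."""

    sample_id: str
    subtype: str = "other"
    ihc_group: Optional[str] = None
    mutations: dict[str, str] = field(default_factory=dict)
    survival_time: Optional[float] = None
    survival_event: Optional[int] = None

    def __post_init__(self) -> None:
        if (self.survival_time is None) != (self.survival_event is None):
            raise FormatError(
                f"sample {self.sample_id!r}: survival_event must be present "
                "iff survival_time is present"
            )
        if self.survival_time is not None and self.survival_time < 0:
            raise FormatError(f"sample {self.sample_id!r}: negative survival_time")
        if self.survival_event is not None and self.survival_event not in (0, 1):
            raise FormatError(f"sample {self.sample_id!r}: survival_event must be 0/1")
        for gene, state in self.mutations.items():
            if state not in MUTATION_STATES:
                raise FormatError(
                    f"sample {self.sample_id!r}: bad mutation state {state!r} for {gene}"
                )


@dataclass
class DrugResponseMatrix:
    """Cell line x drug matrix of IC50 z-scores; NaN marks missing cells."""

    line_ids: list[str]
    drug_ids: list[str]
    z_ic50: np.ndarray

    def __post_init__(self) -> None:
        self.line_ids = [str(x) for x in self.line_ids]
        self.drug_ids = [str(x) for x in self.drug_ids]
        self.z_ic50 = np.asarray(self.z_ic50, dtype=float)
        if len(set(self.line_ids)) != len(self.line_ids):
            raise FormatError("line identifiers must be unique")
        if len(set(self.drug_ids)) != len(self.drug_ids):
            raise FormatError("drug identifiers must be unique")
        if self.z_ic50.shape != (len(self.line_ids), len(self.drug_ids)):
            raise FormatError("z_ic50 shape does not match line/drug identifiers")

    @property
    def shape(self) -> tuple[int, int]:
        return self.z_ic50.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.z_ic50, index=self.line_ids, columns=self.drug_ids)

    def drug_column(self, drug_id: str) -> np.ndarray:
        return self.z_ic50[:, self.drug_ids.index(drug_id)]


@dataclass
class GeneSet:
    """A named, ordered list of unique gene symbols."""

    name: str
    genes: list[str]

    def __post_init__(self) -> None:
        self.genes = [str(g).strip() for g in self.genes]
        if not self.genes:
            raise FormatError(f"gene set {self.name!r} is empty")
        keys = [normalize_gene(g) for g in self.genes]
        if len(set(keys)) != len(keys):
            raise FormatError(f"gene set {self.name!r} contains duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)


# ---------------------------------------------------------------------------
# Low-level helpers
# ---------------------------------------------------------------------------


def _sep_for(path: Path, dialect: Optional[str]) -> str:
    if dialect is not None:
        if dialect not in ("tsv", "csv"):
            raise FormatError(f"unknown dialect {dialect!r}")
        return "\t" if dialect == "tsv" else ","
    return "," if path.suffix.lower() == ".csv" else "\t"


def _parse_cell(token: str, row: str, col: str) -> float:
    token = token.strip()
    if token in MISSING_TOKENS:
        return math.nan
    try:
        return float(token)
    except ValueError:
        raise ParseError(
            f"non-numeric value {token!r} at row {row!r}, column {col!r}"
        ) from None


def _read_table(path: Path, sep: str) -> pd.DataFrame:
    """Read a labelled numeric table as floats, NaN for missing tokens."""
    try:
        raw = pd.read_csv(
            path, sep=sep, index_col=0, dtype=str, keep_default_na=False
        )
    except pd.errors.EmptyDataError:
        raise FormatError(f"empty file: {path}") from None
    raw.index = raw.index.astype(str).str.strip()
    raw.columns = raw.columns.astype(str).str.strip()
    values = np.empty(raw.shape, dtype=float)
    for j, col in enumerate(raw.columns):
        for i, row in enumerate(raw.index):
            values[i, j] = _parse_cell(str(raw.iat[i, j]), row, col)
    return pd.DataFrame(values, index=raw.index, columns=raw.columns)


def _collapse_duplicates(df: pd.DataFrame, rule: DuplicateRule) -> pd.DataFrame:
    keys = df.index.to_series().map(normalize_gene)
    if not keys.duplicated().any():
        return df
    if rule == "error":
        dups = sorted(set(keys[keys.duplicated()]))
        raise FormatError(f"duplicate gene rows {dups}; pass duplicate_rule to collapse")
    first_label = {}
    for label, key in zip(df.index, keys):
        first_label.setdefault(key, label)
    grouped = df.groupby(keys.values, sort=False)
    if rule == "sum":
        out = grouped.sum(min_count=1)
    elif rule == "mean":
        out = grouped.mean()
    elif rule == "first":
        out = grouped.first()
    else:
        raise FormatError(f"unknown duplicate rule {rule!r}")
    out.index = [first_label[k] for k in out.index]
    logger.info("collapsed duplicate gene rows with rule %r", rule)
    return out


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------


def read_expression_matrix(
    path: str | Path,
    dialect: Optional[str] = None,
    duplicate_rule: DuplicateRule = "error",
    value_kind: Literal["counts", "normalized", "zscore"] = "normalized",
) -> ExpressionMatrix:
    """Read a gene x sample matrix (first column = gene ids, header = samples).

    Duplicate gene rows (case-insensitive) are collapsed by ``duplicate_rule``
    (``error``/``sum``/``mean``/``first``); the rule used is logged.
    """
    path = Path(path)
    df = _read_table(path, _sep_for(path, dialect))
    if df.shape[1] == 0:
        raise FormatError(f"no sample columns in {path}")
    df = _collapse_duplicates(df, duplicate_rule)
    logger.info(
        "read expression matrix %s: %d genes x %d samples (duplicate_rule=%s)",
        path, df.shape[0], df.shape[1], duplicate_rule,
    )
    return ExpressionMatrix(
        gene_ids=list(df.index),
        sample_ids=list(df.columns),
        values=df.to_numpy(),
        value_kind=value_kind,
    )


def write_expression_matrix(
    mat: ExpressionMatrix, path: str | Path, dialect: Optional[str] = None
) -> None:
    path = Path(path)
    mat.to_frame().to_csv(
        path, sep=_sep_for(path, dialect), na_rep=MISSING_WRITE_TOKEN,
        index_label="gene",
    )


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------


def read_gene_sets(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: name, description, then >= 1 tab-separated genes."""
    path = Path(path)
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            genes = [g.strip() for g in fields[2:] if g.strip()]
            if len(fields) < 3 or not genes:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description and >= 1 gene"
                )
            # tolerate within-line duplicates: keep first occurrence
            seen: set[str] = set()
            unique = []
            for g in genes:
                key = normalize_gene(g)
                if key not in seen:
                    seen.add(key)
                    unique.append(g)
            if len(unique) < len(genes):
                logger.warning("%s:%d: dropped duplicate genes", path, lineno)
            sets.append(GeneSet(name=fields[0].strip(), genes=unique))
    if not sets:
        raise FormatError(f"no gene sets found in {path}")
    return sets


def write_gene_sets(sets: Sequence[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, "na", *gs.genes]) + "\n")


# ---------------------------------------------------------------------------
# Drug response matrices
# ---------------------------------------------------------------------------

_LONG_LINE_COLS = {"line", "line_id", "cell_line", "sample", "sample_id"}
_LONG_DRUG_COLS = {"drug", "drug_id", "compound"}
_LONG_VALUE_COLS = {"z", "z_ic50", "zscore", "z_score", "value"}


def read_drug_response(path: str | Path, dialect: Optional[str] = None) -> DrugResponseMatrix:
    """Read line x drug z-scores; wide or long layout auto-detected by header.

    Long layout columns (any casing): line/cell_line, drug, z/z_ic50. Missing
    cells are preserved as NaN and never imputed.
    """
    path = Path(path)
    sep = _sep_for(path, dialect)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
    if not header.strip():
        raise FormatError(f"empty file: {path}")
    cols = [c.strip().lower() for c in header.split(sep)]
    is_long = (
        len(cols) == 3
        and cols[0] in _LONG_LINE_COLS
        and cols[1] in _LONG_DRUG_COLS
        and cols[2] in _LONG_VALUE_COLS
    )
    if is_long:
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
        lines, drugs = [], []
        cells: dict[tuple[str, str], float] = {}
        for _, rec in df.iterrows():
            line = str(rec.iloc[0]).strip()
            drug = str(rec.iloc[1]).strip()
            z = _parse_cell(str(rec.iloc[2]), line, drug)
            if (line, drug) in cells:
                raise FormatError(f"duplicate (line, drug) pair ({line!r}, {drug!r})")
            cells[(line, drug)] = z
            if line not in lines:
                lines.append(line)
            if drug not in drugs:
                drugs.append(drug)
        values = np.full((len(lines), len(drugs)), np.nan)
        for (line, drug), z in cells.items():
            values[lines.index(line), drugs.index(drug)] = z
        return DrugResponseMatrix(line_ids=lines, drug_ids=drugs, z_ic50=values)
    df = _read_table(path, sep)
    return DrugResponseMatrix(
        line_ids=list(df.index), drug_ids=list(df.columns), z_ic50=df.to_numpy()
    )


def write_drug_response(
    resp: DrugResponseMatrix,
    path: str | Path,
    dialect: Optional[str] = None,
    layout: Literal["wide", "long"] = "wide",
) -> None:
    path = Path(path)
    sep = _sep_for(path, dialect)
    if layout == "wide":
        resp.to_frame().to_csv(
            path, sep=sep, na_rep=MISSING_WRITE_TOKEN, index_label="line"
        )
        return
    rows = []
    for i, line in enumerate(resp.line_ids):
        for j, drug in enumerate(resp.drug_ids):
            z = resp.z_ic50[i, j]
            if np.isfinite(z):
                rows.append((line, drug, z))
    pd.DataFrame(rows, columns=["line", "drug", "z_ic50"]).to_csv(
        path, sep=sep, index=False
    )


# ---------------------------------------------------------------------------
# Sample annotations
# ---------------------------------------------------------------------------

_MUT_PREFIX = "mut_"


def read_sample_annotations(path: str | Path, dialect: Optional[str] = None) -> list[SampleAnnotation]:
    """Read per-sample annotations.

    Required column ``sample_id``; optional ``subtype``, ``ihc_group``,
    ``survival_time``, ``survival_event`` and any number of ``mut_<GENE>``
    columns holding wild_type/mutant/unknown.
    """
    path = Path(path)
    sep = _sep_for(path, dialect)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: missing required column 'sample_id'")
    mut_cols = [c for c in df.columns if c.startswith(_MUT_PREFIX)]
    out = []
    for _, rec in df.iterrows():
        def _opt(col: str) -> Optional[str]:
            if col not in df.columns:
                return None
            v = str(rec[col]).strip()
            return None if v in MISSING_TOKENS else v

        time_s, event_s = _opt("survival_time"), _opt("survival_event")
        mutations = {}
        for c in mut_cols:
            v = _opt(c)
            mutations[c[len(_MUT_PREFIX):]] = v if v is not None else "unknown"
        out.append(
            SampleAnnotation(
                sample_id=str(rec["sample_id"]).strip(),
                subtype=_opt("subtype") or "other",
                ihc_group=_opt("ihc_group"),
                mutations=mutations,
                survival_time=float(time_s) if time_s is not None else None,
                survival_event=int(float(event_s)) if event_s is not None else None,
            )
        )
    if len({a.sample_id for a in out}) != len(out):
        raise FormatError(f"{path}: duplicate sample_id values")
    return out


def write_sample_annotations(
    annotations: Sequence[SampleAnnotation], path: str | Path, dialect: Optional[str] = None
) -> None:
    path = Path(path)
    mut_genes = sorted({g for a in annotations for g in a.mutations})
    rows = []
    for a in annotations:
        row: dict[str, object] = {
            "sample_id": a.sample_id,
            "subtype": a.subtype,
            "ihc_group": a.ihc_group if a.ihc_group is not None else MISSING_WRITE_TOKEN,
            "survival_time": a.survival_time if a.survival_time is not None else MISSING_WRITE_TOKEN,
            "survival_event": a.survival_event if a.survival_event is not None else MISSING_WRITE_TOKEN,
        }
        for g in mut_genes:
            row[_MUT_PREFIX + g] = a.mutations.get(g, "unknown")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=_sep_for(path, dialect), index=False)


def annotation_map(annotations: Sequence[SampleAnnotation]) -> Mapping[str, SampleAnnotation]:
    return {a.sample_id: a for a in annotations}
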