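"""Readers/writers for all tabular inputs and outputs, with strict schema checks.

No science lives here: just validated containers and lossless round trips.
Delimiter is auto-detected between comma and tab on read; writes are
tab-separated. Missing values may be encoded as an empty cell or ``NA`` on
read; ``NA`` is written.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

REGIONS = ("TCX", "HIP", "PCX", "FWM", "FCX")
UNITS = ("fpkm", "intensity", "protein_ratio")

#: Ordinal age classes, 5-year increments with a top-coded "90+" class.
AGE_CLASSES = ("70-74", "75-79", "80-84", "85-89", "90+")

_TRUE_TOKENS = {"1", "y", "yes", "true", "t"}
_FALSE_TOKENS = {"0", "n", "no", "false", "f"}
_NA_TOKENS = {"", "na", "nan"}


class SchemaError(ValueError):
    """Input violates the declared table schema (duplicates, missing columns...)."""


class UnitError(ValueError):
    """Operation requires a different expression unit than the one provided."""


def _detect_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


@dataclass
class ExpressionMatrix:
    """Gene x sample abundance matrix for one brain region.

    ``values`` is a pandas DataFrame indexed by Entrez-ID strings with
    sample-ID columns; all entries finite and non-negative.
    """

    region: str
    unit: str
    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise SchemaError(f"unknown region {self.region!r}; expected one of {REGIONS}")
        if self.unit not in UNITS:
            raise SchemaError(f"unknown unit {self.unit!r}; expected one of {UNITS}")
        vals = self.values
        dup_genes = vals.index[vals.index.duplicated()].tolist()
        if dup_genes:
            raise SchemaError(f"duplicate gene_ids: {sorted(set(dup_genes))}")
        dup_samples = vals.columns[vals.columns.duplicated()].tolist()
        if dup_samples:
            raise SchemaError(f"duplicate sample_ids: {sorted(set(dup_samples))}")
        arr = vals.to_numpy(dtype=float)
        bad = ~np.isfinite(arr)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"non-finite value at gene {vals.index[i]!r}, sample {vals.columns[j]!r}"
            )
        neg = arr < 0
        if neg.any():
            i, j = np.argwhere(neg)[0]
            raise ValueError(
                f"negative value {arr[i, j]} at gene {vals.index[i]!r}, "
                f"sample {vals.columns[j]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.region, self.unit, self.values.loc[list(gene_ids)])


@dataclass
class SubjectRecord:
    """Per-subject covariates and diagnosis."""

    subject_id: str
    age_increment: int  # ordinal index into AGE_CLASSES
    sex: str | None
    dementia: bool
    apoe4_carrier: bool | None
    tbi_history: bool | None
    education_years: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.age_increment < len(AGE_CLASSES):
            raise SchemaError(
                f"age_increment {self.age_increment} outside ordinal range "
                f"0..{len(AGE_CLASSES) - 1} for subject {self.subject_id!r}"
            )

    @property
    def age_class(self) -> str:
        return AGE_CLASSES[self.age_increment]

    @property
    def missing_covariates(self) -> list[str]:
        return [
            name
            for name in ("sex", "apoe4_carrier", "tbi_history")
            if getattr(self, name) is None
        ]


def subjects_to_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Covariate DataFrame indexed by subject_id (booleans as float 0/1, NaN missing)."""
    rows = {}
    for r in records:
        rows[r.subject_id] = {
            "age_increment": float(r.age_increment),
            "sex_male": np.nan if r.sex is None else float(r.sex == "M"),
            "dementia": float(r.dementia),
            "apoe4": np.nan if r.apoe4_carrier is None else float(r.apoe4_carrier),
            "tbi": np.nan if r.tbi_history is None else float(r.tbi_history),
            "education_years": np.nan if r.education_years is None else float(r.education_years),
        }
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "subject_id"
    return frame


@dataclass
class PathologyPanel:
    """Quantitative and ordinal neuropathology per sample, one region.

    ``quantitative``: DataFrame indexed by sample_id with columns
    ab_ihc, ab40_pg_mg, ab42_pg_mg, at8_ihc, ptau_ng_mg, tau_total_ng_mg.
    ``ordinal``: braak (0-6), neuritic_plaque_score, caa_score; NaN = missing.
    """

    region: str
    quantitative: pd.DataFrame
    ordinal: pd.DataFrame

    QUANT_COLS = ("ab_ihc", "ab40_pg_mg", "ab42_pg_mg", "at8_ihc", "ptau_ng_mg", "tau_total_ng_mg")
    ORDINAL_COLS = ("braak", "neuritic_plaque_score", "caa_score")

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise SchemaError(f"unknown region {self.region!r}")
        missing = set(self.QUANT_COLS) - set(self.quantitative.columns)
        if missing:
            raise SchemaError(f"pathology panel missing columns {sorted(missing)}")
        arr = self.quantitative[list(self.QUANT_COLS)].to_numpy(dtype=float)
        if np.nanmin(arr, initial=0.0) < 0:
            raise ValueError("pathology measures must be non-negative")

    def with_ratios(self) -> pd.DataFrame:
        """Quantitative table plus derived ratios; NaN where the denominator is 0."""
        out = self.quantitative.copy()
        ab40 = out["ab40_pg_mg"]
        tau = out["tau_total_ng_mg"]
        out["ab42_ab40_ratio"] = np.where(ab40 > 0, out["ab42_pg_mg"] / ab40, np.nan)
        out["ptau_tau_ratio"] = np.where(tau > 0, out["ptau_ng_mg"] / tau, np.nan)
        return out


#: The seven continuous pathology outcomes modelled by OLS.
PATHOLOGY_OUTCOMES = (
    "ab_ihc",
    "ab40_pg_mg",
    "ab42_pg_mg",
    "ab42_ab40_ratio",
    "at8_ihc",
    "ptau_ng_mg",
    "ptau_tau_ratio",
)


@dataclass
class CellTypeFractionTable:
    """Per-gene expression by cell type, with the derived astrocyte fraction."""

    values: pd.DataFrame  # gene x cell-type, non-negative
    astro_fraction: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        if "astrocyte" not in self.values.columns:
            raise SchemaError("cell-type table must contain an 'astrocyte' column")
        arr = self.values.to_numpy(dtype=float)
        if (arr < 0).any() or not np.isfinite(arr).all():
            raise ValueError("cell-type expression values must be finite and non-negative")
        total = self.values.sum(axis=1)
        n_zero = int((total == 0).sum())
        if n_zero:
            warnings.warn(f"{n_zero} genes with zero total cell-type expression; fraction set to 0")
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = self.values["astrocyte"] / total
        self.astro_fraction = frac.fillna(0.0)


# ---------------------------------------------------------------------------
# readers


def read_expression(
    path: str | Path,
    region: str,
    unit: str = "fpkm",
    samples_as_rows: bool = False,
) -> ExpressionMatrix:
    """Read a delimited gene x sample table (first column = gene IDs).

    With ``samples_as_rows`` the file holds samples as rows (GEO
    series-matrix-style after export) and is transposed on read.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep=_detect_sep(path), index_col=0, dtype=str)
    frame.index = frame.index.astype(str)
    if samples_as_rows:
        frame = frame.T
    def _parse(v):
        try:
            return float(v)  # correctly-rounded parse: exact round trips
        except (TypeError, ValueError):
            return np.nan

    numeric = frame.map(_parse)
    bad_rows = numeric.isna().any(axis=1) & frame.notna().any(axis=1)
    if bad_rows.any():
        idx = [i for i, b in enumerate(bad_rows) if b]
        raise ValueError(
            f"unparseable numeric values in rows {idx} (genes {list(frame.index[bad_rows])})"
        )
    return ExpressionMatrix(region=region, unit=unit, values=numeric.astype(float))


def _parse_bool(token: str, what: str) -> bool | None:
    tok = token.strip().lower()
    if tok in _NA_TOKENS:
        return None
    if tok in _TRUE_TOKENS:
        return True
    if tok in _FALSE_TOKENS:
        return False
    raise SchemaError(f"cannot parse boolean {what}={token!r}")


def parse_age_class(token: str) -> int:
    """Map an age-class string like '80-84' or '90+' to its ordinal index."""
    tok = token.strip()
    if tok in AGE_CLASSES:
        return AGE_CLASSES.index(tok)
    # accept a plain integer age, binned into the 5-year classes
    try:
        age = float(tok)
    except ValueError:
        raise SchemaError(f"unrecognized age class {token!r}") from None
    if age >= 90:
        return len(AGE_CLASSES) - 1
    for i, cls in enumerate(AGE_CLASSES[:-1]):
        lo, hi = (int(x) for x in cls.split("-"))
        if lo <= age <= hi:
            return i
    raise SchemaError(f"age {token!r} outside configured ordinal range")


def read_subjects(
    path: str | Path, column_map: Mapping[str, str] | str | Path | None = None
) -> list[SubjectRecord]:
    """Read the per-subject covariate table.

    Mandatory columns: subject_id, age, sex, dementia, apoe4, tbi.
    Optional: education_years. Booleans accept Y/N, 0/1, TRUE/FALSE;
    missing covariates are allowed and flagged on the record.

    ``column_map`` renames source columns to the canonical names before
    validation — either a mapping ``{source: canonical}`` or the path of a
    two-column file holding one — so cohort downloads with release-specific
    headers can be read without editing the file.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep=_detect_sep(path), dtype=str).fillna("")
    if column_map is not None:
        if not isinstance(column_map, Mapping):
            column_map = read_gene_symbol_map(column_map)  # same 2-column layout
        frame = frame.rename(columns=dict(column_map))
    required = {"subject_id", "age", "sex", "dementia", "apoe4", "tbi"}
    missing = required - set(frame.columns)
    if missing:
        raise SchemaError(f"subject table missing mandatory columns {sorted(missing)}")
    records: list[SubjectRecord] = []
    seen: set[str] = set()
    for _, row in frame.iterrows():
        sid = row["subject_id"].strip()
        if sid in seen:
            raise SchemaError(f"duplicate subject_id {sid!r}")
        seen.add(sid)
        sex_tok = row["sex"].strip().upper()
        sex = None if sex_tok.lower() in _NA_TOKENS else sex_tok[0]
        dementia = _parse_bool(row["dementia"], "dementia")
        if dementia is None:
            raise SchemaError(f"dementia status missing for subject {sid!r}")
        edu = row.get("education_years", "").strip()
        records.append(
            SubjectRecord(
                subject_id=sid,
                age_increment=parse_age_class(row["age"]),
                sex=sex,
                dementia=dementia,
                apoe4_carrier=_parse_bool(row["apoe4"], "apoe4"),
                tbi_history=_parse_bool(row["tbi"], "tbi"),
                education_years=None if edu.lower() in _NA_TOKENS else int(float(edu)),
            )
        )
    return records


def read_celltype_table(path: str | Path) -> CellTypeFractionTable:
    """Read a gene x cell-type non-negative expression table."""
    path = Path(path)
    frame = pd.read_csv(path, sep=_detect_sep(path), index_col=0)
    frame.index = frame.index.astype(str)
    return CellTypeFractionTable(values=frame.astype(float))


def read_pathology(path: str | Path, region: str) -> PathologyPanel:
    path = Path(path)
    frame = pd.read_csv(path, sep=_detect_sep(path), index_col=0)
    frame.index = frame.index.astype(str)
    quant = frame[list(PathologyPanel.QUANT_COLS)].astype(float)
    ordinal_cols = [c for c in PathologyPanel.ORDINAL_COLS if c in frame.columns]
    ordinal = frame[ordinal_cols].astype(float)
    return PathologyPanel(region=region, quantitative=quant, ordinal=ordinal)


def read_gene_symbol_map(path: str | Path) -> dict[str, str]:
    """Two-column symbol -> Entrez-ID mapping, exact match only."""
    path = Path(path)
    frame = pd.read_csv(path, sep=_detect_sep(path), dtype=str)
    if frame.shape[1] != 2:
        raise SchemaError("symbol map must have exactly two columns (symbol, gene_id)")
    return dict(zip(frame.iloc[:, 0], frame.iloc[:, 1]))


# ---------------------------------------------------------------------------
# writers


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    # %.17g guarantees the shortest exact round trip for doubles
    expr.values.to_csv(
        path, sep="\t", index_label="gene_id", na_rep="NA", float_format="%.17g"
    )


def write_subjects(records: Sequence[SubjectRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "subject_id": r.subject_id,
                "age": r.age_class,
                "sex": "NA" if r.sex is None else r.sex,
                "dementia": "Y" if r.dementia else "N",
                "apoe4": "NA" if r.apoe4_carrier is None else ("Y" if r.apoe4_carrier else "N"),
                "tbi": "NA" if r.tbi_history is None else ("Y" if r.tbi_history else "N"),
                "education_years": "NA" if r.education_years is None else r.education_years,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_results(records: Iterable, path: str | Path) -> None:
    """Write a collection of result records (dataclasses or a DataFrame) as TSV.

    Column order is deterministic; rows are sorted by (gene, region, outcome)
    where those columns exist, so identical inputs give byte-identical files.
    """
    if isinstance(records, pd.DataFrame):
        frame = records.copy()
    else:
        rows = []
        for rec in records:
            if dataclasses.is_dataclass(rec):
                rows.append(dataclasses.asdict(rec))
            elif isinstance(rec, Mapping):
                rows.append(dict(rec))
            else:
                raise TypeError(f"cannot serialize record of type {type(rec)!r}")
        frame = pd.DataFrame(rows)
    sort_cols = [c for c in ("gene_id", "region", "outcome") if c in frame.columns]
    if sort_cols:
        frame = frame.sort_values(sort_cols, kind="mergesort")
    frame.to_csv(path, sep="\t", index=False, na_rep="NA")


def write_config_echo(config: Mapping, path: str | Path) -> None:
    """Echo the run configuration as sorted key-value lines."""
    with open(path, "w") as fh:
        for key in sorted(config):
            fh.write(f"{key}\t{config[key]}\n")
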