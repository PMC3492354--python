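"""Domain types and tab-delimited readers/writers.

The in-memory containers are thin wrappers around pandas DataFrames:

* :class:`BetaMatrix` — CpG probes x samples methylation fractions in
  [0, 1], with an optional matched detection p-value matrix.  Missing
  measurements are NaN and are excluded pairwise downstream (never
  imputed, except for the PCA/clustering views which state so).
* probe annotation — a DataFrame indexed by probe id with columns
  ``gene_symbol, chromosome, cytoband, position, promoter_class,
  is_pcg_target, is_gonosomal``.
* sample sheet — a DataFrame indexed by sample id with columns
  ``group, inss_stage, mycn, age_months, risk``.

All files are plain TSV.  The first column carries the row identifier,
the header row the column names; lines starting with ``#`` are
metadata comments (config hash, seed) and are ignored on read.
Genomic positions use a 0-based internal convention; any interval
output follows BED.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BetaMatrix",
    "FormatError",
    "ParseError",
    "GROUPS",
    "PROMOTER_CLASSES",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_annotation",
    "write_annotation",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_matrix_tsv",
    "write_tsv",
    "derive_risk",
    "config_hash",
]

GROUPS = ("NB", "GN", "GNB", "FB", "AG")
PROMOTER_CLASSES = ("HCP", "ICP", "LCP", "MIXED", "UNKNOWN")
INSS_STAGES = ("1", "2", "3", "4", "4S", "NA")
MYCN_STATUS = ("amplified", "non_amplified", "undetermined")


class FormatError(ValueError):
    """Structural problem in an input file (duplicate ids, missing columns...)."""


class ParseError(ValueError):
    """Cell-level problem, reported with row/column context."""


@dataclass
class BetaMatrix:
    """Probes x samples methylation fractions with optional detection p-values.

    Parameters
    ----------
    beta
        DataFrame of methylation fractions, probes as index, samples as
        columns. NaN marks a missing measurement.
    detection_p
        Optional DataFrame of per-probe detection p-values with the exact
        same index/columns as ``beta``.
    """

    beta: pd.DataFrame
    detection_p: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        b = self.beta
        if not b.index.is_unique:
            dup = b.index[b.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate probe ids: {dup[:5]}")
        if not b.columns.is_unique:
            dup = b.columns[b.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dup[:5]}")
        vals = b.to_numpy(dtype=float)
        bad = np.isfinite(vals) & ((vals < 0.0) | (vals > 1.0))
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise FormatError(
                f"beta value out of [0,1]: {vals[i, j]!r} at probe "
                f"{b.index[i]!r}, sample {b.columns[j]!r}"
            )
        self.beta = b.astype(float)
        if self.detection_p is not None:
            d = self.detection_p
            if list(d.index) != list(b.index) or list(d.columns) != list(b.columns):
                raise FormatError("detection_p dimensions/ids do not match beta")
            self.detection_p = d.astype(float)

    # -- basic introspection -------------------------------------------------
    @property
    def probe_ids(self) -> list[str]:
        return list(self.beta.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.beta.columns)

    @property
    def n_probes(self) -> int:
        return self.beta.shape[0]

    @property
    def n_samples(self) -> int:
        return self.beta.shape[1]

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.beta.isna()

    def subset(
        self,
        probes: Sequence[str] | None = None,
        samples: Sequence[str] | None = None,
    ) -> "BetaMatrix":
        """Return a new BetaMatrix restricted to the given probes/samples."""
        b = self.beta
        d = self.detection_p
        if probes is not None:
            b = b.loc[list(probes)]
            d = d.loc[list(probes)] if d is not None else None
        if samples is not None:
            b = b[list(samples)]
            d = d[list(samples)] if d is not None else None
        return BetaMatrix(b, d)

    def values_for(self, sample_ids: Sequence[str]) -> np.ndarray:
        """Float array (probes x len(sample_ids)) for the given samples."""
        return self.beta[list(sample_ids)].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# generic TSV plumbing
# ---------------------------------------------------------------------------

def config_hash(obj) -> str:
    """Short stable hash of a (nested) configuration mapping."""
    import json

    payload = json.dumps(obj, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_tsv(df: pd.DataFrame, path, comments: Mapping[str, object] | None = None,
              index_label: str | None = None) -> None:
    """Write a DataFrame as TSV with leading ``# key: value`` comment lines."""
    with open(path, "w") as fh:
        for key, val in (comments or {}).items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, sep="\t", index_label=index_label)


def read_header_comments(path) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if ":" in body:
                key, val = body.split(":", 1)
                out[key.strip()] = val.strip()
    return out


def _read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)


def read_matrix_tsv(path, value_range: tuple[float, float] | None = None) -> pd.DataFrame:
    """Read an id x sample numeric matrix, with cell-level error context.

    Empty cells become NaN (missing).  Non-numeric cells raise
    :class:`ParseError` naming the probe row and sample column; values
    outside ``value_range`` (when given) raise :class:`FormatError`.
    """
    with open(path) as fh:
        header = next((ln for ln in fh if not ln.startswith("#")), "")
    names = header.rstrip("\n").split("\t")[1:]
    if len(names) != len(set(names)):
        raise FormatError(f"{path}: duplicate sample ids in header")
    raw = _read_table(path)
    if raw.shape[1] < 2:
        raise FormatError(f"{path}: expected an id column plus >=1 sample column")
    ids = raw.iloc[:, 0]
    if ids.duplicated().any():
        raise FormatError(
            f"{path}: duplicate row ids: {ids[ids.duplicated()].unique()[:5].tolist()}"
        )
    body = raw.iloc[:, 1:].copy()
    mat = pd.DataFrame(index=ids.to_numpy(), columns=body.columns, dtype=float)
    for col in body.columns:
        cell = body[col].str.strip()
        cell = cell.mask(cell.isin(["", "NA", "NaN", "nan"]))
        num = pd.to_numeric(cell, errors="coerce")
        bad = num.isna() & cell.notna()
        if bad.any():
            row = bad.idxmax()
            raise ParseError(
                f"{path}: non-numeric value {cell[row]!r} at probe "
                f"{ids[row]!r}, sample {col!r}"
            )
        mat[col] = num.to_numpy()
    if value_range is not None:
        lo, hi = value_range
        vals = mat.to_numpy()
        bad2 = np.isfinite(vals) & ((vals < lo) | (vals > hi))
        if bad2.any():
            i, j = map(int, np.argwhere(bad2)[0])
            raise FormatError(
                f"{path}: value {vals[i, j]!r} outside [{lo}, {hi}] at probe "
                f"{mat.index[i]!r}, sample {mat.columns[j]!r}"
            )
    mat.index.name = None
    return mat


# ---------------------------------------------------------------------------
# beta matrix
# ---------------------------------------------------------------------------

def read_beta_matrix(path, detection_p_path=None) -> BetaMatrix:
    """Read a beta matrix (and optional companion detection-p matrix).

    The dialect is the tab-delimited layout of GEO series-matrix style
    exports: first column probe ids, header row of sample ids.
    """
    beta = read_matrix_tsv(path, value_range=(0.0, 1.0))
    det = None
    if detection_p_path is not None:
        det = read_matrix_tsv(detection_p_path, value_range=(0.0, 1.0))
        det = det.reindex(index=beta.index, columns=beta.columns)
    return BetaMatrix(beta, det)


def write_beta_matrix(bm: BetaMatrix, path, detection_p_path=None,
                      comments: Mapping[str, object] | None = None) -> None:
    write_tsv(bm.beta, path, comments, index_label="probe_id")
    if detection_p_path is not None and bm.detection_p is not None:
        write_tsv(bm.detection_p, detection_p_path, comments, index_label="probe_id")


# ---------------------------------------------------------------------------
# probe annotation
# ---------------------------------------------------------------------------

_ANN_REQUIRED = ("probe_id", "gene_symbol", "chromosome")
_ANN_OPTIONAL = ("cytoband", "position", "promoter_class", "is_pcg_target")

_TRUTHY = {"1", "true", "yes", "y"}
_FALSY = {"0", "false", "no", "n", ""}


def normalize_chromosome(chrom: str) -> str:
    c = str(chrom).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    return c.upper()


def read_annotation(path) -> pd.DataFrame:
    """Read a probe annotation table.

    Required columns: probe_id, gene_symbol, chromosome.  Optional:
    cytoband, position, promoter_class, is_pcg_target.  The gonosomal
    flag is derived (chromosome X or Y); promoter_class defaults to
    UNKNOWN when the column is absent.
    """
    raw = _read_table(path)
    missing = [c for c in _ANN_REQUIRED if c not in raw.columns]
    if missing:
        raise FormatError(f"{path}: missing required annotation columns {missing}")
    if raw["probe_id"].duplicated().any():
        dup = raw.loc[raw["probe_id"].duplicated(), "probe_id"].unique()[:5].tolist()
        raise FormatError(f"{path}: duplicate probe_id rows: {dup}")
    ann = pd.DataFrame(index=raw["probe_id"].to_numpy())
    ann["gene_symbol"] = raw["gene_symbol"].to_numpy()
    ann["chromosome"] = [normalize_chromosome(c) for c in raw["chromosome"]]
    ann["cytoband"] = raw["cytoband"].to_numpy() if "cytoband" in raw.columns else ""
    if "position" in raw.columns:
        pos = pd.to_numeric(raw["position"].replace("", np.nan), errors="raise")
        ann["position"] = pos.astype("Int64").to_numpy()
    else:
        ann["position"] = pd.array([pd.NA] * len(ann), dtype="Int64")
    if "promoter_class" in raw.columns:
        cls = raw["promoter_class"].str.strip().str.upper().replace("", "UNKNOWN")
        bad = ~cls.isin(PROMOTER_CLASSES)
        if bad.any():
            raise FormatError(
                f"{path}: unknown promoter_class {cls[bad].unique()[:3].tolist()}"
            )
        ann["promoter_class"] = cls.to_numpy()
    else:
        ann["promoter_class"] = "UNKNOWN"
    if "is_pcg_target" in raw.columns:
        ann["is_pcg_target"] = [_parse_bool(v, path, "is_pcg_target")
                                for v in raw["is_pcg_target"]]
    else:
        ann["is_pcg_target"] = False
    ann["is_gonosomal"] = ann["chromosome"].isin(["X", "Y"]).to_numpy()
    return ann


def _parse_bool(v, path, col) -> bool:
    s = str(v).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise ParseError(f"{path}: cannot parse boolean {v!r} in column {col}")


def write_annotation(ann: pd.DataFrame, path,
                     comments: Mapping[str, object] | None = None) -> None:
    out = ann.copy()
    out["is_pcg_target"] = out["is_pcg_target"].astype(int)
    out = out.drop(columns=["is_gonosomal"])  # derived on read
    write_tsv(out, path, comments, index_label="probe_id")


# ---------------------------------------------------------------------------
# sample sheet
# ---------------------------------------------------------------------------

def derive_risk(inss_stage: str, mycn: str) -> str:
    """Clinical risk label: HR = stage 4 with MYCN amplification, LR =
    stage 1-3 without it; everything else is "other"."""
    stage = str(inss_stage)
    if stage == "4" and mycn == "amplified":
        return "HR"
    if stage in ("1", "2", "3") and mycn == "non_amplified":
        return "LR"
    return "other"


def read_sample_sheet(path, allow_other: bool = False) -> pd.DataFrame:
    """Read a sample sheet and derive the HR/LR risk label.

    Groups must be one of NB/GN/GNB/FB/AG (the neuroblastic tumor
    spectrum plus the two normal reference tissues); with
    ``allow_other=True`` unknown labels pass through unchanged.
    """
    raw = _read_table(path)
    required = ("sample_id", "group", "inss_stage", "mycn", "age_months")
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise FormatError(f"{path}: missing required sample-sheet columns {missing}")
    if raw["sample_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate sample_id rows")
    groups = raw["group"].str.strip()
    unknown = ~groups.isin(GROUPS)
    if unknown.any() and not allow_other:
        raise FormatError(
            f"{path}: unknown group token {groups[unknown].unique()[:3].tolist()}"
        )
    stage = raw["inss_stage"].str.strip().str.upper().replace("", "NA")
    bad_stage = ~stage.isin(INSS_STAGES)
    if bad_stage.any():
        raise FormatError(
            f"{path}: unknown INSS stage {stage[bad_stage].unique()[:3].tolist()}"
        )
    mycn = raw["mycn"].str.strip().replace("", "undetermined")
    bad_mycn = ~mycn.isin(MYCN_STATUS)
    if bad_mycn.any():
        raise FormatError(
            f"{path}: unknown MYCN status {mycn[bad_mycn].unique()[:3].tolist()}"
        )
    age = pd.to_numeric(raw["age_months"].replace("", np.nan), errors="coerce")
    if (age < 0).any():
        raise FormatError(f"{path}: negative age_months")
    sheet = pd.DataFrame(index=raw["sample_id"].to_numpy())
    sheet["group"] = groups.to_numpy()
    sheet["inss_stage"] = stage.to_numpy()
    sheet["mycn"] = mycn.to_numpy()
    sheet["age_months"] = age.to_numpy(dtype=float)
    sheet["risk"] = [derive_risk(s, m) for s, m in zip(sheet["inss_stage"], sheet["mycn"])]
    return sheet


def write_sample_sheet(sheet: pd.DataFrame, path,
                       comments: Mapping[str, object] | None = None) -> None:
    out = sheet.drop(columns=["risk"])  # derived on read
    write_tsv(out, path, comments, index_label="sample_id")
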