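"""Reading, writing and validation of every table the pipeline touches.

Four tables move through the pipeline:

* long protein table — tidy longitudinal measurements, one row per
  (patient, sample, aptamer) with a positive RFU readout and the sampling
  time in years since the baseline visit;
* aptamer annotation — one row per aptamer reagent with its protein
  target, human/validation flags and binding affinity (dissociation
  constant Kd, lower = tighter binding);
* clinical table — one row per patient with typed covariates;
* outcome table — one row per patient with time-to-first-event and an
  event indicator.

All text output is TSV with '.' decimals, UTF-8 and LF line endings so
that repeated runs are byte-identical.  A minimal read-only dialect of
the SomaLogic ADAT format is supported for ingesting aptamer matrices.
"""

from __future__ import annotations

import hashlib
import json

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ParseError",
    "LONG_COLUMNS",
    "ANNOTATION_COLUMNS",
    "read_long_protein_table",
    "write_long_protein_table",
    "validate_long_protein_table",
    "read_annotation",
    "write_annotation",
    "read_clinical",
    "write_clinical",
    "read_outcomes",
    "write_outcomes",
    "read_adat",
    "write_report",
    "validate_manifest",
    "ClinicalTable",
]

LONG_COLUMNS = ["patient_id", "sample_id", "time_years", "seq_id", "rfu"]
ANNOTATION_COLUMNS = ["seq_id", "target_id", "is_human", "is_validated", "affinity_kd"]


class ParseError(ValueError):
    """A table failed structural validation; the message names the row."""


@dataclass
class ClinicalTable:
    """Per-patient covariates plus a declared type for each column.

    ``types`` maps column name -> ``"numeric" | "binary" | "categorical"``.
    """

    data: pd.DataFrame
    types: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if "patient_id" not in self.data.columns:
            raise ParseError("clinical table lacks a patient_id column")
        if self.data["patient_id"].duplicated().any():
            dup = self.data["patient_id"][self.data["patient_id"].duplicated()].iloc[0]
            raise ParseError(f"clinical table has duplicate patient_id {dup!r}")
        for name, kind in self.types.items():
            if kind not in ("numeric", "binary", "categorical"):
                raise ParseError(f"unknown declared type {kind!r} for {name!r}")
            if kind == "binary":
                vals = set(pd.unique(self.data[name].dropna()))
                if not vals <= {0, 1, True, False}:
                    raise ParseError(f"binary column {name!r} holds values outside 0/1")

    @property
    def variables(self) -> list[str]:
        return [c for c in self.data.columns if c != "patient_id"]


# ---------------------------------------------------------------------------
# TSV primitives

def _write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    # %.12g keeps full float precision while writing integers without '.0'
    text = df.to_csv(sep="\t", index=False, float_format="%.12g", lineterminator="\n")
    Path(path).write_bytes(text.encode("utf-8"))


def _read_tsv(path: str | Path) -> pd.DataFrame:
    text = Path(path).read_text(encoding="utf-8")
    if "," in text.split("\n", 1)[0] and "\t" not in text.split("\n", 1)[0]:
        sep = ","
    else:
        sep = "\t"
    from io import StringIO

    return pd.read_csv(StringIO(text), sep=sep)


# ---------------------------------------------------------------------------
# long protein table

def validate_long_protein_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and canonicalize a long protein table.

    Rows are sorted by (patient_id, time_years, seq_id).  Raises
    :class:`ParseError` naming the first offending row (1-based, counting
    the header as row 1) on: missing column, non-positive RFU, duplicate
    (patient, sample, aptamer) key, or a patient without a unique
    baseline (time 0) sample.
    """
    missing = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"long protein table missing column(s) {missing}")
    df = df[LONG_COLUMNS].copy()
    df["time_years"] = pd.to_numeric(df["time_years"]).astype(float)
    df["rfu"] = pd.to_numeric(df["rfu"]).astype(float)
    if (df["time_years"] < 0).any():
        row = int(np.flatnonzero(df["time_years"].to_numpy() < 0)[0])
        raise ParseError(f"negative time_years at data row {row + 2}")
    bad = df["rfu"].to_numpy() <= 0
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ParseError(f"non-positive rfu {df['rfu'].iloc[row]} at data row {row + 2}")
    dup = df.duplicated(subset=["patient_id", "sample_id", "seq_id"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise ParseError(f"duplicate (patient, sample, aptamer) key at data row {row + 2}")
    base = df[df["time_years"] == 0].groupby("patient_id", observed=True)["sample_id"].nunique()
    all_patients = df["patient_id"].unique()
    for pid in all_patients:
        n0 = int(base.get(pid, 0))
        if n0 != 1:
            raise ParseError(
                f"patient {pid!r} has {n0} baseline (time 0) samples; exactly one required"
            )
    return df.sort_values(["patient_id", "time_years", "seq_id"], kind="mergesort").reset_index(
        drop=True
    )


def read_long_protein_table(path: str | Path) -> pd.DataFrame:
    return validate_long_protein_table(_read_tsv(path))


def write_long_protein_table(df: pd.DataFrame, path: str | Path) -> None:
    _write_tsv(validate_long_protein_table(df), path)


# ---------------------------------------------------------------------------
# annotation / clinical / outcomes

def validate_annotation(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"annotation missing column(s) {missing}")
    df = df[ANNOTATION_COLUMNS].copy()
    if df["seq_id"].duplicated().any():
        dup = df["seq_id"][df["seq_id"].duplicated()].iloc[0]
        raise ParseError(f"annotation has duplicate seq_id {dup!r}")
    df["is_human"] = df["is_human"].astype(bool)
    df["is_validated"] = df["is_validated"].astype(bool)
    df["affinity_kd"] = pd.to_numeric(df["affinity_kd"])
    if (df["affinity_kd"] <= 0).any():
        row = int(np.flatnonzero(df["affinity_kd"].to_numpy() <= 0)[0])
        raise ParseError(f"non-positive affinity_kd at data row {row + 2}")
    return df.sort_values("seq_id", kind="mergesort").reset_index(drop=True)


def read_annotation(path: str | Path) -> pd.DataFrame:
    return validate_annotation(_read_tsv(path))


def write_annotation(df: pd.DataFrame, path: str | Path) -> None:
    _write_tsv(validate_annotation(df), path)


def read_clinical(path: str | Path, types: dict[str, str] | None = None) -> ClinicalTable:
    df = _read_tsv(path)
    if types is None:
        types = {}
        for c in df.columns:
            if c == "patient_id":
                continue
            vals = set(pd.unique(df[c].dropna()))
            if vals <= {0, 1}:
                types[c] = "binary"
            elif pd.api.types.is_numeric_dtype(df[c]):
                types[c] = "numeric"
            else:
                types[c] = "categorical"
    return ClinicalTable(df, types)


def write_clinical(table: ClinicalTable, path: str | Path) -> None:
    _write_tsv(table.data, path)


def validate_outcomes(df: pd.DataFrame) -> pd.DataFrame:
    for c in ("patient_id", "time_to_event_years", "event"):
        if c not in df.columns:
            raise ParseError(f"outcome table missing column {c!r}")
    df = df[["patient_id", "time_to_event_years", "event"]].copy()
    if df["patient_id"].duplicated().any():
        raise ParseError("outcome table has duplicate patient rows")
    df["time_to_event_years"] = pd.to_numeric(df["time_to_event_years"])
    if (df["time_to_event_years"] <= 0).any():
        row = int(np.flatnonzero(df["time_to_event_years"].to_numpy() <= 0)[0])
        raise ParseError(f"non-positive time_to_event_years at data row {row + 2}")
    df["event"] = df["event"].astype(int).astype(bool)
    return df.sort_values("patient_id", kind="mergesort").reset_index(drop=True)


def read_outcomes(path: str | Path) -> pd.DataFrame:
    return validate_outcomes(_read_tsv(path))


def write_outcomes(df: pd.DataFrame, path: str | Path) -> None:
    out = validate_outcomes(df).copy()
    out["event"] = out["event"].astype(int)
    _write_tsv(out, path)


# ---------------------------------------------------------------------------
# minimal ADAT dialect
#
# Layout (tab-delimited, section sentinels in column 1):
#
#   ^HEADER
#   !AdatId<TAB>...                    free-form key/value lines
#   ^COL_DATA
#   !Name<TAB>SeqId<TAB>TargetId<TAB>IsHuman<TAB>IsValidated<TAB>AffinityKd
#   ^ROW_DATA
#   !Name<TAB>PatientId<TAB>SampleId<TAB>TimeYears
#   ^TABLE_BEGIN
#   <empty row-meta cells><TAB>SeqId<TAB>sq1<TAB>sq2 ...      one line per
#   <empty row-meta cells><TAB>TargetId<TAB>...               COL_DATA field
#   ...
#   PatientId<TAB>SampleId<TAB>TimeYears                      row header
#   P1<TAB>P1-V00<TAB>0.0<TAB>rfu<TAB>rfu ...                 one line/sample

_ADAT_COL_FIELDS = {"SeqId": "seq_id", "TargetId": "target_id", "IsHuman": "is_human",
                    "IsValidated": "is_validated", "AffinityKd": "affinity_kd"}
_ADAT_ROW_FIELDS = {"PatientId": "patient_id", "SampleId": "sample_id",
                    "TimeYears": "time_years"}


def read_adat(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Parse the minimal ADAT dialect into (long protein table, annotation)."""
    lines = Path(path).read_text(encoding="utf-8").split("\n")
    sections: dict[str, int] = {}
    for i, line in enumerate(lines):
        head = line.split("\t", 1)[0]
        if head.startswith("^"):
            sections[head] = i
    for sentinel in ("^HEADER", "^COL_DATA", "^ROW_DATA", "^TABLE_BEGIN"):
        if sentinel not in sections:
            raise ParseError(f"ADAT file missing section sentinel {sentinel}")

    def _names(section: str) -> list[str]:
        i = sections[section] + 1
        while i < len(lines) and not lines[i].startswith("!Name"):
            i += 1
        if i >= len(lines):
            raise ParseError(f"ADAT section {section} lacks a !Name line")
        return lines[i].rstrip("\n").split("\t")[1:]

    col_fields = _names("^COL_DATA")
    row_fields = _names("^ROW_DATA")
    if "SeqId" not in col_fields:
        raise ParseError("ADAT column metadata lacks a SeqId field")
    for f in ("PatientId", "SampleId", "TimeYears"):
        if f not in row_fields:
            raise ParseError(f"ADAT row metadata lacks a {f} field")

    body = [ln for ln in lines[sections["^TABLE_BEGIN"] + 1:] if ln.strip("\t ")]
    n_row = len(row_fields)
    col_meta: dict[str, list[str]] = {}
    for j in range(len(col_fields)):
        cells = body[j].split("\t")
        # n_row empty padding cells, the field name, then one value per aptamer
        col_meta[cells[n_row]] = cells[n_row + 1:]
    n_aptamers = len(col_meta["SeqId"])
    for name, vals in col_meta.items():
        if len(vals) != n_aptamers:
            raise ParseError(f"ragged ADAT column-metadata line for {name!r}")
    header = body[len(col_fields)].split("\t")
    if header[:n_row] != row_fields:
        raise ParseError("ADAT row header does not match ^ROW_DATA field names")

    rows = []
    for ln in body[len(col_fields) + 1:]:
        cells = ln.split("\t")
        if len(cells) != n_row + n_aptamers:
            raise ParseError(
                f"ragged ADAT data row: expected {n_row + n_aptamers} cells, got {len(cells)}"
            )
        rows.append(cells)

    meta = pd.DataFrame([r[:n_row] for r in rows], columns=row_fields)
    rfu = np.array([[float(x) for x in r[n_row:]] for r in rows])
    long = pd.DataFrame(
        {
            "patient_id": np.repeat(meta["PatientId"].to_numpy(), n_aptamers),
            "sample_id": np.repeat(meta["SampleId"].to_numpy(), n_aptamers),
            "time_years": np.repeat(meta["TimeYears"].astype(float).to_numpy(), n_aptamers),
            "seq_id": np.tile(np.asarray(col_meta["SeqId"]), len(rows)),
            "rfu": rfu.ravel(),
        }
    )
    annot = pd.DataFrame(
        {
            "seq_id": col_meta["SeqId"],
            "target_id": col_meta.get("TargetId", col_meta["SeqId"]),
            "is_human": [x in ("1", "true", "True") for x in
                         col_meta.get("IsHuman", ["1"] * n_aptamers)],
            "is_validated": [x in ("1", "true", "True") for x in
                             col_meta.get("IsValidated", ["1"] * n_aptamers)],
            "affinity_kd": [float(x) for x in col_meta.get("AffinityKd", ["1"] * n_aptamers)],
        }
    )
    return validate_long_protein_table(long), validate_annotation(annot)


# ---------------------------------------------------------------------------
# report writer + manifest

def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_report(bundle: dict, directory: str | Path) -> dict[str, str]:
    """Write the result tables of a run plus a JSON manifest.

    ``bundle`` maps logical names to DataFrames (written as
    ``<name>.tsv``); the special key ``"manifest"`` holds a JSON-able
    dict recording config, seeds and warnings.  Returns the mapping of
    written file names to sha256 checksums.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    checksums: dict[str, str] = {}
    for name, obj in sorted(bundle.items()):
        if name == "manifest":
            continue
        if not isinstance(obj, pd.DataFrame):
            raise TypeError(f"bundle entry {name!r} is not a DataFrame")
        path = directory / f"{name}.tsv"
        _write_tsv(obj, path)
        checksums[path.name] = _checksum(path)
    manifest = dict(bundle.get("manifest", {}))
    manifest["files"] = checksums
    validate_manifest(manifest)
    mpath = directory / "manifest.json"
    mpath.write_bytes(
        (json.dumps(manifest, indent=2, sort_keys=True, default=_json_default) + "\n").encode()
    )
    checksums["manifest.json"] = _checksum(mpath)
    return checksums


def _json_default(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")


def _schema_path() -> Path:
    return Path(__file__).with_name("manifest_schema.json")


def _check_schema(obj, schema, where: str) -> list[str]:
    """Tiny JSON-schema checker for the keyword subset the manifest schema uses
    (type, required, properties, items, additionalProperties pass-through)."""
    errors: list[str] = []
    t = schema.get("type")
    type_map = {"object": dict, "array": list, "string": str, "boolean": bool}
    if t is not None:
        if t == "number":
            ok = isinstance(obj, (int, float)) and not isinstance(obj, bool)
        elif t == "integer":
            ok = isinstance(obj, int) and not isinstance(obj, bool)
        else:
            ok = isinstance(obj, type_map[t])
        if not ok:
            errors.append(f"{where}: expected type {t}, got {type(obj).__name__}")
            return errors
    for key in schema.get("required", []):
        if key not in obj:
            errors.append(f"{where}: missing required key {key!r}")
    for key, sub in schema.get("properties", {}).items():
        if isinstance(obj, dict) and key in obj:
            errors.extend(_check_schema(obj[key], sub, f"{where}.{key}"))
    if "items" in schema and isinstance(obj, list):
        for i, item in enumerate(obj):
            errors.extend(_check_schema(item, schema["items"], f"{where}[{i}]"))
    return errors


def validate_manifest(manifest: dict) -> None:
    """Validate a run manifest against the bundled JSON schema."""
    schema = json.loads(_schema_path().read_text())
    # round-trip through JSON so numpy scalars are checked as their JSON form
    obj = json.loads(json.dumps(manifest, default=_json_default))
    errors = _check_schema(obj, schema, "manifest")
    if errors:
        raise ParseError("manifest schema violation: " + "; ".join(errors))
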