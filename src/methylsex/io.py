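"""Readers and writers for intensity tables, beta matrices, annotations,
sample sheets, the serialized model, and prediction reports.

All formats are delimited or structured plain text. Readers reject
structural corruption (ragged rows, duplicate identifiers) instead of
repairing it silently; writers are deterministic, and the model file
preserves full float precision so a write/read round-trip is exact.
"""

from __future__ import annotations

import ast
import io as _io
import warnings
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .datamodel import (
    BetaMatrix,
    DataError,
    IntensityMatrix,
    ProbeAnnotation,
    SampleSheet,
    SexModel,
    SexPrediction,
)

MODEL_MAGIC = "#%methylsex-model"
MODEL_SCHEMA_VERSION = 1

#: tolerance for clamping beta values that sit just outside [0, 1]
BETA_CLAMP_TOL = 1e-6

_MISSING_TOKENS = {"", "na", "n/a", "nan", "null", "none", "."}


def _detect_sep(path: Union[str, Path], override: Optional[str]) -> str:
    """Pick the delimiter among tab/comma/semicolon from the header line."""
    if override is not None:
        return override
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    counts = {sep: header.count(sep) for sep in ("\t", ",", ";")}
    sep = max(counts, key=counts.get)  # type: ignore[arg-type]
    if counts[sep] == 0:
        raise DataError(f"could not detect a delimiter in {path}")
    return sep


def _read_table(path: Union[str, Path], sep: Optional[str]) -> pd.DataFrame:
    sep = _detect_sep(path, sep)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise DataError(f"empty table: {path}")
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise DataError(f"duplicate probe IDs in {path}: {dups[:5]}")
    if df.columns.duplicated().any():
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise DataError(f"duplicate column names in {path}: {dups[:5]}")
    return df


def _parse_cell(v: str) -> float:
    try:
        return float(v)
    except ValueError:
        return float("nan")


def _to_numeric(df: pd.DataFrame) -> np.ndarray:
    """Convert string cells to floats; unparseable/missing tokens become NaN.

    Uses Python's correctly-rounded float parser cell by cell so that a
    value written with ``repr`` reads back bit-identical.
    """
    raw = df.to_numpy(dtype=object)
    cleaned = np.empty(raw.shape, dtype=float)
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            v = str(raw[i, j]).strip()
            cleaned[i, j] = (
                float("nan") if v.lower() in _MISSING_TOKENS else _parse_cell(v)
            )
    return cleaned


# ---------------------------------------------------------------------------
# intensity tables

def read_intensity_table(
    path: Union[str, Path],
    dialect: str = "paired-columns",
    unmethylated_path: Optional[Union[str, Path]] = None,
    sep: Optional[str] = None,
) -> IntensityMatrix:
    """Read methylated/unmethylated signal intensities from text tables.

    Two dialects are supported:

    ``paired-columns``
        One file whose columns come in ``"<sample> Methylated"`` /
        ``"<sample> Unmethylated"`` pairs (suffix matching is
        case-insensitive; ``.``/``_`` separators are accepted).
    ``split-files``
        Two files (``path`` = methylated, ``unmethylated_path`` =
        unmethylated) with identical sample columns; rows are aligned by
        probe ID, not position.

    Non-numeric cells become missing entries.
    """
    if dialect == "paired-columns":
        df = _read_table(path, sep)
        m_cols: Dict[str, str] = {}
        u_cols: Dict[str, str] = {}
        orphans = []
        for col in df.columns:
            name = col.strip()
            low = name.lower()
            if low.endswith("unmethylated"):
                sample = name[: -len("unmethylated")].rstrip(" ._-")
                u_cols[sample] = col
            elif low.endswith("methylated"):
                sample = name[: -len("methylated")].rstrip(" ._-")
                m_cols[sample] = col
            else:
                orphans.append(name)
        if orphans:
            raise DataError(
                f"columns without a Methylated/Unmethylated suffix: {orphans[:5]}"
            )
        unpaired = sorted(set(m_cols) ^ set(u_cols))
        if unpaired:
            raise DataError(f"samples with unpaired M/U columns: {unpaired[:5]}")
        samples = [s for s in (c for c in m_cols) if s in u_cols]
        m = _to_numeric(df[[m_cols[s] for s in samples]])
        u = _to_numeric(df[[u_cols[s] for s in samples]])
        return IntensityMatrix(list(df.index), samples, m, u)

    if dialect == "split-files":
        if unmethylated_path is None:
            raise DataError("split-files dialect requires unmethylated_path")
        dfm = _read_table(path, sep)
        dfu = _read_table(unmethylated_path, sep)
        if list(dfm.columns) != list(dfu.columns):
            raise DataError(
                "sample columns differ between methylated and unmethylated files"
            )
        shared = [p for p in dfm.index if p in set(dfu.index)]
        if not shared:
            raise DataError("no probe IDs shared between the two intensity files")
        dropped = (len(dfm.index) - len(shared)) + (len(dfu.index) - len(shared))
        if dropped:
            warnings.warn(
                f"{dropped} probe rows present in only one intensity file were dropped",
                stacklevel=2,
            )
        m = _to_numeric(dfm.loc[shared])
        u = _to_numeric(dfu.loc[shared])
        return IntensityMatrix(shared, list(dfm.columns), m, u)

    raise DataError(f"unknown intensity dialect {dialect!r}")


def write_intensity_table(intens: IntensityMatrix, path: Union[str, Path]) -> None:
    """Write an intensity matrix in the paired-columns dialect (TSV)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        cols = []
        for s in intens.sample_ids:
            cols.append(f"{s} Methylated")
            cols.append(f"{s} Unmethylated")
        fh.write("probe_id\t" + "\t".join(cols) + "\n")
        for i, p in enumerate(intens.probe_ids):
            cells = []
            for j in range(len(intens.sample_ids)):
                if intens.missing_mask[i, j]:
                    cells.extend(("NA", "NA"))
                else:
                    cells.append(repr(float(intens.methylated[i, j])))
                    cells.append(repr(float(intens.unmethylated[i, j])))
            fh.write(p + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# beta matrices

def read_beta_matrix(path: Union[str, Path], sep: Optional[str] = None) -> BetaMatrix:
    """Read a probes x samples beta-value table.

    Values outside [0, 1] by more than ``BETA_CLAMP_TOL`` raise an error
    naming the offending cell (the table is probably M-values or raw
    intensities); values within the tolerance are clamped to the boundary
    with a warning. Non-numeric cells become missing.
    """
    df = _read_table(path, sep)
    values = _to_numeric(df)
    missing = ~np.isfinite(values)
    obs = ~missing
    out_low = obs & (values < -BETA_CLAMP_TOL)
    out_high = obs & (values > 1 + BETA_CLAMP_TOL)
    if out_low.any() or out_high.any():
        i, j = np.argwhere(out_low | out_high)[0]
        raise DataError(
            f"value {values[i, j]!r} at probe {df.index[i]!r}, sample "
            f"{df.columns[j]!r} is outside [0, 1]; this does not look like a "
            "beta-value matrix (M-values or intensities misfed?)"
        )
    clamp = obs & ((values < 0) | (values > 1))
    if clamp.any():
        warnings.warn(
            f"{int(clamp.sum())} beta values within {BETA_CLAMP_TOL} of the "
            "[0, 1] boundary were clamped",
            stacklevel=2,
        )
        values = np.clip(values, 0.0, 1.0)
    # the container requires values strictly below 1; nudge exact 1.0 down
    # by one ulp (the +100 offset in the beta formula makes true 1.0
    # unattainable from finite intensities)
    exact_one = obs & (values >= 1.0)
    values[exact_one] = np.nextafter(1.0, 0.0)
    values[missing] = np.nan
    return BetaMatrix(list(df.index), list(df.columns), values, missing)


def write_beta_matrix(beta: BetaMatrix, path: Union[str, Path]) -> None:
    """Write a beta matrix as TSV with full float precision; missing -> NA."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("probe_id\t" + "\t".join(beta.sample_ids) + "\n")
        for i, p in enumerate(beta.probe_ids):
            cells = [
                "NA" if beta.missing_mask[i, j] else repr(float(beta.values[i, j]))
                for j in range(len(beta.sample_ids))
            ]
            fh.write(p + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# annotation and sample sheets

def read_annotation(path: Union[str, Path], sep: Optional[str] = None) -> ProbeAnnotation:
    """Read a probe -> chromosome table (first two columns are used)."""
    sep_ = _detect_sep(path, sep)
    df = pd.read_csv(path, sep=sep_, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise DataError(f"annotation file {path} needs probe and chromosome columns")
    probes = df.iloc[:, 0].str.strip()
    if probes.duplicated().any():
        raise DataError(
            f"duplicate probe IDs in annotation: "
            f"{probes[probes.duplicated()].unique().tolist()[:5]}"
        )
    return ProbeAnnotation(dict(zip(probes, df.iloc[:, 1].str.strip())))


def write_annotation(annotation: ProbeAnnotation, path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("probe_id,chromosome\n")
        for p, c in annotation.chromosome.items():
            fh.write(f"{p},{c}\n")


def read_sample_sheet(path: Union[str, Path], sep: Optional[str] = None) -> SampleSheet:
    """Read a sample sheet; a second column, if present, is the labelled sex."""
    try:
        sep_ = _detect_sep(path, sep)
    except DataError:
        sep_ = ","  # single-column sheet: IDs only, no labels
    df = pd.read_csv(path, sep=sep_, dtype=str, keep_default_na=False)
    if df.shape[1] == 0:
        raise DataError(f"empty sample sheet: {path}")
    ids = df.iloc[:, 0].str.strip().tolist()
    sexes = df.iloc[:, 1].tolist() if df.shape[1] >= 2 else None
    return SampleSheet(ids, sexes)


def write_sample_sheet(sheet: SampleSheet, path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("sample_id,sex\n")
        for s, lab in zip(sheet.sample_ids, sheet.labelled_sex):
            fh.write(f"{s},{'' if lab == 'unknown' else lab}\n")


# ---------------------------------------------------------------------------
# model serialization

def write_model(model: SexModel, path: Union[str, Path]) -> None:
    """Serialize a trained model as versioned, human-readable text.

    Floats are written with ``repr`` (shortest exact round-trip), so
    ``read_model(write_model(m)) == m`` bit-for-bit.
    """
    model.validate()
    buf = _io.StringIO()
    buf.write(f"{MODEL_MAGIC}\t{MODEL_SCHEMA_VERSION}\n")
    buf.write("[metadata]\n")
    for key in sorted(model.metadata):
        buf.write(f"{key}\t{model.metadata[key]!r}\n")
    for name, sign, ids, center, load in (
        ("x_axis", model.x_orientation_sign, model.x_probe_ids, model.x_center, model.x_loadings),
        ("y_axis", model.y_orientation_sign, model.y_probe_ids, model.y_center, model.y_loadings),
    ):
        buf.write(f"[{name}]\n")
        buf.write(f"orientation_sign\t{sign:+d}\n")
        buf.write("probe_id\tchromosome\tcenter\tloading\n")
        chrom = "X" if name == "x_axis" else "Y"
        for p, c, w in zip(ids, center, load):
            buf.write(f"{p}\t{chrom}\t{float(c)!r}\t{float(w)!r}\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8", newline="\n")


def read_model(path: Union[str, Path]) -> SexModel:
    """Read a serialized model, validating schema version and invariants."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines or not lines[0].startswith(MODEL_MAGIC):
        raise DataError(f"{path} is not a methylsex model file")
    try:
        version = int(lines[0].split("\t")[1])
    except (IndexError, ValueError) as exc:
        raise DataError(f"model file {path} has no schema version") from exc
    if version != MODEL_SCHEMA_VERSION:
        raise DataError(
            f"model schema version mismatch: file has {version}, "
            f"this package reads {MODEL_SCHEMA_VERSION}"
        )
    sections: Dict[str, List[str]] = {}
    current: Optional[str] = None
    for line in lines[1:]:
        if not line.strip():
            continue
        if line.startswith("[") and line.rstrip().endswith("]"):
            current = line.strip()[1:-1]
            sections[current] = []
        elif current is None:
            raise DataError(f"model file {path}: content before first section")
        else:
            sections[current].append(line)

    metadata: Dict[str, object] = {}
    for line in sections.get("metadata", []):
        key, _, raw = line.partition("\t")
        try:
            metadata[key] = ast.literal_eval(raw)
        except (ValueError, SyntaxError):
            metadata[key] = raw

    def parse_axis(name: str):
        if name not in sections:
            raise DataError(f"model incomplete: missing [{name}] section")
        rows = sections[name]
        if len(rows) < 3:
            raise DataError(f"model incomplete: [{name}] has no probe records")
        sign_key, _, sign_val = rows[0].partition("\t")
        if sign_key != "orientation_sign":
            raise DataError(f"[{name}] must start with orientation_sign")
        ids, centers, loads = [], [], []
        for row in rows[2:]:
            fields = row.split("\t")
            if len(fields) != 4:
                raise DataError(f"malformed probe record in [{name}]: {row!r}")
            ids.append(fields[0])
            centers.append(float(fields[2]))
            loads.append(float(fields[3]))
        return int(sign_val), ids, np.array(centers), np.array(loads)

    x_sign, x_ids, x_center, x_load = parse_axis("x_axis")
    y_sign, y_ids, y_center, y_load = parse_axis("y_axis")
    return SexModel(
        x_probe_ids=x_ids,
        y_probe_ids=y_ids,
        x_center=x_center,
        y_center=y_center,
        x_loadings=x_load,
        y_loadings=y_load,
        x_orientation_sign=x_sign,
        y_orientation_sign=y_sign,
        metadata=metadata,
    )


# ---------------------------------------------------------------------------
# predictions

def write_predictions(preds: Sequence[SexPrediction], path: Union[str, Path]) -> None:
    """Write one CSV row per sample; scores carry 9 significant digits."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(
            "sample_id,x_score,y_score,karyotype_call,predicted_sex,"
            "labelled_sex,label_mismatch,note\n"
        )
        for p in preds:
            mismatch = "" if p.label_mismatch is None else str(p.label_mismatch).lower()
            labelled = p.labelled_sex or ""
            fh.write(
                f"{p.sample_id},{p.x_score:.9g},{p.y_score:.9g},"
                f'"{p.karyotype_call}",{p.predicted_sex},{labelled},{mismatch},{p.note}\n'
            )


def read_predictions(path: Union[str, Path]) -> pd.DataFrame:
    """Read a predictions CSV back as a DataFrame (convenience for reports)."""
    return pd.read_csv(path, dtype={"sample_id": str})
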