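"""Plate-level data model: frame metadata, plate maps, and object tables.

Time-lapse experiments arrive as one gray-scale frame per (plate, well, hour),
with the coordinates encoded in the filename, plus a plate map (CSV) assigning
each well a cell line and an experimental condition (for example a fibronectin
concentration).  Per-object measurements are collected into a flat *object
table* keyed by (plate, well, hour, object_id), which can be round-tripped
through CSV or a single-file SQLite database with identical contents.
"""

from __future__ import annotations

import re
import sqlite3
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, JoinError, ParseError, SchemaError, ValidationError

#: Default filename layout for exported frames.
DEFAULT_FRAME_PATTERN = "{plate}_{well}_{hour}h"

#: Identity columns of an object table, in canonical order.
KEY_COLUMNS = ("plate", "well", "hour", "object_id")

#: Positional columns that follow the key.
POSITION_COLUMNS = ("centroid_row", "centroid_col")

#: Metadata columns appended by :func:`annotate_objects`.
ANNOTATION_COLUMNS = ("cell_line", "condition", "condition_value", "replicate_group")

_WELL_RE = re.compile(r"^[A-Za-z]+\d+$")


@dataclass(frozen=True)
class FrameMetadata:
    """Plate/well/hour coordinates of one acquired frame."""

    plate_id: str
    well_id: str
    hour: int
    path: str

    def __post_init__(self) -> None:
        if self.hour < 0:
            raise ValidationError(f"hour must be >= 0, got {self.hour}")
        if not _WELL_RE.match(self.well_id):
            raise ValidationError(
                f"well id {self.well_id!r} does not match letter(s)+digits"
            )


def _pattern_to_regex(pattern: str) -> re.Pattern:
    """Translate a ``{plate}_{well}_{hour}h``-style template to a regex."""
    for field in ("{plate}", "{well}", "{hour}"):
        if field not in pattern:
            raise ParseError(f"filename pattern {pattern!r} must contain {field}")
    out = ""
    pos = 0
    for m in re.finditer(r"\{(plate|well|hour)\}", pattern):
        out += re.escape(pattern[pos : m.start()])
        name = m.group(1)
        out += rf"(?P<{name}>\d+)" if name == "hour" else rf"(?P<{name}>[A-Za-z0-9]+)"
        pos = m.end()
    out += re.escape(pattern[pos:])
    return re.compile("^" + out + "$")


def parse_frame_metadata(path: str | Path, pattern: str = DEFAULT_FRAME_PATTERN) -> FrameMetadata:
    """Parse plate/well/hour from a frame filename.

    ``pattern`` is a template with ``{plate}``, ``{well}`` and ``{hour}``
    placeholders; it is matched against the file's stem, or against the full
    name when the template itself carries an extension.
    """
    path = Path(path)
    name = path.name if "." in pattern else path.stem
    m = _pattern_to_regex(pattern).match(name)
    if m is None:
        raise ParseError(
            f"filename {path.name!r} does not match pattern {pattern!r}"
        )
    return FrameMetadata(
        plate_id=m.group("plate"),
        well_id=m.group("well"),
        hour=int(m.group("hour")),
        path=str(path),
    )


def format_frame_name(
    plate: str, well: str, hour: int, pattern: str = DEFAULT_FRAME_PATTERN, ext: str = ".png"
) -> str:
    """Inverse of :func:`parse_frame_metadata`: build a frame filename."""
    stem = pattern.format(plate=plate, well=well, hour=f"{hour:02d}")
    return stem if "." in pattern else stem + ext


def find_frames(
    directory: str | Path, pattern: str = DEFAULT_FRAME_PATTERN,
    extensions: Sequence[str] = (".tif", ".tiff", ".png"),
) -> list[FrameMetadata]:
    """Discover frames under ``directory`` matching the filename template.

    Non-matching files are ignored; matches are sorted by (plate, well, hour).
    """
    frames = []
    for p in sorted(Path(directory).iterdir()):
        if p.suffix.lower() not in extensions:
            continue
        try:
            frames.append(parse_frame_metadata(p, pattern))
        except ParseError:
            continue
    frames.sort(key=lambda f: (f.plate_id, f.well_id, f.hour))
    return frames


# ---------------------------------------------------------------------------
# Plate map

PLATE_MAP_REQUIRED = ("plate", "well", "cell_line", "condition")


class PlateMap:
    """Well-to-metadata assignment for one or more plates.

    Wraps a DataFrame with columns plate, well, cell_line, condition and
    optionally condition_value (numeric) and replicate_group.  (plate, well)
    pairs are unique.
    """

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in PLATE_MAP_REQUIRED if c not in table.columns]
        if missing:
            raise SchemaError(f"plate map missing column(s): {', '.join(missing)}")
        dup = table.duplicated(subset=["plate", "well"])
        if dup.any():
            wells = table.loc[dup, ["plate", "well"]].apply(tuple, axis=1).tolist()
            raise ValidationError(f"duplicate plate/well entries: {wells}")
        table = table.copy()
        if "condition_value" not in table.columns:
            table["condition_value"] = _condition_values(table["condition"])
        else:
            table["condition_value"] = pd.to_numeric(table["condition_value"])
        by_label = table.groupby("condition")["condition_value"].nunique()
        if (by_label > 1).any():
            bad = by_label[by_label > 1].index.tolist()
            raise ValidationError(
                f"condition label(s) with more than one numeric value: {bad}"
            )
        if "replicate_group" not in table.columns:
            table["replicate_group"] = table["well"]
        self.table = table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def lookup(self, plate: str, well: str) -> pd.Series:
        hit = self.table[(self.table["plate"] == plate) & (self.table["well"] == well)]
        if hit.empty:
            raise KeyError((plate, well))
        return hit.iloc[0]


def _condition_values(labels: pd.Series) -> pd.Series:
    """Extract the numeric part of condition labels like ``FN25`` or ``5 ug/mL``."""
    def one(label: str) -> float:
        m = re.search(r"[-+]?\d*\.?\d+(?:[eE][-+]?\d+)?", str(label))
        if m is None:
            raise ValidationError(f"condition label {label!r} has no numeric value")
        return float(m.group(0))

    return labels.map(one)


def read_frame(path: str | Path) -> np.ndarray:
    """Load a gray-scale frame (8/16-bit TIFF or 8-bit PNG) as a 2-D array."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(str(path))
    else:
        from PIL import Image

        arr = np.asarray(Image.open(path).convert("L"))
    if arr.ndim == 3:  # collapse an accidental singleton/RGB axis
        arr = arr[..., 0] if arr.shape[-1] <= 4 else arr[0]
    return arr


def read_plate_map(path: str | Path) -> PlateMap:
    """Load a plate map CSV (header: plate,well,cell_line,condition,...)."""
    table = pd.read_csv(path, dtype={"plate": str, "well": str})
    return PlateMap(table)


def write_plate_map(plate_map: PlateMap, path: str | Path) -> None:
    plate_map.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Object table

def make_object_table(rows: pd.DataFrame | None, feature_columns: Sequence[str]) -> pd.DataFrame:
    """Return an object table with the canonical column order.

    ``rows`` may be None/empty; the result then has zero rows but the full
    header, so downstream writers always emit a schema.
    """
    columns = list(KEY_COLUMNS) + list(POSITION_COLUMNS) + list(feature_columns)
    if rows is None or len(rows) == 0:
        return pd.DataFrame({c: pd.Series(dtype=float) for c in columns}).astype(
            {"plate": str, "well": str, "hour": int, "object_id": int}
        )[columns]
    missing = [c for c in columns if c not in rows.columns]
    if missing:
        raise SchemaError(f"object table missing column(s): {', '.join(missing)}")
    out = rows[columns].copy()
    out["hour"] = out["hour"].astype(int)
    out["object_id"] = out["object_id"].astype(int)
    dup = out.duplicated(subset=list(KEY_COLUMNS))
    if dup.any():
        raise ValidationError(
            f"duplicate (plate, well, hour, object_id) keys at rows {np.nonzero(dup.to_numpy())[0].tolist()}"
        )
    return out.reset_index(drop=True)


def feature_columns_of(objects: pd.DataFrame) -> list[str]:
    """Columns of an object table that hold measured features."""
    reserved = set(KEY_COLUMNS) | set(POSITION_COLUMNS) | set(ANNOTATION_COLUMNS)
    return [c for c in objects.columns if c not in reserved]


def annotate_objects(
    objects: pd.DataFrame, plate_map: PlateMap, strict: bool = True
) -> pd.DataFrame:
    """Append cell_line/condition metadata to an object table.

    Joins on (plate, well).  Under ``strict`` every object well must appear in
    the plate map; otherwise unmapped rows keep missing metadata.  Feature
    values and row count are never altered.
    """
    meta = plate_map.table[["plate", "well", *ANNOTATION_COLUMNS]]
    merged = objects.merge(meta, on=["plate", "well"], how="left", validate="m:1")
    if strict and len(objects):
        orphan = merged["cell_line"].isna()
        if orphan.any():
            wells = sorted(
                set(map(tuple, merged.loc[orphan, ["plate", "well"]].to_numpy()))
            )
            raise JoinError(f"wells absent from plate map: {wells}")
    return merged


_TEXT_COLUMNS = {"plate", "well", "cell_line", "condition", "replicate_group"}
_INT_COLUMNS = {"hour", "object_id"}


def _coerce_object_table(table: pd.DataFrame, source: str) -> pd.DataFrame:
    for col in table.columns:
        if col in _TEXT_COLUMNS:
            table[col] = table[col].astype(str)
        elif col in _INT_COLUMNS:
            try:
                table[col] = table[col].astype(int)
            except (ValueError, TypeError) as exc:
                raise FormatError(f"{source}: non-integer value in column {col!r}: {exc}")
        else:
            coerced = pd.to_numeric(table[col], errors="coerce")
            bad = coerced.isna() & table[col].notna() & (table[col].astype(str).str.strip() != "")
            # values that were literal NaN markers are fine; anything else is not
            bad &= ~table[col].astype(str).str.lower().isin(["nan", "none", ""])
            if bad.any():
                row = int(np.nonzero(bad.to_numpy())[0][0])
                raise FormatError(
                    f"{source}: non-numeric value {table[col].iloc[row]!r} "
                    f"in feature column {col!r} at data row {row}"
                )
            table[col] = coerced.astype(float)
    return table


def write_object_table(
    objects: pd.DataFrame, dest: str | Path, table_prefix: str = "per"
) -> None:
    """Persist an object table to CSV or a single-file SQLite database.

    The backend is chosen by extension: ``.csv`` writes text, anything else
    (``.db``, ``.sqlite``) writes an SQLite file with table
    ``<table_prefix>_object``.  Floats are written with 17 significant digits
    so that read(write(T)) reproduces T bit for bit.
    """
    dest = Path(dest)
    if dest.suffix.lower() == ".csv":
        objects.to_csv(dest, index=False, float_format="%.17g")
    else:
        with sqlite3.connect(dest) as con:
            objects.to_sql(f"{table_prefix}_object", con, index=False, if_exists="replace")


def read_object_table(src: str | Path, table_prefix: str = "per") -> pd.DataFrame:
    """Load an object table written by :func:`write_object_table`."""
    src = Path(src)
    if src.suffix.lower() == ".csv":
        try:
            table = pd.read_csv(src, dtype={"plate": str, "well": str},
                                float_precision="round_trip")
        except pd.errors.ParserError as exc:
            raise FormatError(f"{src}: {exc}")
    else:
        with sqlite3.connect(src) as con:
            table = pd.read_sql(f"SELECT * FROM {table_prefix}_object", con)
    missing = [c for c in KEY_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"{src}: object table missing key column(s) {missing}")
    return _coerce_object_table(table, str(src))


def write_summary_table(summary: pd.DataFrame, dest: str | Path) -> None:
    """Persist a trend summary (one row per group x feature) as CSV."""
    summary.to_csv(dest, index=False, float_format="%.17g")


def read_summary_table(src: str | Path) -> pd.DataFrame:
    return pd.read_csv(src)
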