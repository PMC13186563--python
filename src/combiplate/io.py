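"""Readers and writers for the package's tidy CSV schemas.

Canonical interchange formats (long/tidy, one observation per row):

layout
    ``plate,row_letter,col_local,well_name,col_global,consortium_binary,
    consortium_int,richness``
spectra measurements
    ``sample,replicate,wavelength_nm,absorbance`` — or plate-reader export
    style with ``plate,well`` columns joined against a layout file
function table
    ``consortium_binary,replicate,value``

Column names can be remapped via ``colmap`` (canonical -> actual) when
ingesting third-party exports.  Floating-point output is rendered with six
significant digits; all internal computation stays at full precision.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .codec import PlateLayout, SpeciesLibrary
from .errors import ValidationError

__all__ = [
    "FLOAT_FORMAT",
    "write_csv",
    "read_layout",
    "layout_code_lookup",
    "read_function_table",
    "read_spectra_table",
    "write_run_metadata",
    "file_sha256",
]

FLOAT_FORMAT = "%.6g"


def write_csv(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return path


#: columns holding binary consortium strings: leading zeros must survive
_CODE_COLUMNS = ("consortium_binary", "sample", "subset_binary", "background")


def _read_csv(path, colmap: dict[str, str] | None = None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"input file not found: {path}")
    code_cols = set(_CODE_COLUMNS) | {
        (colmap or {}).get(c, c) for c in _CODE_COLUMNS
    }
    try:
        df = pd.read_csv(path, dtype={c: str for c in code_cols})
    except pd.errors.EmptyDataError:
        raise ValidationError(f"input file is empty: {path}") from None
    if df.empty:
        raise ValidationError(f"input file has no data rows: {path}")
    return df


def _apply_colmap(df: pd.DataFrame, colmap: dict[str, str] | None) -> pd.DataFrame:
    if colmap:
        df = df.rename(columns={v: k for k, v in colmap.items()})
    return df


def _require(df: pd.DataFrame, columns: list[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(
            f"{what} is missing columns {missing}; present: {list(df.columns)} "
            "(use a column mapping if headers differ)"
        )


def _numeric(df: pd.DataFrame, column: str, what: str) -> pd.Series:
    coerced = pd.to_numeric(df[column], errors="coerce")
    bad = df.index[coerced.isna() & df[column].notna()]
    if len(bad):
        rows = ", ".join(str(i + 2) for i in bad[:5])  # +2: header + 1-based
        raise ValidationError(
            f"{what}: non-numeric values in column {column!r} at file row(s) {rows}"
        )
    if coerced.isna().any():
        rows = ", ".join(str(i + 2) for i in df.index[coerced.isna()][:5])
        raise ValidationError(
            f"{what}: missing values in column {column!r} at file row(s) {rows}"
        )
    return coerced


def _no_duplicates(df: pd.DataFrame, keys: list[str], what: str) -> None:
    dup = df.duplicated(subset=keys)
    if dup.any():
        rows = ", ".join(str(i + 2) for i in df.index[dup][:5])
        raise ValidationError(
            f"{what}: duplicate {tuple(keys)} entries at file row(s) {rows}"
        )


# ---------------------------------------------------------------------------
# Layout


def read_layout(path) -> pd.DataFrame:
    df = _read_csv(path)
    _require(df, ["plate", "well_name", "consortium_binary"], "layout file")
    return df


def layout_code_lookup(layout_df: pd.DataFrame) -> dict[tuple[int, str], str]:
    """(plate, well_name) -> binary code string."""
    return {
        (int(r.plate), str(r.well_name)): str(r.consortium_binary)
        for r in layout_df.itertuples()
    }


def build_layout(m: int, plate_format: int = 96, names=None) -> PlateLayout:
    library = (
        SpeciesLibrary(tuple(names)) if names else SpeciesLibrary.with_size(m)
    )
    return PlateLayout(library, plate_format)


# ---------------------------------------------------------------------------
# Measurement tables


def read_function_table(path, colmap: dict[str, str] | None = None) -> pd.DataFrame:
    """Per-consortium function values: ``consortium_binary,replicate,value``."""
    df = _apply_colmap(_read_csv(path, colmap), colmap)
    if "replicate" not in df.columns:
        df["replicate"] = 1
    _require(df, ["consortium_binary", "replicate", "value"], "function table")
    df["consortium_binary"] = df["consortium_binary"].astype(str)
    widths = df["consortium_binary"].str.len().unique()
    if len(widths) != 1:
        raise ValidationError(
            f"function table mixes code widths {sorted(widths)}"
        )
    df["value"] = _numeric(df, "value", "function table")
    _no_duplicates(df, ["consortium_binary", "replicate"], "function table")
    return df[["consortium_binary", "replicate", "value"]]


def read_spectra_table(
    path,
    layout: pd.DataFrame | None = None,
    colmap: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Long spectra table; joins wells against a layout when codes are absent.

    Accepts either a ``sample`` (binary code) column directly, or
    ``plate`` + ``well`` columns resolved through the layout's
    consortium <-> well bijection.
    """
    df = _apply_colmap(_read_csv(path, colmap), colmap)
    if "sample" not in df.columns and "consortium_binary" in df.columns:
        df = df.rename(columns={"consortium_binary": "sample"})
    if "sample" not in df.columns:
        if layout is None:
            raise ValidationError(
                "spectra table has no 'sample' column and no layout was given "
                "to resolve (plate, well) addresses"
            )
        well_col = "well" if "well" in df.columns else "well_name"
        _require(df, ["plate", well_col], "spectra table")
        lookup = layout_code_lookup(layout)
        codes = []
        for idx, row in enumerate(df.itertuples()):
            key = (int(row.plate), str(getattr(row, well_col)))
            if key not in lookup:
                raise ValidationError(
                    f"spectra table: unknown well plate {key[0]} {key[1]!r} "
                    f"at file row {idx + 2}"
                )
            codes.append(lookup[key])
        df["sample"] = codes
    if "replicate" not in df.columns:
        df["replicate"] = 1
    _require(df, ["sample", "replicate", "wavelength_nm", "absorbance"], "spectra table")
    df["sample"] = df["sample"].astype(str)
    df["wavelength_nm"] = _numeric(df, "wavelength_nm", "spectra table")
    df["absorbance"] = _numeric(df, "absorbance", "spectra table")
    _no_duplicates(df, ["sample", "replicate", "wavelength_nm"], "spectra table")
    return df[["sample", "replicate", "wavelength_nm", "absorbance"]]


# ---------------------------------------------------------------------------
# Run metadata


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_run_metadata(outdir, command: str, params: dict, inputs: list | None = None):
    """Reproducibility record: version, command, parameters, input hashes."""
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {
        "package": "combiplate",
        "version": __version__,
        "command": command,
        "parameters": {k: (str(v) if isinstance(v, Path) else v) for k, v in params.items()},
        "inputs": {str(p): file_sha256(p) for p in (inputs or [])},
    }
    path = outdir / "run_metadata.json"
    path.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return path
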