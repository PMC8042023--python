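"""Schema-validated CSV table I/O.

Tables are UTF-8 CSV with a header row; units are micrometres and minutes.
Each schema lists the required columns and their dtypes; unknown columns
are preserved but reported.  Writing uses a fixed float format so repeated
runs with the same seed are byte-identical.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from wallmark.errors import SchemaError

_FLOAT_FMT = "%.9g"

SCHEMAS: dict[str, dict[str, str]] = {
    "positions": {
        "cell_id": "str", "motor_id": "int", "frame": "int", "time_min": "float",
        "x_um": "float", "y_um": "float", "P_y_um": "float", "color": "str",
    },
    "spots": {
        "cell_id": "str", "frame": "int", "time_min": "float",
        "x_um": "float", "y_um": "float", "P_y_um": "float",
    },
    "geometry": {
        "cell_id": "str", "frame": "int", "time_min": "float",
        "cell_length_um": "float", "phase": "str",
    },
    "traces": {
        "cell_id": "str", "motor_id": "int", "time_min": "float",
        "x_um": "float", "y_um": "float", "P_y_um": "float",
    },
    "lineage": {
        "mother_id": "str", "daughter_id": "str", "motor_id": "int",
        "N_y_mother": "float", "N_y_daughter": "float",
    },
    "pairs": {
        "cell_id": "str", "motor_i": "int", "motor_j": "int", "time_min": "float",
        "dt_min": "float", "D_x_um": "float", "D_y_um": "float",
        "V_Dx_um_min": "float", "V_Dy_um_min": "float",
    },
}

_CASTS = {"str": str, "int": "int64", "float": "float64"}


def validate_table(df: pd.DataFrame, schema: str) -> pd.DataFrame:
    """Check required columns, coerce dtypes, report unknown columns."""
    if schema not in SCHEMAS:
        raise KeyError(f"unknown schema {schema!r}; known: {sorted(SCHEMAS)}")
    spec = SCHEMAS[schema]
    missing = [c for c in spec if c not in df.columns]
    if missing:
        raise SchemaError(f"table does not match schema {schema!r}: missing columns {missing}")
    extra = [c for c in df.columns if c not in spec]
    if extra:
        warnings.warn(f"schema {schema!r}: unknown columns preserved: {extra}", stacklevel=2)
    out = df.copy()
    for col, kind in spec.items():
        try:
            if kind == "str":
                out[col] = out[col].astype(str)
            else:
                out[col] = out[col].astype(_CASTS[kind])
        except (TypeError, ValueError) as err:
            raise SchemaError(f"column {col!r} not coercible to {kind}: {err}") from err
    return out


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read and validate a CSV table (locale-independent decimal parsing)."""
    df = pd.read_csv(path, dtype={"cell_id": str, "mother_id": str, "daughter_id": str})
    return validate_table(df, schema)


def write_table(df: pd.DataFrame, path: str | Path, schema: str | None = None) -> Path:
    """Validate (optionally) and write a table deterministically."""
    if schema is not None:
        df = validate_table(df, schema)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path
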