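"""Per-cell observation tables.

A cohort of observed cells is a pandas DataFrame with one row per cell and
the following columns (marker statuses use the pandas nullable boolean
dtype so that missing readouts are representable):

=============  =========================================================
cell_id        unique string
embryo_id      string; required for any record entering group statistics
condition      string (e.g. "control", "cdkn1c_sh")
timepoint_h    hours since the reference event (>= 0)
gfp_pos, prb_pos, edu_pos, ft_pos, hucd_pos   tri-state booleans
x_um, y_um, z_um            optional positions (y = apico-basal distance)
gfp_int, ft_int             optional channel intensities
=============  =========================================================
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["MARKER_COLS", "validate_cells", "read_cells_csv", "write_cells_csv"]

MARKER_COLS = ("gfp_pos", "prb_pos", "edu_pos", "ft_pos", "hucd_pos")
REQUIRED_COLS = ("cell_id", "embryo_id", "condition", "timepoint_h")


def validate_cells(cells: pd.DataFrame) -> pd.DataFrame:
    """Validate and coerce a cell table; returns a normalized copy."""
    df = cells.copy()
    for c in REQUIRED_COLS:
        if c not in df.columns:
            raise ValueError(f"cell table missing required column '{c}'")
    if df["cell_id"].duplicated().any():
        raise ValueError("duplicate cell_id")
    tp = df["timepoint_h"].to_numpy(dtype=float)
    if np.any(tp < 0) or np.any(~np.isfinite(tp)):
        raise ValueError("timepoint_h must be finite and >= 0")
    for c in MARKER_COLS:
        if c in df.columns:
            df[c] = df[c].astype("boolean")
        else:
            df[c] = pd.Series(pd.NA, index=df.index, dtype="boolean")
    return df


def read_cells_csv(path) -> pd.DataFrame:
    return validate_cells(pd.read_csv(path))


def write_cells_csv(cells: pd.DataFrame, path) -> None:
    cells.to_csv(path, index=False)
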