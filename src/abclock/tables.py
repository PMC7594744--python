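"""Table schemas and validated TSV input/output.

All on-disk tables are tab-separated with unit-suffixed column names so
the pipeline's three clocks are unmistakable: ``t_h`` counts hours from
the exit trigger (2i/LIF removal), ``t_min`` minutes from cytokinesis
end, ``t_s`` seconds from the photobleaching pulse.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["SCHEMAS", "SCHEMA_VERSION", "read_table", "write_table"]

SCHEMA_VERSION = "1"

#: kind -> (required columns, numeric columns, duplicate-key columns)
SCHEMAS: dict[str, tuple[list[str], list[str], list[str]]] = {
    "lineage": (["cell_id", "parent_id", "division_times_h"], [],
                ["cell_id"]),
    "trajectories": (["cell_id", "t_h", "intensity_au"],
                     ["t_h", "intensity_au"], ["cell_id", "t_h"]),
    "fits": (["cell_id", "tau_h", "sigma_tau_h", "converged", "kept"],
             ["tau_h", "sigma_tau_h"], ["cell_id"]),
    "bridges": (["bridge_id", "condition", "t_min", "width_um"],
                ["t_min", "width_um"], ["bridge_id", "t_min"]),
    "frap": (["trace_id", "role", "t_s", "intensity_norm"],
             ["t_s", "intensity_norm"], ["trace_id", "t_s"]),
    "counts": (["frame_id", "n_cells", "n_bridges"],
               ["n_cells", "n_bridges"], ["frame_id"]),
    "durations": (["cell_id", "cytokinesis_end_h", "abscission_time_h"],
                  ["cytokinesis_end_h", "abscission_time_h"], ["cell_id"]),
}


def read_table(path: str | Path, kind: str) -> pd.DataFrame:
    """Read and validate a TSV table of the given kind.

    Column order is irrelevant (header-keyed).  Raises on a missing
    column (naming it), a non-numeric value in a numeric column, or
    duplicated key rows.
    """
    if kind not in SCHEMAS:
        raise ValueError(f"unknown table kind: {kind!r}")
    required, numeric, keys = SCHEMAS[kind]
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in required:
        if col not in df.columns:
            raise ValueError(f"schema error in {path}: missing column "
                             f"{col!r}")
    for col in numeric:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()]
            lines = (bad.index + 2).tolist()[:5]  # +2: header + 1-based
            raise ValueError(
                f"parse error in {path}, column {col!r}: non-numeric "
                f"value(s) at line(s) {lines}") from exc
    ids = ("cell_id", "parent_id", "bridge_id", "trace_id", "condition",
           "role", "division_times_h", "gating_division", "cycle_stage")
    for col in df.columns:  # convert extra numeric-looking columns (truth)
        if col in numeric or col in ids:
            continue
        try:
            df[col] = pd.to_numeric(df[col].replace("", "nan"))
        except (ValueError, TypeError):
            pass
    if keys and df.duplicated(subset=keys).any():
        dup = df[df.duplicated(subset=keys)]
        raise ValueError(f"duplicate sample in {path}: key(s) "
                         f"{dup[keys].iloc[0].tolist()}")
    if kind == "fits":
        for col in ("converged", "kept"):
            df[col] = df[col].astype(str).str.lower().isin(
                ("true", "1", "yes"))
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a table as TSV (no index)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
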