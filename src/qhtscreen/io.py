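"""Long-format plate I/O and the raw plate-stack container.

The interchange format is one CSV row per well:

``plate_id, stack_index, row, col, role, compound_id, conc_uM, value``

A compound-free (DMSO-only) plate is one whose wells are all role
``dmso_control``; the screening stack carries one such plate at each end
for spatial pattern correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import plates
from .errors import SchemaError

STACK_COLUMNS = ["plate_id", "stack_index", "row", "col", "role", "compound_id", "conc_uM", "value"]

VALID_ROLES = (
    plates.ROLE_DMSO,
    plates.ROLE_POS_TITRATION,
    plates.ROLE_POS_TOP,
    plates.ROLE_COMPOUND,
    plates.ROLE_EMPTY,
)


@dataclass
class RawPlateStack:
    """Ordered raw luminescence plates for one sample's screen."""

    sample_id: str
    wells: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.wells = validate_stack_frame(self.wells)

    @property
    def plate_ids(self) -> list[str]:
        """Plate ids in stack order."""
        order = self.wells[["plate_id", "stack_index"]].drop_duplicates().sort_values("stack_index")
        return order["plate_id"].tolist()

    def dmso_plate_ids(self) -> list[str]:
        """Compound-free plates (every well role ``dmso_control``), in stack order."""
        all_dmso = self.wells.groupby("plate_id", sort=False)["role"].agg(
            lambda r: (r == plates.ROLE_DMSO).all()
        )
        ids = set(all_dmso[all_dmso].index)
        return [p for p in self.plate_ids if p in ids]

    def plate(self, plate_id: str) -> pd.DataFrame:
        return self.wells[self.wells["plate_id"] == plate_id]


def validate_stack_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Validate the long-format well schema, reporting offending row numbers."""
    missing = [c for c in STACK_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")
    df = df.copy()
    df["compound_id"] = df["compound_id"].fillna("").astype(str)

    bad_row = ~df["row"].between(1, plates.N_ROWS)
    bad_col = ~df["col"].between(1, plates.N_COLS)
    if bad_row.any() or bad_col.any():
        rows = df.index[bad_row | bad_col].tolist()[:10]
        raise SchemaError(f"out-of-range well addresses at rows {rows}")

    bad_role = ~df["role"].isin(VALID_ROLES)
    if bad_role.any():
        rows = df.index[bad_role].tolist()[:10]
        raise SchemaError(f"unknown roles at rows {rows}")

    dup = df.duplicated(subset=["plate_id", "row", "col"])
    if dup.any():
        rows = df.index[dup].tolist()[:10]
        raise SchemaError(f"duplicate wells at rows {rows}")

    if df.groupby("plate_id")["stack_index"].nunique().gt(1).any():
        raise SchemaError("a plate_id maps to more than one stack_index")

    return df.sort_values(["stack_index", "row", "col"], kind="mergesort").reset_index(drop=True)


def read_raw_stack(path: str | Path, sample_id: str | None = None) -> RawPlateStack:
    """Read a long-format raw plate stack CSV.

    The sample id defaults to the file stem.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"compound_id": str}, keep_default_na=False, na_values=[""])
    df["compound_id"] = df["compound_id"].fillna("")
    return RawPlateStack(sample_id=sample_id or path.stem, wells=df)


def write_raw_stack(stack: RawPlateStack, path: str | Path) -> Path:
    """Write a stack back to the long-format CSV (full float precision)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    stack.wells.to_csv(path, index=False, columns=STACK_COLUMNS)
    return path


def write_plate_map(stack: RawPlateStack, path: str | Path) -> Path:
    """Write the stack's plate map (layout without measurements)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = ["plate_id", "row", "col", "role", "compound_id", "conc_uM"]
    stack.wells[cols].to_csv(path, index=False)
    return path


def write_library_manifest(records, path: str | Path) -> Path:
    """Write a compound library manifest (``compound_id, name, category``)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [{"compound_id": r.compound_id, "name": r.name, "category": r.category} for r in records]
    ).to_csv(path, index=False)
    return path


def grid_from_plate(plate_df: pd.DataFrame, column: str = "value") -> np.ndarray:
    """Pivot one plate's long rows to a (32, 48) array (NaN where absent)."""
    grid = np.full((plates.N_ROWS, plates.N_COLS), np.nan)
    grid[plate_df["row"].to_numpy() - 1, plate_df["col"].to_numpy() - 1] = (
        plate_df[column].to_numpy(dtype=float)
    )
    return grid
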