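"""1536-well plate geometry, control layout, and dilution-series arithmetic.

The screening protocol plates compounds in an inter-plate titration: each
compound keeps a fixed well across a stack of plates, and each plate in the
stack carries one concentration of a geometric dilution series.  The first
four columns of every compound plate are reserved for controls:

* columns 1 and 3 — DMSO only (basal viability, 0% anchor),
* column 2 — a doxorubicin titration, 1:2 from 10 uM down to 5 nM,
* column 4 — doxorubicin at the top dose (full-kill, -100% anchor).

Columns 5-48 hold library compounds (32 rows x 44 columns = 1408 wells).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError

N_ROWS = 32
N_COLS = 48

ROLE_DMSO = "dmso_control"
ROLE_POS_TITRATION = "pos_titration"
ROLE_POS_TOP = "pos_top"
ROLE_COMPOUND = "compound"
ROLE_EMPTY = "empty"

DMSO_COLS = (1, 3)
POS_TITRATION_COL = 2
POS_TOP_COL = 4
FIRST_COMPOUND_COL = 5

#: doxorubicin control titration: 1:2 from 10 uM, 12 points reach the 5 nM floor
DOX_TOP_UM = 10.0
DOX_FACTOR = 2.0
DOX_N_POINTS = 12
POS_TOP_UM = 10.0

COMPOUND_WELLS_PER_PLATE = N_ROWS * (N_COLS - FIRST_COMPOUND_COL + 1)


@dataclass(frozen=True, order=True)
class WellAddress:
    """1-based (row, col) address on a 1536-well plate."""

    row: int
    col: int

    def __post_init__(self) -> None:
        if not (1 <= self.row <= N_ROWS):
            raise InvalidArgumentError(f"row must be in [1, {N_ROWS}], got {self.row}")
        if not (1 <= self.col <= N_COLS):
            raise InvalidArgumentError(f"col must be in [1, {N_COLS}], got {self.col}")


@dataclass(frozen=True)
class ConcentrationSeries:
    """Descending geometric concentration series (uM)."""

    top: float
    factor: float
    n_points: int
    values: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.values:
            object.__setattr__(
                self, "values", tuple(self.top / self.factor**i for i in range(self.n_points))
            )

    @property
    def bottom(self) -> float:
        return self.values[-1]

    def __len__(self) -> int:
        return self.n_points

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


def make_series(top: float, factor: float, n_points: int) -> ConcentrationSeries:
    """Build the descending geometric series ``values[i] = top / factor**i``.

    Parameters
    ----------
    top : float
        Highest concentration (uM), > 0.
    factor : float
        Dilution ratio between consecutive points, > 1.
    n_points : int
        Number of concentrations, >= 1.
    """
    if not math.isfinite(top) or top <= 0:
        raise InvalidArgumentError(f"top concentration must be > 0, got {top}")
    if not math.isfinite(factor) or factor <= 1:
        raise InvalidArgumentError(f"dilution factor must be > 1, got {factor}")
    if int(n_points) != n_points or n_points < 1:
        raise InvalidArgumentError(f"n_points must be a positive integer, got {n_points}")
    return ConcentrationSeries(top=float(top), factor=float(factor), n_points=int(n_points))


def transfer_concentration(stock_uM: float, v_transfer_nL: float, v_assay_uL: float) -> float:
    """Final concentration after a pintool transfer into the assay volume.

    ``final = stock * v_transfer / (v_assay + v_transfer)`` with volumes on a
    common scale (the assay volume is given in uL, the transfer in nL).
    A 23 nL transfer of 10 mM stock into 4 uL gives ~57 uM.
    """
    if stock_uM < 0:
        raise InvalidArgumentError(f"stock concentration must be >= 0, got {stock_uM}")
    if v_transfer_nL <= 0 or v_assay_uL <= 0:
        raise InvalidArgumentError("transfer and assay volumes must be > 0")
    total_nL = v_assay_uL * 1000.0 + v_transfer_nL
    return stock_uM * v_transfer_nL / total_nL


def titration_concentration(row: int) -> float:
    """Doxorubicin column-2 concentration for a 1-based row.

    The 12-point 1:2 block (10 uM -> ~5 nM) is cycled down the 32-well
    column rather than extended below its 5 nM floor.
    """
    if not (1 <= row <= N_ROWS):
        raise InvalidArgumentError(f"row must be in [1, {N_ROWS}], got {row}")
    return DOX_TOP_UM / DOX_FACTOR ** ((row - 1) % DOX_N_POINTS)


@dataclass(frozen=True)
class PlateSpec:
    """Role layout of a 1536-well compound plate."""

    n_rows: int = N_ROWS
    n_cols: int = N_COLS

    def role_of_col(self, col: int) -> str:
        if col in DMSO_COLS:
            return ROLE_DMSO
        if col == POS_TITRATION_COL:
            return ROLE_POS_TITRATION
        if col == POS_TOP_COL:
            return ROLE_POS_TOP
        return ROLE_COMPOUND

    def role_grid(self) -> np.ndarray:
        """(n_rows, n_cols) array of role strings."""
        grid = np.empty((self.n_rows, self.n_cols), dtype=object)
        for c in range(1, self.n_cols + 1):
            grid[:, c - 1] = self.role_of_col(c)
        return grid


@dataclass(frozen=True)
class CompoundRecord:
    """Library compound and its fixed position in the plate stack."""

    compound_id: str
    name: str
    category: str
    well: WellAddress
    plate_position: int  # which sub-stack of plates holds this compound

    def __post_init__(self) -> None:
        spec = PlateSpec()
        if spec.role_of_col(self.well.col) != ROLE_COMPOUND:
            raise InvalidArgumentError(
                f"compound well must be in the compound area (cols >= {FIRST_COMPOUND_COL}), "
                f"got col {self.well.col}"
            )


def control_layout(spec: PlateSpec | None = None) -> dict[WellAddress, tuple[str, float]]:
    """Map every control well to its (role, expected concentration in uM)."""
    spec = spec or PlateSpec()
    layout: dict[WellAddress, tuple[str, float]] = {}
    for row in range(1, spec.n_rows + 1):
        for col in (*DMSO_COLS, POS_TITRATION_COL, POS_TOP_COL):
            role = spec.role_of_col(col)
            if role == ROLE_DMSO:
                conc = 0.0
            elif role == ROLE_POS_TITRATION:
                conc = titration_concentration(row)
            else:
                conc = POS_TOP_UM
            layout[WellAddress(row, col)] = (role, conc)
    return layout


def assign_compound_wells(n_compounds: int) -> list[tuple[int, WellAddress]]:
    """Fixed (plate_position, well) assignment for a library, row-major in the compound area."""
    if n_compounds < 1:
        raise InvalidArgumentError("n_compounds must be >= 1")
    out = []
    for i in range(n_compounds):
        position, j = divmod(i, COMPOUND_WELLS_PER_PLATE)
        row = 1 + j // (N_COLS - FIRST_COMPOUND_COL + 1)
        col = FIRST_COMPOUND_COL + j % (N_COLS - FIRST_COMPOUND_COL + 1)
        out.append((position, WellAddress(row, col)))
    return out
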