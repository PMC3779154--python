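"""Control-anchored normalization, spatial pattern correction, and assay QC.

Raw luminescence is mapped to percent activity anchored at the DMSO basal
signal (0%) and the doxorubicin full-kill signal (-100%), so cytotoxicity is
negative.  Anchors use per-plate medians of the control columns (robust to
occasional dead wells); the Z'-factor uses means and SDs per the standard
screening-window formula.

Spatial plate artifacts are removed on the raw scale by dividing each well by
a relative background field estimated from the compound-free (DMSO-only)
plates that bracket the stack, linearly interpolated across stack position.
Division exactly removes multiplicative artifacts shared by all plates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from . import plates
from .errors import ConfigurationError, DegenerateControlsError, InvalidArgumentError
from .io import RawPlateStack, grid_from_plate


@dataclass(frozen=True)
class ControlStats:
    """Per-plate control-well statistics.

    ``mu_neg``/``mu_pos`` are the median DMSO (cols 1, 3) and full-kill
    (col 4) signals used as normalization anchors; SDs feed the Z'-factor.
    """

    plate_id: str
    mu_neg: float
    mu_pos: float
    sd_neg: float
    sd_pos: float
    mad_neg: float
    mad_pos: float
    n_neg: int
    n_pos: int


def compute_control_stats(plate_df: pd.DataFrame, plate_id: str = "") -> ControlStats:
    """Control statistics for one plate's long-format rows.

    Only columns 1 and 3 contribute to the DMSO group and column 4 to the
    positive group; the column-2 titration is excluded.
    """
    is_neg = (plate_df["role"] == plates.ROLE_DMSO) & plate_df["col"].isin(plates.DMSO_COLS)
    is_pos = plate_df["role"] == plates.ROLE_POS_TOP
    neg = plate_df.loc[is_neg, "value"].to_numpy(dtype=float)
    pos = plate_df.loc[is_pos, "value"].to_numpy(dtype=float)
    if neg.size < 2 or pos.size < 2:
        raise DegenerateControlsError(
            f"plate {plate_id or '?'}: need >= 2 wells per control group, "
            f"got {neg.size} DMSO / {pos.size} positive"
        )
    return ControlStats(
        plate_id=plate_id or str(plate_df["plate_id"].iloc[0]),
        mu_neg=float(np.median(neg)),
        mu_pos=float(np.median(pos)),
        sd_neg=float(np.std(neg, ddof=1)),
        sd_pos=float(np.std(pos, ddof=1)),
        mad_neg=float(np.median(np.abs(neg - np.median(neg)))),
        mad_pos=float(np.median(np.abs(pos - np.median(pos)))),
        n_neg=int(neg.size),
        n_pos=int(pos.size),
    )


def normalize_values(raw: np.ndarray | float, stats: ControlStats) -> np.ndarray | float:
    """Map raw signal to % activity: ``100 * (raw - mu_neg) / (mu_neg - mu_pos)``."""
    if stats.mu_neg == stats.mu_pos:
        raise DegenerateControlsError(f"plate {stats.plate_id}: mu_neg == mu_pos")
    return 100.0 * (np.asarray(raw, dtype=float) - stats.mu_neg) / (stats.mu_neg - stats.mu_pos)


def normalize_plate(plate_df: pd.DataFrame, stats: ControlStats) -> pd.DataFrame:
    """Return the plate rows with a ``value_norm`` column added."""
    out = plate_df.copy()
    out["value_norm"] = normalize_values(plate_df["value"].to_numpy(dtype=float), stats)
    return out


def z_factor(stats: ControlStats) -> float:
    """Screening-window coefficient ``1 - 3(sd_pos + sd_neg)/|mu_pos - mu_neg|``."""
    sep = abs(stats.mu_pos - stats.mu_neg)
    if sep == 0:
        raise DegenerateControlsError("z_factor undefined: mu_pos == mu_neg")
    return 1.0 - 3.0 * (stats.sd_pos + stats.sd_neg) / sep


def signal_background(stats: ControlStats) -> float:
    """Signal-to-background ratio ``mu_neg / mu_pos``."""
    if stats.mu_pos <= 0:
        raise DegenerateControlsError("signal/background undefined: mu_pos <= 0")
    return stats.mu_neg / stats.mu_pos


class PlateNormalizer(BaseEstimator, TransformerMixin):
    """Per-plate control-anchored normalization of a raw stack.

    ``fit`` computes control statistics per plate; ``transform`` adds a
    ``value_norm`` column.  Compound-free (DMSO-only) plates carry no
    positive controls: they serve pattern correction and are dropped from
    the normalized output.

    Attributes
    ----------
    control_stats_ : dict[str, ControlStats]
        Per-plate statistics keyed by plate id (compound plates only).
    """

    def fit(self, stack: RawPlateStack, y=None) -> "PlateNormalizer":
        dmso_only = set(stack.dmso_plate_ids())
        self.control_stats_ = {
            pid: compute_control_stats(grp, pid)
            for pid, grp in stack.wells.groupby("plate_id", sort=False)
            if pid not in dmso_only
        }
        return self

    def transform(self, stack: RawPlateStack) -> pd.DataFrame:
        dmso_only = set(stack.dmso_plate_ids())
        parts = []
        for pid, grp in stack.wells.groupby("plate_id", sort=False):
            if pid in dmso_only:
                continue
            try:
                stats = self.control_stats_[pid]
            except KeyError:
                raise InvalidArgumentError(f"no fitted control stats for plate {pid!r}")
            parts.append(normalize_plate(grp, stats))
        out = pd.concat(parts, axis=0)
        return out.sort_values(["stack_index", "row", "col"], kind="mergesort").reset_index(
            drop=True
        )


class PatternCorrector(BaseEstimator, TransformerMixin):
    """Spatial pattern correction from bracketing DMSO-only plates.

    ``fit`` derives a relative background field ``b_k(w) = dmso_k(w) /
    median(dmso_k)`` from the first and last compound-free plates of the
    stack; ``transform`` divides every well by the field linearly
    interpolated at its plate's stack position.  Plate medians of the DMSO
    plates are unchanged, and re-applying the corrector to its own output is
    the identity.

    Attributes
    ----------
    b_lead_, b_trail_ : ndarray of shape (32, 48)
        Relative background fields of the leading/trailing DMSO plates.
    idx_lead_, idx_trail_ : int
        Their stack indices.
    """

    def fit(self, stack: RawPlateStack, y=None) -> "PatternCorrector":
        dmso_ids = stack.dmso_plate_ids()
        if len(dmso_ids) < 2:
            raise ConfigurationError(
                "pattern correction needs a DMSO-only plate at each end of the stack"
            )
        order = stack.plate_ids
        if order[0] != dmso_ids[0] or order[-1] != dmso_ids[-1]:
            raise ConfigurationError("stack must begin and end with a DMSO-only plate")
        idx = stack.wells.groupby("plate_id")["stack_index"].first()
        self.idx_lead_ = int(idx[dmso_ids[0]])
        self.idx_trail_ = int(idx[dmso_ids[-1]])
        self.b_lead_ = self._relative_field(stack.plate(dmso_ids[0]))
        self.b_trail_ = self._relative_field(stack.plate(dmso_ids[-1]))
        return self

    @staticmethod
    def _relative_field(plate_df: pd.DataFrame) -> np.ndarray:
        grid = grid_from_plate(plate_df)
        med = np.nanmedian(grid)
        if med <= 0:
            raise ConfigurationError("DMSO plate median must be > 0")
        return grid / med

    def transform(self, stack: RawPlateStack) -> RawPlateStack:
        span = self.idx_trail_ - self.idx_lead_
        wells = stack.wells.copy()
        si = wells["stack_index"].to_numpy(dtype=float)
        t = np.clip((si - self.idx_lead_) / span, 0.0, 1.0) if span > 0 else np.zeros_like(si)
        r = wells["row"].to_numpy() - 1
        c = wells["col"].to_numpy() - 1
        b = (1.0 - t) * self.b_lead_[r, c] + t * self.b_trail_[r, c]
        wells["value"] = wells["value"].to_numpy(dtype=float) / b
        return RawPlateStack(sample_id=stack.sample_id, wells=wells)


def pattern_correct(stack: RawPlateStack) -> RawPlateStack:
    """Fit-and-apply pattern correction; wrapper over :class:`PatternCorrector`."""
    return PatternCorrector().fit(stack).transform(stack)


def qc_report(stack: RawPlateStack) -> pd.DataFrame:
    """Per-plate QC table: ``plate_id, z_factor, sb_ratio, cv_dmso``.

    Compound-free plates have no positive controls and are excluded.
    """
    dmso_only = set(stack.dmso_plate_ids())
    rows = []
    for pid, grp in stack.wells.groupby("plate_id", sort=False):
        if pid in dmso_only:
            continue
        stats = compute_control_stats(grp, pid)
        rows.append(
            (
                pid,
                int(grp["stack_index"].iloc[0]),
                z_factor(stats),
                signal_background(stats),
                stats.sd_neg / stats.mu_neg if stats.mu_neg else np.nan,
            )
        )
    return pd.DataFrame(rows, columns=["plate_id", "stack_index", "z_factor", "sb_ratio", "cv_dmso"])


def normalize_stack(stack: RawPlateStack) -> pd.DataFrame:
    """Normalize a (pattern-corrected) stack; adds ``value_norm`` and ``sample_id``."""
    out = PlateNormalizer().fit(stack).transform(stack)
    out.insert(0, "sample_id", stack.sample_id)
    return out
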