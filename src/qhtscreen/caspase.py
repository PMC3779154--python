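"""Caspase-3/7, -8 and -9 activation analysis.

Caspase luminescence is normalized against the DMSO control so that 0% is
the DMSO level and 100% is a 2-fold induction over DMSO.  Activation curves
rise with concentration; strongly cytotoxic compounds produce bell-shaped
curves whose high-concentration tail falls off because the cells die before
the caspase signal develops.  The fitter detects the peak and, when the
post-peak tail drops below half the peak response, masks the tail (a suffix
of the concentration-ordered points, never the peak itself) and fits a
rising four-parameter logistic to the ascending limb; the fitted midpoint is
the activation EC50.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .doseresponse import FitResult, FourParamLogistic
from .errors import InsufficientDataError, InvalidArgumentError

CASPASE_TYPES = ("3/7", "8", "9")


@dataclass(frozen=True)
class CaspaseCurve:
    """One compound x sample caspase activation series (DMSO-normalized %)."""

    compound_id: str
    sample_id: str
    caspase_type: str
    concentrations: np.ndarray
    responses: np.ndarray

    def __post_init__(self) -> None:
        if self.caspase_type not in CASPASE_TYPES:
            raise InvalidArgumentError(f"caspase_type must be one of {CASPASE_TYPES}")
        c = np.asarray(self.concentrations, dtype=float)
        y = np.asarray(self.responses, dtype=float)
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "responses", y)
        if c.shape != y.shape or np.any(c <= 0) or np.any(np.diff(c) <= 0):
            raise InvalidArgumentError("need equal-length, positive, increasing concentrations")


def normalize_caspase(raw: np.ndarray | float, mu_dmso: float) -> np.ndarray | float:
    """Percent activation: ``100 * (raw - mu_dmso) / mu_dmso``.

    DMSO level maps to 0%, a 2-fold induction to 100%.
    """
    if mu_dmso <= 0:
        raise InvalidArgumentError("mu_dmso must be > 0")
    return 100.0 * (np.asarray(raw, dtype=float) - mu_dmso) / mu_dmso


def fit_activation(
    curve: CaspaseCurve,
    mask_fraction: float = 0.5,
    **fit_params,
) -> tuple[FitResult, np.ndarray]:
    """Fit a rising 4PL to an activation curve, masking a bell-shaped tail.

    Returns the fit and the (possibly empty) array of masked point indices.
    Post-peak points are masked only when at least one of them falls below
    ``mask_fraction`` of the peak response.  A flat curve yields
    ``converged=False``; fewer than 4 unmasked points (bell too narrow)
    raises :class:`InsufficientDataError`.
    """
    c = curve.concentrations
    y = curve.responses
    if c.size < 4:
        raise InsufficientDataError("need >= 4 points")
    peak = int(np.argmax(y))
    masked = np.array([], dtype=int)
    tail = y[peak + 1:]
    if tail.size and y[peak] > 0 and np.any(tail < mask_fraction * y[peak]):
        masked = np.arange(peak + 1, c.size)
    keep = np.setdiff1d(np.arange(c.size), masked)
    if keep.size < 4:
        raise InsufficientDataError(
            f"bell too narrow: only {keep.size} points left of the masked tail"
        )
    params = {
        "yinf_bounds": (-30.0, 500.0),
        "y0_bounds": (-50.0, 50.0),
        "efficacy_cap": 500.0,
    }
    params.update(fit_params)
    est = FourParamLogistic(**params)
    est.fit(c[keep], y[keep])
    return est.result_(), masked


def fit_caspase_table(curves: pd.DataFrame, mask_fraction: float = 0.5) -> pd.DataFrame:
    """Fit every caspase activation series in a long-format table.

    ``curves`` columns: ``compound_id, sample_id, caspase_type, conc_uM,
    response``.  Mirrors the viability fit table with ``caspase_type`` and
    ``masked_points`` (semicolon-joined indices) columns added; series too
    narrow to fit get ``converged=False`` and an empty mask.
    """
    rows = []
    keys = ["compound_id", "sample_id", "caspase_type"]
    for (cid, sid, ctype), grp in curves.groupby(keys, sort=True):
        agg = grp.groupby("conc_uM", sort=True)["response"].mean()
        curve = CaspaseCurve(cid, sid, ctype, agg.index.to_numpy(float), agg.to_numpy(float))
        try:
            fit, masked = fit_activation(curve, mask_fraction=mask_fraction)
        except InsufficientDataError:
            fit, masked = None, np.array([], dtype=int)
        rows.append(
            {
                "compound_id": cid,
                "sample_id": sid,
                "caspase_type": ctype,
                "y0": fit.y0 if fit else np.nan,
                "yinf": fit.yinf if fit else np.nan,
                "ec50_uM": fit.ac50 if fit else np.nan,
                "hill": fit.hill if fit else np.nan,
                "efficacy_pct": fit.efficacy if fit else np.nan,
                "r2": fit.r2 if fit else np.nan,
                "converged": bool(fit.converged) if fit else False,
                "n_points": fit.n_points if fit else len(curve.concentrations),
                "masked_points": ";".join(map(str, masked.tolist())),
            }
        )
    return pd.DataFrame(rows)
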