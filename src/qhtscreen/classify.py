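"""Concentration-response curve (CRC) classification.

Each fitted curve is graded into the qHTS curve-class taxonomy:

* **1.1 / 1.2** — complete curves with both asymptotes inside the tested
  range, efficacy >= 80% / < 80%;
* **2.1 / 2.2** — incomplete curves (lower plateau not reached), efficacy
  >= 80% / < 80%;
* **3** — low-confidence activity: response only at the single highest
  concentration, a poor fit, or a Hill slope stuck at its lower bound
  (shallow, single-point-extrapolated curves);
* **4** — inactive (no significant response).

Classes then collapse to three activity categories: *active* (class
1.1/1.2/2.1/2.2 with efficacy > 60%), *inactive* (class 4), and
*inconclusive* (everything else).  Only excursions toward kill (negative
normalized activity) count as a response; signal increases are never active.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .doseresponse import CurveData, FitResult
from .errors import InvalidArgumentError

CLASS_1_1 = "1.1"
CLASS_1_2 = "1.2"
CLASS_2_1 = "2.1"
CLASS_2_2 = "2.2"
CLASS_3 = "3"
CLASS_4 = "4"
CURVE_CLASSES = (CLASS_1_1, CLASS_1_2, CLASS_2_1, CLASS_2_2, CLASS_3, CLASS_4)

ACTIVE = "active"
INCONCLUSIVE = "inconclusive"
INACTIVE = "inactive"
CATEGORIES = (ACTIVE, INCONCLUSIVE, INACTIVE)

#: classes eligible for the active category
ACTIVE_CLASSES = frozenset({CLASS_1_1, CLASS_1_2, CLASS_2_1, CLASS_2_2})


class CurveClassifier(BaseEstimator):
    """Rule-based CRC classifier over fitted curves.

    Parameters
    ----------
    act_threshold : float
        Response magnitude (points toward kill) a point must exceed to count
        as significant activity.
    efficacy_high : float
        Efficacy boundary between the x.1 and x.2 sub-classes.
    efficacy_active : float
        Minimum efficacy for the *active* category.
    r2_min : float
        Fits with r2 below this are "poorly fit" and demoted to class 3.
    plateau_tol : float
        A curve is complete when the fitted response at the top tested
        concentration is within ``plateau_tol * efficacy`` of ``yinf``.
    hill_floor : float
        A fitted Hill slope at or below this bound marks a shallow curve
        (class 3).
    """

    def __init__(
        self,
        act_threshold: float = 25.0,
        efficacy_high: float = 80.0,
        efficacy_active: float = 60.0,
        r2_min: float = 0.3,
        plateau_tol: float = 0.05,
        hill_floor: float = 0.3,
    ) -> None:
        self.act_threshold = act_threshold
        self.efficacy_high = efficacy_high
        self.efficacy_active = efficacy_active
        self.r2_min = r2_min
        self.plateau_tol = plateau_tol
        self.hill_floor = hill_floor

    def fit(self, X=None, y=None) -> "CurveClassifier":
        """No-op; the classifier is fully determined by its thresholds."""
        return self

    # -- single curve ------------------------------------------------------

    def classify(self, fit: FitResult, data: CurveData) -> str:
        """Assign one curve class to a (fit, data) pair."""
        if fit.n_points != len(data):
            raise InvalidArgumentError("fit and data refer to different series")
        y = data.responses
        c = data.concentrations
        significant = y <= -self.act_threshold

        if not significant.any():
            return CLASS_4
        if not fit.converged:
            # activity present but no usable fit
            return CLASS_3
        if significant.sum() == 1 and significant[-1]:
            return CLASS_3
        if fit.r2 < self.r2_min or fit.hill <= self.hill_floor:
            return CLASS_3

        efficacy = fit.efficacy
        if efficacy <= 0:
            return CLASS_4
        complete = abs(float(fit.predict(c[-1])) - fit.yinf) < self.plateau_tol * efficacy
        if complete:
            return CLASS_1_1 if efficacy >= self.efficacy_high else CLASS_1_2
        return CLASS_2_1 if efficacy >= self.efficacy_high else CLASS_2_2

    def categorize(self, curve_class: str, efficacy: float) -> str:
        """Collapse a curve class + efficacy to active/inconclusive/inactive."""
        if curve_class not in CURVE_CLASSES:
            raise InvalidArgumentError(f"unknown curve class {curve_class!r}")
        if curve_class == CLASS_4:
            return INACTIVE
        if curve_class in ACTIVE_CLASSES and efficacy > self.efficacy_active:
            return ACTIVE
        return INCONCLUSIVE

    # -- batch -------------------------------------------------------------

    def predict(self, fits: pd.DataFrame, curves: pd.DataFrame) -> pd.DataFrame:
        """Add ``curve_class`` and ``category`` columns to a fit table.

        Parameters
        ----------
        fits : DataFrame
            Output of :func:`qhtscreen.doseresponse.fit_table`.
        curves : DataFrame
            Long-format responses (``compound_id, sample_id, conc_uM,
            response``) the fits were computed from.
        """
        grouped = {
            key: grp.groupby("conc_uM", sort=True)["response"].mean()
            for key, grp in curves.groupby(["compound_id", "sample_id"], sort=False)
        }
        classes, categories = [], []
        for row in fits.itertuples(index=False):
            agg = grouped[(row.compound_id, row.sample_id)]
            data = CurveData(
                row.compound_id, row.sample_id,
                agg.index.to_numpy(dtype=float), agg.to_numpy(dtype=float),
            )
            fit = FitResult(
                y0=row.y0, yinf=row.yinf, ac50=row.ac50_uM, hill=row.hill,
                efficacy=row.efficacy_pct, r2=row.r2, converged=row.converged,
                n_points=row.n_points,
            )
            cls = self.classify(fit, data)
            classes.append(cls)
            categories.append(self.categorize(cls, fit.efficacy))
        out = fits.copy()
        out["curve_class"] = classes
        out["category"] = categories
        return out


def classify_crc(fit: FitResult, data: CurveData, act_threshold: float = 25.0, **params) -> str:
    """Classify one curve; thin wrapper over :class:`CurveClassifier`."""
    return CurveClassifier(act_threshold=act_threshold, **params).classify(fit, data)


def categorize(curve_class: str, efficacy: float, efficacy_active: float = 60.0) -> str:
    """Collapse (class, efficacy) to a category; wrapper over :class:`CurveClassifier`."""
    return CurveClassifier(efficacy_active=efficacy_active).categorize(curve_class, efficacy)
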