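"""Four-parameter logistic (Hill) dose-response fitting.

The model is

    y(c) = y0 + (yinf - y0) / (1 + (ac50 / c)**hill)

with ``y0`` the zero-dose asymptote, ``yinf`` the infinite-dose asymptote,
``ac50`` the midpoint concentration and ``hill`` the slope.  For a cytotoxic
(descending) curve in the -100%..0% normalization convention, ``ac50`` is the
IC50 and efficacy is ``|yinf - y0|``.

Fitting is bounded nonlinear least squares with a deterministic,
derivative-free start: asymptotes from the edge responses and the midpoint
from a log-spaced grid search.  The midpoint is optimized on a log10 scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import InsufficientDataError, InvalidArgumentError

_LN10 = np.log(10.0)


def four_param_logistic(
    c: np.ndarray | float, y0: float, yinf: float, ac50: float, hill: float
) -> np.ndarray | float:
    """Evaluate the 4PL at concentration(s) ``c`` (uM, > 0)."""
    c = np.asarray(c, dtype=float)
    return y0 + (yinf - y0) / (1.0 + (ac50 / c) ** hill)


@dataclass(frozen=True)
class CurveData:
    """One compound x sample concentration-response series."""

    compound_id: str
    sample_id: str
    concentrations: np.ndarray  # uM, strictly increasing
    responses: np.ndarray  # normalized % activity

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        y = np.asarray(self.responses, dtype=float)
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "responses", y)
        if c.shape != y.shape or c.ndim != 1:
            raise InvalidArgumentError("concentrations and responses must be equal-length 1-D")
        if np.any(c <= 0) or not np.all(np.isfinite(c)):
            raise InvalidArgumentError("concentrations must be strictly positive and finite")
        if np.any(np.diff(c) <= 0):
            raise InvalidArgumentError("concentrations must be strictly increasing")

    def __len__(self) -> int:
        return self.concentrations.size


@dataclass(frozen=True)
class FitResult:
    """Fitted 4PL parameters and diagnostics for one curve."""

    y0: float
    yinf: float
    ac50: float
    hill: float
    efficacy: float
    r2: float
    converged: bool
    n_points: int

    def predict(self, c: np.ndarray | float) -> np.ndarray | float:
        c_arr = np.asarray(c, dtype=float)
        if np.any(c_arr <= 0):
            raise InvalidArgumentError("concentration must be > 0")
        return four_param_logistic(c_arr, self.y0, self.yinf, self.ac50, self.hill)


class FourParamLogistic(BaseEstimator, RegressorMixin):
    """Bounded 4PL regressor for a single concentration-response curve.

    Parameters
    ----------
    hill_bounds : tuple of float
        Allowed Hill-slope range.
    y0_bounds, yinf_bounds : tuple of float
        Asymptote bounds in normalized %.
    ac50_span : float
        ac50 is bounded to [c_min / ac50_span, c_max * ac50_span].
    flat_span : float
        Observed response span (max - min) below which the curve is declared
        flat and the fit is marked unconverged.
    n_grid : int
        Size of the log-spaced ac50 initialization grid over
        [c_min/10, c_max*10].
    efficacy_cap : float
        Efficacy is clamped to [0, efficacy_cap].

    Attributes
    ----------
    y0_, yinf_, ac50_, hill_ : float
        Fitted parameters (ac50_ is NaN for flat/failed fits).
    efficacy_ : float
        ``|yinf_ - y0_|`` clamped to [0, efficacy_cap]; 0 for flat fits.
    r2_ : float
        Coefficient of determination of the fit.
    converged_ : bool
        False for flat data or optimizer failure.
    """

    def __init__(
        self,
        hill_bounds: tuple[float, float] = (0.3, 10.0),
        y0_bounds: tuple[float, float] = (-30.0, 30.0),
        yinf_bounds: tuple[float, float] = (-120.0, 30.0),
        ac50_span: float = 100.0,
        flat_span: float = 5.0,
        n_grid: int = 20,
        efficacy_cap: float = 120.0,
        max_nfev: int = 200,
    ) -> None:
        self.hill_bounds = hill_bounds
        self.y0_bounds = y0_bounds
        self.yinf_bounds = yinf_bounds
        self.ac50_span = ac50_span
        self.flat_span = flat_span
        self.n_grid = n_grid
        self.efficacy_cap = efficacy_cap
        self.max_nfev = max_nfev

    # -- model internals ---------------------------------------------------

    @staticmethod
    def _residuals(params: np.ndarray, log_c: np.ndarray, y: np.ndarray) -> np.ndarray:
        y0, yinf, log_ac50, hill = params
        t = np.exp(_LN10 * hill * (log_ac50 - log_c))
        return y0 + (yinf - y0) / (1.0 + t) - y

    @staticmethod
    def _jacobian(params: np.ndarray, log_c: np.ndarray, y: np.ndarray) -> np.ndarray:
        y0, yinf, log_ac50, hill = params
        d = _LN10 * (log_ac50 - log_c)
        t = np.exp(hill * d)
        u = 1.0 / (1.0 + t)
        span = yinf - y0
        w = -span * u * u * t
        jac = np.empty((log_c.size, 4))
        jac[:, 0] = 1.0 - u
        jac[:, 1] = u
        jac[:, 2] = w * hill * _LN10
        jac[:, 3] = w * d
        return jac

    def fit(self, C: np.ndarray, y: np.ndarray) -> "FourParamLogistic":
        """Fit the 4PL to concentrations ``C`` (uM) and responses ``y`` (%)."""
        c = np.asarray(C, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if c.size != y.size:
            raise InvalidArgumentError("C and y must have the same length")
        if c.size < 4:
            raise InsufficientDataError(f"need >= 4 points for a 4PL fit, got {c.size}")
        if np.any(c <= 0) or not np.all(np.isfinite(c)):
            raise InvalidArgumentError("concentrations must be strictly positive and finite")
        if not np.all(np.isfinite(y)):
            raise InvalidArgumentError("responses must be finite")

        self.n_points_ = int(c.size)
        order = np.argsort(c)
        c, y = c[order], y[order]

        span_obs = float(y.max() - y.min())
        if span_obs < self.flat_span:
            self._set_flat(y)
            return self

        log_c = np.log10(c)
        lo = np.array([self.y0_bounds[0], self.yinf_bounds[0],
                       np.log10(c[0] / self.ac50_span), self.hill_bounds[0]])
        hi = np.array([self.y0_bounds[1], self.yinf_bounds[1],
                       np.log10(c[-1] * self.ac50_span), self.hill_bounds[1]])

        y0_init = float(np.clip(y[:2].mean(), *self.y0_bounds))
        yinf_init = float(np.clip(y[-2:].mean(), *self.yinf_bounds))
        grid = np.linspace(np.log10(c[0] / 10.0), np.log10(c[-1] * 10.0), self.n_grid)
        # vectorized RSS over the grid at hill = 1
        t = 10.0 ** (grid[:, None] - log_c[None, :])
        pred = y0_init + (yinf_init - y0_init) / (1.0 + t)
        rss = ((pred - y[None, :]) ** 2).sum(axis=1)
        log_ac50_init = float(np.clip(grid[int(np.argmin(rss))], lo[2], hi[2]))
        x0 = np.array([y0_init, yinf_init, log_ac50_init, 1.0])

        try:
            sol = least_squares(
                self._residuals, x0, jac=self._jacobian, bounds=(lo, hi),
                args=(log_c, y), method="trf",
                xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=self.max_nfev,
            )
        except Exception:
            self._set_flat(y)
            return self

        y0_f, yinf_f, log_ac50_f, hill_f = sol.x
        self.y0_ = float(y0_f)
        self.yinf_ = float(yinf_f)
        self.ac50_ = float(10.0**log_ac50_f)
        self.hill_ = float(hill_f)
        self.efficacy_ = float(np.clip(abs(self.yinf_ - self.y0_), 0.0, self.efficacy_cap))
        ss_res = float(np.sum(sol.fun**2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        self.r2_ = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        self.converged_ = bool(sol.success)
        return self

    def _set_flat(self, y: np.ndarray) -> None:
        mean = float(y.mean())
        self.y0_ = mean
        self.yinf_ = mean
        self.ac50_ = float("nan")
        self.hill_ = float("nan")
        self.efficacy_ = 0.0
        self.r2_ = 0.0
        self.converged_ = False

    def predict(self, C: np.ndarray) -> np.ndarray:
        c = np.asarray(C, dtype=float)
        if np.any(c <= 0):
            raise InvalidArgumentError("concentration must be > 0")
        return four_param_logistic(c, self.y0_, self.yinf_, self.ac50_, self.hill_)

    def result_(self) -> FitResult:
        """Package the fitted attributes as an immutable :class:`FitResult`."""
        return FitResult(
            y0=self.y0_, yinf=self.yinf_, ac50=self.ac50_, hill=self.hill_,
            efficacy=self.efficacy_, r2=self.r2_, converged=self.converged_,
            n_points=self.n_points_,
        )


def fit_4pl(data: CurveData, **params) -> FitResult:
    """Fit one curve; thin wrapper over :class:`FourParamLogistic`."""
    est = FourParamLogistic(**params)
    est.fit(data.concentrations, data.responses)
    return est.result_()


def predict(fit: FitResult, c: np.ndarray | float) -> np.ndarray | float:
    """Evaluate a fitted 4PL at concentration ``c`` (uM, > 0)."""
    if not fit.converged:
        raise InvalidArgumentError("cannot predict from an unconverged fit")
    return fit.predict(c)


def fit_table(curves: pd.DataFrame, **params) -> pd.DataFrame:
    """Fit every compound x sample series in a long-format response table.

    Parameters
    ----------
    curves : DataFrame
        Columns ``compound_id, sample_id, conc_uM, response``.
    **params
        Forwarded to :class:`FourParamLogistic`.

    Returns
    -------
    DataFrame with one row per (compound_id, sample_id):
    ``y0, yinf, ac50_uM, hill, efficacy_pct, r2, converged, n_points``.
    """
    est = FourParamLogistic(**params)
    rows = []
    for (cid, sid), grp in curves.groupby(["compound_id", "sample_id"], sort=True):
        agg = grp.groupby("conc_uM", sort=True)["response"].mean()
        c = agg.index.to_numpy(dtype=float)
        y = agg.to_numpy(dtype=float)
        est.fit(c, y)
        rows.append(
            (cid, sid, est.y0_, est.yinf_, est.ac50_, est.hill_,
             est.efficacy_, est.r2_, est.converged_, est.n_points_)
        )
    return pd.DataFrame(
        rows,
        columns=["compound_id", "sample_id", "y0", "yinf", "ac50_uM", "hill",
                 "efficacy_pct", "r2", "converged", "n_points"],
    )
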