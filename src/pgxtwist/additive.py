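"""Constant-coefficient (Lin-Ying) additive hazards regression.

The model is h_i(t) = beta' z_i with time-fixed covariates z_i and time-fixed
coefficients, i.e. covariates shift the hazard by a constant number of events
per person-year.  This is the semiparametric additive-hazards analogue of an
exponential rate regression and the natural scale for a per-year genetically
moderated treatment effect.

The estimator solves the least-squares estimating equation over risk sets

    U(beta) = sum_i  int  {z_i - zbar(t)} {dN_i(t) - Y_i(t) beta' z_i dt} = 0

where zbar(t) is the covariate mean of the risk set at t.  In closed form
beta_hat = A^{-1} b with

    A = sum_i int Y_i(t) {z_i - zbar(t)}^{x2} dt
    b = sum_{events} {z_i - zbar(T_i)}

and sandwich covariance A^{-1} B A^{-1} with B the sum over events of the
outer products of the centred covariates (the observed optional variation of
the score).  Everything reduces to cumulative sums over the sorted follow-up
times, so a fit is O(n log n + n p^2).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .errors import FitError


def _as_duration_event(y) -> tuple[np.ndarray, np.ndarray]:
    """Accept (n,2) arrays, DataFrames with duration/event, or structured arrays."""
    if isinstance(y, pd.DataFrame):
        cols = {c.lower(): c for c in y.columns}
        try:
            dur = y[cols.get("duration", cols.get("time"))].to_numpy(float)
            ev = y[cols.get("event", cols.get("status"))].to_numpy(float)
        except KeyError as exc:  # pragma: no cover - defensive
            raise FitError("y must have duration/time and event/status columns") from exc
        return dur, ev
    arr = np.asarray(y)
    if arr.dtype.names:  # scikit-survival style structured array
        names = list(arr.dtype.names)
        ev = arr[names[0]].astype(float)
        dur = arr[names[1]].astype(float)
        return dur, ev
    arr = np.atleast_2d(arr)
    if arr.shape[1] != 2:
        raise FitError("y must be (n, 2) with columns (duration, event)")
    return arr[:, 0].astype(float), arr[:, 1].astype(float)


def _linying_solve(Z: np.ndarray, time: np.ndarray, event: np.ndarray,
                   names: Sequence[str]):
    """Solve the estimating equation; also return per-subject influence.

    The influence decomposition uses the full martingale residual

        eps_i = int {z_i - zbar(t)} dM_i(t),
        dM_i  = dN_i - Y_i dLambda0_hat - Y_i z_i' beta_hat dt,

    with the Breslow-type baseline dLambda0_hat = (dNbar - S1' beta dt)/S0.
    sum_i eps_i = 0 at the solution, var(beta_hat) = A^{-1} (sum eps eps') A^{-1},
    and cross-covariances between estimators fitted on overlapping subjects
    follow from the per-subject products of their influences.
    """
    n, p = Z.shape
    order = np.argsort(time, kind="stable")
    t = time[order]
    d = event[order].astype(bool)
    Z = Z[order]

    # risk set on (t_{k-1}, t_k] is {j : t_j >= t_k}; with ties, positional
    # suffix sums are correct because tied intervals have zero length and the
    # event-time lookups below index the first member of each tie group
    suffix = np.cumsum(Z[::-1], axis=0)[::-1]  # suffix[k] = sum_{j>=k} z_j
    s0 = (n - np.arange(n)).astype(float)
    dt = np.diff(np.concatenate(([0.0], t)))

    A = Z.T @ (Z * t[:, None]) - np.einsum("k,ki,kj->ij", dt / s0, suffix, suffix)

    first = np.searchsorted(t, t, side="left")  # first index of each tie group
    zbar = suffix / s0[:, None]
    zbar_ev = zbar[first[d]]
    b = (Z[d] - zbar_ev).sum(axis=0)

    try:
        beta = np.linalg.solve(A, b)
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        rank = np.linalg.matrix_rank(A)
        # smallest R-diagonal entries of a QR factorisation point at the
        # (near-)collinear columns
        diag = np.abs(np.diag(np.linalg.qr(A, mode="r")))
        bad = [names[i] for i in np.argsort(diag)[: p - rank]]
        raise FitError(
            f"singular design (rank {rank} of {p}); collinear columns: {bad}"
        )

    # per-subject martingale-residual influence, evaluated at beta_hat
    last = np.searchsorted(t, t, side="right") - 1
    zb = Z @ beta
    czbar = np.cumsum(zbar * dt[:, None], axis=0)  # int_0^t zbar ds
    dlam = d / s0[first] - (zbar @ beta) * dt  # Breslow baseline increments
    lam_cum = np.cumsum(dlam)
    izbar_lam = np.cumsum(zbar * dlam[:, None], axis=0)

    eps = np.zeros_like(Z)
    eps[d] = Z[d] - zbar_ev
    eps -= (Z * t[:, None] - czbar[last]) * zb[:, None]
    eps -= Z * lam_cum[last, None] - izbar_lam[last]

    B = eps.T @ eps
    cov = Ainv @ B @ Ainv.T
    influence = np.empty_like(eps)
    influence[order] = eps @ Ainv.T
    return beta, cov, influence


class AdditiveHazardsRegressor(BaseEstimator):
    """Lin-Ying constant additive hazards model with sandwich errors.

    The baseline hazard is semiparametric (risk-set centering removes any
    constant column from the estimating equation), so the design must not
    contain an intercept; `baseline_rate_` reports the residual
    occurrence/exposure rate instead.

    Parameters
    ----------
    alpha : float, default 0.05
        Two-sided level for `conf_int_`.

    Attributes (after `fit`)
    ----------
    coef_ : ndarray, per-year hazard differences, one per design column
    se_ : ndarray, robust (sandwich) standard errors
    covariance_ : ndarray, full sandwich covariance matrix
    zvalues_, pvalues_, conf_int_ : Wald statistics per coefficient
    feature_names_in_ : design column names
    baseline_rate_ : residual baseline hazard (events/person-year at z = 0)
    influence_ : (n, p) per-subject influence contributions; column sums of
        squares reproduce the sandwich variances, and inner products across
        two fits sharing subjects estimate the covariance of their estimates
    n_, n_events_, person_years_ : fit dimensions

    Examples
    --------
    >>> reg = AdditiveHazardsRegressor().fit(X, y)   # y = (duration, event)
    >>> dict(zip(reg.feature_names_in_, reg.coef_))  # doctest: +SKIP
    """

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            Z = X.to_numpy(float)
        else:
            Z = np.asarray(X, float)
            if Z.ndim == 1:
                Z = Z[:, None]
            names = [f"x{i}" for i in range(Z.shape[1])]
        dur, ev = _as_duration_event(y)
        if Z.shape[0] != dur.shape[0]:
            raise FitError("X and y have different lengths")
        if np.any(dur <= 0):
            raise FitError("durations must be strictly positive")
        if not np.isin(ev, (0, 1)).all():
            raise FitError("event indicator must be 0/1")
        if ev.sum() < 1:
            raise FitError("at least one event is required")
        if np.ptp(Z, axis=0).min() == 0:
            const = names[int(np.argmin(np.ptp(Z, axis=0)))]
            raise FitError(
                f"column {const!r} is constant; the semiparametric baseline "
                "absorbs any intercept, drop constant columns from the design"
            )

        beta, cov, influence = _linying_solve(Z, dur, ev, names)
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.influence_ = influence
        self.coef_ = beta
        self.covariance_ = cov
        self.se_ = np.sqrt(np.diag(cov))
        with np.errstate(divide="ignore", invalid="ignore"):
            self.zvalues_ = np.where(self.se_ > 0, beta / self.se_, np.nan)
        self.pvalues_ = 2.0 * stats.norm.sf(np.abs(self.zvalues_))
        zc = stats.norm.ppf(1 - self.alpha / 2)
        self.conf_int_ = np.column_stack(
            [beta - zc * self.se_, beta + zc * self.se_]
        )
        self.n_ = int(len(dur))
        self.n_events_ = int(ev.sum())
        self.person_years_ = float(dur.sum())
        # residual occurrence/exposure rate: events not explained by the
        # covariate effects, per person-year (exact exponential MLE when the
        # true baseline is constant)
        self.baseline_rate_ = float(
            (ev.sum() - (Z @ beta) @ dur) / dur.sum()
        )
        return self

    def predict(self, X):
        """Predicted hazard rate (events per person-year) per row."""
        Z = X.to_numpy(float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
        if Z.ndim == 1:
            Z = Z[:, None]
        return self.baseline_rate_ + Z @ self.coef_

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef_,
                "se": self.se_,
                "z": self.zvalues_,
                "p": self.pvalues_,
                "ci_low": self.conf_int_[:, 0],
                "ci_high": self.conf_int_[:, 1],
            },
            index=self.feature_names_in_,
        )


@dataclass
class AalenFit:
    """Summary of one additive-hazards fit on a cohort subset."""

    subset: str
    coef: pd.Series
    se: pd.Series
    covariance: pd.DataFrame
    n: int
    n_events: int
    person_years: float
    influence: pd.DataFrame = field(repr=False, default=None)
    model: AdditiveHazardsRegressor = field(repr=False, default=None)

    def estimate(self, name: str) -> tuple[float, float]:
        return float(self.coef[name]), float(self.se[name])


def fit_additive_hazards(
    rows: pd.DataFrame,
    design: Sequence[str],
    duration_col: str,
    event_col: str,
    covariates: Sequence[str] = (),
    subset: str = "all",
) -> AalenFit:
    """Fit the Lin-Ying model on `rows` for `design` + `covariates` columns."""
    cols = list(design) + list(covariates)
    df = rows[cols + [duration_col, event_col]].dropna()
    if df.empty or df[event_col].sum() < 1:
        raise FitError(f"subset {subset!r} has no usable rows/events")
    reg = AdditiveHazardsRegressor().fit(
        df[cols], df[[duration_col, event_col]].rename(
            columns={duration_col: "duration", event_col: "event"}
        )
    )
    tab = reg.coef_table()
    return AalenFit(
        subset=subset,
        coef=tab["coef"],
        se=tab["se"],
        covariance=pd.DataFrame(
            reg.covariance_, index=reg.feature_names_in_, columns=reg.feature_names_in_
        ),
        n=reg.n_,
        n_events=reg.n_events_,
        person_years=reg.person_years_,
        influence=pd.DataFrame(
            reg.influence_[:, : len(design)], index=df.index, columns=list(design)
        ),
        model=reg,
    )
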