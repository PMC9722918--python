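"""Circadian rhythm statistics: fixed-period cosinor regression and a
minimal JTK-style nonparametric rhythm test.

The cosinor model
-----------------
For observations :math:`Y_i` at times :math:`t_i` (hours) and a fixed
period :math:`\\tau` (24 h by default), the single-component cosinor is
the linear model

.. math::

    Y_i = M + \\beta \\cos(2\\pi t_i/\\tau) + \\gamma \\sin(2\\pi t_i/\\tau)
          + \\varepsilon_i,

fitted by ordinary least squares with replicates pooled.  The mesor
:math:`M` is the rhythm midline, the amplitude is
:math:`A = \\sqrt{\\beta^2+\\gamma^2}` (distance from mesor to peak) and
the acrophase :math:`\\Phi = \\operatorname{atan2}(\\gamma,\\beta)\\,
\\tau/2\\pi \\bmod \\tau` is the clock time at which the fitted curve
attains its maximum.  (The arctangent form ``tan⁻¹(−γ/β)`` often quoted
for the acrophase is quadrant-ambiguous; ``atan2`` resolves the quadrant
so that Φ is literally the peak time, and equals that form modulo π.)

Rhythmicity is assessed with the zero-amplitude F test of
H₀: β = γ = 0 against the intercept-only model:

.. math::

    F = \\frac{(SS_0 - SS_1)/q}{SS_1/(n - q - 1)},
    \\qquad p = \\Pr[F_{q,\\,n-q-1} > F],

with q = 2 for a full-rank design.  Sampling designs in which one
harmonic regressor vanishes (e.g. 12-h sampling of a 24-h rhythm makes
the sine term identically zero) are handled by rank-revealing least
squares: the minimum-norm solution sets the unidentifiable coefficient
to zero and q drops to the identifiable harmonic dimension.

The JTK-style test correlates the data with cosine reference waveforms
over a grid of candidate acrophases using Kendall's tau, and Bonferroni-
adjusts the smallest per-phase p-value over the number of phases tried.
This is the fixed-period variant (period 24 h, as used for circadian
screens); it does not scan periods or integrate multiple methods.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .types import ParameterError

__all__ = [
    "TimeSeries",
    "Cosinor",
    "CosinorResults",
    "JTKResult",
    "acrophase_hours",
    "zero_amplitude_test",
    "jtk_test",
    "batch_rhythm",
]

#: numerical floor used when a perfect fit drives the residual SS to zero
P_UNDERFLOW_FLOOR = 1e-15


class SingularDesignError(ParameterError):
    """The time design cannot identify the cosinor coefficients."""


@dataclass(frozen=True)
class TimeSeries:
    """Tidy rhythm observations: value per (time, replicate).

    ``times_h`` are hours post-synchronisation (e.g. post serum shock or
    Zeitgeber time).  At least 4 distinct times are recommended for a
    well-conditioned cosinor fit; fewer than 3 is a hard error at fit
    time.
    """

    times_h: np.ndarray
    values: np.ndarray
    replicate: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ParameterError("times_h and values must be 1-D and of equal length")
        if t.size == 0:
            raise ParameterError("time series is empty")
        if not np.all(np.isfinite(t)):
            raise ParameterError("times must be finite")
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "values", v)
        if self.replicate is not None:
            r = np.asarray(self.replicate)
            if r.shape != t.shape:
                raise ParameterError("replicate ids must match times in length")
            object.__setattr__(self, "replicate", r)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        time_col: str = "time_h",
        value_col: str = "value",
        replicate_col: str | None = "replicate",
        label: str = "",
    ) -> "TimeSeries":
        rep = None
        if replicate_col is not None and replicate_col in df.columns:
            rep = df[replicate_col].to_numpy()
        return cls(df[time_col].to_numpy(float), df[value_col].to_numpy(float), rep, label)

    def to_dataframe(self) -> pd.DataFrame:
        out = pd.DataFrame({"time_h": self.times_h, "value": self.values})
        if self.replicate is not None:
            out["replicate"] = self.replicate
        return out

    def __len__(self) -> int:
        return self.times_h.size


def acrophase_hours(beta: float, gamma: float, period_h: float = 24.0) -> float:
    """Peak time (hours in [0, period)) of M + β·cos + γ·sin.

    Returns NaN when β = γ = 0 (a flat curve has no acrophase).
    """
    if period_h <= 0:
        raise ParameterError("period_h must be > 0")
    if beta == 0.0 and gamma == 0.0:
        return math.nan
    phi = math.atan2(gamma, beta) * period_h / (2.0 * math.pi)
    return phi % period_h


class Cosinor:
    """Fixed-period single-component cosinor model.

    Parameters
    ----------
    times_h, values
        Pooled observations (replicates included as separate rows).
    period_h
        Fixed period τ in hours; 24 for circadian analysis.

    Examples
    --------
    >>> t = np.arange(0, 48, 4.0)
    >>> y = 10 + 3 * np.cos(2 * np.pi * (t - 8) / 24)
    >>> res = Cosinor(t, y).fit()
    >>> round(res.amplitude, 9), round(res.acrophase_h, 9)
    (3.0, 8.0)
    """

    def __init__(self, times_h, values, period_h: float = 24.0):
        ts = TimeSeries(np.asarray(times_h, float), np.asarray(values, float))
        if period_h <= 0:
            raise ParameterError("period_h must be > 0")
        self.times_h = ts.times_h
        self.values = ts.values
        self.period_h = float(period_h)
        n_distinct = np.unique(self.times_h).size
        if n_distinct < 3:
            raise SingularDesignError(
                f"cosinor needs >= 3 distinct times (4+ recommended); got {n_distinct}"
            )

    @classmethod
    def from_timeseries(cls, ts: TimeSeries, period_h: float = 24.0) -> "Cosinor":
        return cls(ts.times_h, ts.values, period_h)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        time_col: str = "time_h",
        value_col: str = "value",
        period_h: float = 24.0,
    ) -> "Cosinor":
        return cls(df[time_col].to_numpy(float), df[value_col].to_numpy(float), period_h)

    def design_matrix(self, times_h: np.ndarray | None = None) -> np.ndarray:
        t = self.times_h if times_h is None else np.asarray(times_h, float)
        w = 2.0 * np.pi * t / self.period_h
        return np.column_stack([np.ones_like(t), np.cos(w), np.sin(w)])

    def fit(self) -> "CosinorResults":
        """OLS fit; rank-deficient harmonic columns get coefficient 0."""
        X = self.design_matrix()
        y = self.values
        n = y.size
        # rank-revealing solve: minimum-norm solution zeroes coefficients of
        # degenerate columns (e.g. sin == 0 under 12-h sampling of a 24-h period)
        coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        if rank < 2:
            raise SingularDesignError("time design identifies no harmonic component")
        if np.ptp(y) == 0.0:  # constant data: flat fit, amplitude exactly 0
            coef = np.array([y[0], 0.0, 0.0])
        fitted = X @ coef
        resid = y - fitted
        ss_resid = float(resid @ resid)
        ss_total = float(np.sum((y - y.mean()) ** 2))
        XtX_pinv = np.linalg.pinv(X.T @ X)
        dof = n - rank
        sigma2 = ss_resid / dof if dof > 0 else math.nan
        bse = np.sqrt(np.clip(np.diag(XtX_pinv) * sigma2, 0, None)) if dof > 0 else np.full(3, np.nan)
        return CosinorResults(
            model=self,
            params=coef,
            bse=bse,
            rank=int(rank),
            ss_resid=ss_resid,
            ss_total=ss_total,
            nobs=n,
            fittedvalues=fitted,
            resid=resid,
        )


@dataclass
class CosinorResults:
    """Estimates and diagnostics from :meth:`Cosinor.fit`."""

    model: Cosinor
    params: np.ndarray  # (mesor, beta, gamma)
    bse: np.ndarray
    rank: int
    ss_resid: float
    ss_total: float
    nobs: int
    fittedvalues: np.ndarray
    resid: np.ndarray
    _p: float | None = field(default=None, repr=False)

    @property
    def period_h(self) -> float:
        return self.model.period_h

    @property
    def mesor(self) -> float:
        return float(self.params[0])

    @property
    def beta(self) -> float:
        return float(self.params[1])

    @property
    def gamma(self) -> float:
        return float(self.params[2])

    @property
    def amplitude(self) -> float:
        """A = sqrt(β² + γ²), distance from mesor to fitted peak."""
        return math.hypot(self.beta, self.gamma)

    @property
    def acrophase_h(self) -> float:
        """Fitted peak time in [0, period); NaN for a flat fit."""
        return acrophase_hours(self.beta, self.gamma, self.period_h)

    @property
    def df_num(self) -> int:
        return self.rank - 1

    @property
    def df_resid(self) -> int:
        return self.nobs - self.rank

    @property
    def p_zero_amplitude(self) -> float:
        """p-value of the F test of H₀: amplitude = 0 (β = γ = 0)."""
        if self._p is None:
            self._p = zero_amplitude_test(self)
        return self._p

    def predict(self, times_h) -> np.ndarray:
        return self.model.design_matrix(np.asarray(times_h, float)) @ self.params

    def summary(self) -> str:
        lines = [
            "Cosinor regression results",
            "=" * 46,
            f"{'n observations':<24}{self.nobs:>12}",
            f"{'period (h)':<24}{self.period_h:>12.4g}",
            f"{'design rank':<24}{self.rank:>12}",
            "-" * 46,
            f"{'coef':<10}{'estimate':>12}{'std err':>12}",
            f"{'mesor':<10}{self.mesor:>12.5g}{self.bse[0]:>12.4g}",
            f"{'beta':<10}{self.beta:>12.5g}{self.bse[1]:>12.4g}",
            f"{'gamma':<10}{self.gamma:>12.5g}{self.bse[2]:>12.4g}",
            "-" * 46,
            f"{'amplitude':<24}{self.amplitude:>12.5g}",
            f"{'acrophase (h)':<24}{self.acrophase_h:>12.5g}",
            f"{'p (zero amplitude)':<24}{self.p_zero_amplitude:>12.4g}",
            f"{'residual SS':<24}{self.ss_resid:>12.5g}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None, n_curve: int = 241):
        """Scatter of the observations with the fitted cosine overlaid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t, y = self.model.times_h, self.model.values
        ax.plot(t, y, "o", color="0.3", label="observed")
        tt = np.linspace(t.min(), t.max(), n_curve)
        ax.plot(tt, self.predict(tt), "-", color="crimson", label="cosinor fit")
        ax.set_xlabel("time (h)")
        ax.set_ylabel("value")
        ax.legend(frameon=False)
        return ax


def zero_amplitude_test(fit: CosinorResults) -> float:
    """F test of a flat midline against the fitted cosinor.

    Constant data (zero total SS) have amplitude 0 by construction and
    are assigned p = 1.  A perfect rhythmic fit (zero residual SS with
    nonzero amplitude) underflows; p is then reported as the floor 1e-15.
    """
    q = fit.df_num
    dof = fit.df_resid
    if dof <= 0:
        raise ParameterError(f"zero-amplitude test needs n > {fit.rank} observations")
    if fit.ss_total == 0.0:
        return 1.0
    if fit.ss_resid == 0.0:
        return P_UNDERFLOW_FLOOR
    f = ((fit.ss_total - fit.ss_resid) / q) / (fit.ss_resid / dof)
    p = float(stats.f.sf(f, q, dof))
    return max(p, P_UNDERFLOW_FLOOR)


# ---------------------------------------------------------------------------
# JTK-style nonparametric test
# ---------------------------------------------------------------------------


@dataclass
class JTKResult:
    """Outcome of the fixed-period JTK-style scan over candidate phases."""

    period_h: float
    best_phase_h: float
    tau: float
    p_adjusted: float
    table: pd.DataFrame  # columns: phase_h, tau, p
    tie_flag: bool = False

    @property
    def n_phases(self) -> int:
        return len(self.table)


def _phase_step_default(times_h: np.ndarray) -> float:
    diffs = np.diff(np.unique(times_h))
    diffs = diffs[diffs > 0]
    if diffs.size == 0:
        raise ParameterError("cannot infer phase step from a single time point")
    return float(np.min(diffs))


def jtk_test(
    ts: TimeSeries | pd.DataFrame,
    period_h: float = 24.0,
    phase_step_h: float | None = None,
) -> JTKResult:
    """Rank-correlation rhythm test against phase-shifted cosine references.

    For each candidate acrophase φ on a grid of spacing ``phase_step_h``
    (default: the sampling interval), Kendall's tau is computed between
    the observations and cos(2π(t−φ)/τ) evaluated at the observation
    times, with a one-sided (concordance) p-value from the exact Kendall
    null when n ≤ 9 and no ties are present, otherwise from the normal
    approximation.  The reported p is the per-phase minimum multiplied by
    the number of phases (Bonferroni), capped at 1.
    """
    if isinstance(ts, pd.DataFrame):
        ts = TimeSeries.from_dataframe(ts)
    t, y = ts.times_h, ts.values
    if t.size < 6:
        raise ParameterError(f"jtk_test needs >= 6 observations, got {t.size}")
    if period_h <= 0:
        raise ParameterError("period_h must be > 0")
    step = _phase_step_default(t) if phase_step_h is None else float(phase_step_h)
    if step <= 0:
        raise ParameterError("phase_step_h must be > 0")
    phases = np.arange(0.0, period_h, step)

    if np.all(y == y[0]):
        table = pd.DataFrame({"phase_h": phases, "tau": np.nan, "p": 1.0})
        return JTKResult(period_h, math.nan, math.nan, 1.0, table, tie_flag=True)

    rows = []
    for phi in phases:
        # fold to one period and round: reference values equal in exact
        # arithmetic must be exact ties, and tie structure must not drift
        # across phases (tau-b tie corrections are rank-sensitive to 1 ulp)
        ref = np.round(np.cos(2.0 * np.pi * ((t - phi) % period_h) / period_h), 12)
        has_ties = np.unique(y).size < y.size or np.unique(ref).size < ref.size
        method = "exact" if (t.size <= 9 and not has_ties) else "asymptotic"
        tau, p = stats.kendalltau(ref, y, method=method, alternative="greater")
        if math.isnan(tau):  # degenerate reference (should not occur on a phase grid)
            tau, p = 0.0, 1.0
        rows.append((phi, float(tau), float(p)))
    table = pd.DataFrame(rows, columns=["phase_h", "tau", "p"])
    best = int(np.argmin(table["p"].to_numpy()))
    p_adj = min(1.0, float(table["p"].iloc[best]) * len(table))
    return JTKResult(
        period_h=period_h,
        best_phase_h=float(table["phase_h"].iloc[best]),
        tau=float(table["tau"].iloc[best]),
        p_adjusted=p_adj,
        table=table,
    )


# ---------------------------------------------------------------------------
# Batch interface over tidy tables
# ---------------------------------------------------------------------------


def batch_rhythm(
    df: pd.DataFrame,
    analyte_col: str = "analyte",
    time_col: str = "time_h",
    value_col: str = "value",
    period_h: float = 24.0,
    method: str = "cosinor",
    alpha: float = 0.05,
    adjust_bh: bool = False,
) -> pd.DataFrame:
    """Per-analyte rhythm report over a tidy (analyte, time, value) table.

    Duplicated rows per analyte/time are treated as replicates and pooled.
    Analytes with too few observations are reported with status
    ``insufficient data`` instead of being dropped.  ``method`` selects
    which p-value drives the ``rhythmic`` flag: ``cosinor``, ``jtk`` or
    ``both`` (both must reject).  With ``adjust_bh`` the driving p-values
    are Benjamini–Hochberg adjusted across analytes before flagging.
    """
    if method not in ("cosinor", "jtk", "both"):
        raise ParameterError(f"unknown method {method!r}")
    records = []
    for analyte, sub in df.groupby(analyte_col, sort=True):
        row: dict = {"analyte": analyte, "n": len(sub), "status": "ok"}
        ts = TimeSeries(sub[time_col].to_numpy(float), sub[value_col].to_numpy(float))
        try:
            res = Cosinor.from_timeseries(ts, period_h).fit()
            row.update(
                mesor=res.mesor,
                amplitude=res.amplitude,
                acrophase_h=res.acrophase_h,
                p_cosinor=res.p_zero_amplitude,
            )
        except ParameterError:
            row["status"] = "insufficient data"
        if method in ("jtk", "both") and row["status"] == "ok":
            try:
                jtk = jtk_test(ts, period_h)
                row.update(p_jtk=jtk.p_adjusted, jtk_phase_h=jtk.best_phase_h)
            except ParameterError:
                row["status"] = "insufficient data"
        records.append(row)
    out = pd.DataFrame(records)
    if out.empty:
        return out

    ok = out["status"] == "ok"
    for col in ("p_cosinor", "p_jtk"):
        if col not in out.columns:
            out[col] = np.nan

    def _driver(frame: pd.DataFrame) -> pd.Series:
        if method == "cosinor":
            return frame["p_cosinor"]
        if method == "jtk":
            return frame["p_jtk"]
        return frame[["p_cosinor", "p_jtk"]].max(axis=1)

    pvals = _driver(out).where(ok)
    if adjust_bh and ok.any():
        p = pvals[ok].to_numpy()
        order = np.argsort(p)
        m = p.size
        adj = np.empty(m)
        prev = 1.0
        for i in range(m - 1, -1, -1):
            prev = min(prev, p[order[i]] * m / (i + 1))
            adj[order[i]] = prev
        pvals.loc[ok[ok].index] = adj
    out["p_driver"] = pvals
    out["rhythmic"] = (pvals < alpha).fillna(False)
    return out
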