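"""Carbon-budget closure, mortality/turnover rates, smoothing, equilibrium stats.

The woody carbon budget of a demographic run is considered closed when the
annual stock change equals the net woody flux:

    residual(t) = Cwood(t+1) - Cwood(t) - (WBgrowth(t) - Cmort(t))

The fractional mortality rate is cmort_rate = 100 * Cmort / Cwood (% yr-1)
and the woody turnover time is tau = Cwood / Cmort (yr), so that
tau * cmort_rate = 100 wherever both are defined. Time-series analyses use a
left-aligned k-yr rolling mean (default 30 yr, matching a repeated 30-yr
climate cycle) after discarding the first 30 yr following spin-up; the
mature-forest comparison uses unsmoothed annual values over an equilibrium
window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MissingColumnError, StandSeries

__all__ = [
    "BudgetReport",
    "RateSeries",
    "check_budget",
    "mortality_rate",
    "turnover_time",
    "compute_rates",
    "smooth_left",
    "drop_post_spinup",
    "equilibrium_stats",
    "DEFAULT_TOLERANCE_SYNTHETIC",
    "DEFAULT_TOLERANCE_EXTERNAL",
]

log = logging.getLogger(__name__)

#: default relative budget tolerances: generated data must close to rounding;
#: external model archives are granted percent-level drift.
DEFAULT_TOLERANCE_SYNTHETIC = 1e-6
DEFAULT_TOLERANCE_EXTERNAL = 1e-2


@dataclass
class BudgetReport:
    """Per-year budget residuals and the pass/fail verdict."""

    years: np.ndarray            # year t of each residual (t -> t+1 step)
    residual: np.ndarray         # kgC m-2
    max_abs_residual: float
    relative_drift: float        # max |residual| / max Cwood
    tolerance: float
    passed: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"year": self.years, "residual": self.residual})


def check_budget(series: StandSeries,
                 tolerance: float = DEFAULT_TOLERANCE_SYNTHETIC) -> BudgetReport:
    """Verify demographic woody-carbon closure of an annual stand series."""
    if len(series) < 2:
        raise ValueError("budget check needs at least 2 years")
    cwood = series.column("cwood")
    growth = series.column("wbgrowth")
    mort = series.column("cmort")
    residual = cwood[1:] - cwood[:-1] - (growth[:-1] - mort[:-1])
    max_abs = float(np.max(np.abs(residual)))
    scale = float(np.max(cwood))
    drift = max_abs / scale if scale > 0 else np.inf if max_abs > 0 else 0.0
    return BudgetReport(
        years=series.years[:-1],
        residual=residual,
        max_abs_residual=max_abs,
        relative_drift=drift,
        tolerance=tolerance,
        passed=bool(drift <= tolerance),
    )


@dataclass
class RateSeries:
    """Annual demographic rates: cmort_rate (% yr-1), tau (yr), WBgrowth.

    Years with Cwood = 0 are flagged undefined (NaN rate) rather than
    dropped; years with Cmort = 0 carry an explicitly infinite turnover
    time. ``smoothed``/``window`` record whether a rolling mean was applied.
    """

    data: pd.DataFrame           # columns: year, cmort_rate, tau, wbgrowth
    smoothed: bool = False
    window: int | None = None
    undefined_years: tuple[int, ...] = ()
    infinite_tau_years: tuple[int, ...] = ()

    @property
    def years(self) -> np.ndarray:
        return self.data["year"].to_numpy()

    def column(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy(dtype=float)

    def smooth(self, k: int = 30) -> "RateSeries":
        """Left-aligned k-yr rolling mean of the rate and growth columns."""
        rate = smooth_left(self.column("cmort_rate"), k)
        growth = smooth_left(self.column("wbgrowth"), k)
        years = self.years[: len(rate)]
        with np.errstate(divide="ignore"):
            tau = np.where(rate > 0, 100.0 / rate, np.inf)
        df = pd.DataFrame({"year": years, "cmort_rate": rate,
                           "tau": tau, "wbgrowth": growth})
        return RateSeries(df, smoothed=True, window=k)

    def drop_post_spinup(self, n: int = 30) -> "RateSeries":
        if len(self.data) <= n:
            raise ValueError(f"series has <= {n} years; nothing would remain")
        df = self.data.iloc[n:].reset_index(drop=True)
        return RateSeries(df, smoothed=self.smoothed, window=self.window,
                          undefined_years=self.undefined_years,
                          infinite_tau_years=self.infinite_tau_years)


def compute_rates(series: StandSeries) -> RateSeries:
    """Fractional mortality rate and turnover time from fluxes and stocks."""
    cwood = series.column("cwood")
    cmort = series.column("cmort")
    growth = series.column("wbgrowth")
    years = series.years
    undefined = cwood <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(undefined, np.nan, 100.0 * cmort / cwood)
        tau = np.where(undefined, np.nan,
                       np.where(cmort > 0, cwood / np.maximum(cmort, 1e-300),
                                np.inf))
    n_undef = int(undefined.sum())
    if n_undef:
        log.warning("mortality rate undefined (Cwood = 0) for %d years", n_undef)
    inf_years = tuple(int(y) for y in years[np.isinf(tau)])
    if inf_years:
        log.info("turnover time infinite (Cmort = 0) for %d years", len(inf_years))
    df = pd.DataFrame({"year": years, "cmort_rate": rate, "tau": tau,
                       "wbgrowth": growth})
    return RateSeries(df, undefined_years=tuple(int(y) for y in years[undefined]),
                      infinite_tau_years=inf_years)


def mortality_rate(series: StandSeries) -> RateSeries:
    """cmort_rate = 100 * Cmort / Cwood (% yr-1), with turnover alongside."""
    return compute_rates(series)


def turnover_time(series: StandSeries) -> RateSeries:
    """tau = Cwood / Cmort (yr), annual and unsmoothed."""
    return compute_rates(series)


def smooth_left(values, k: int = 30) -> np.ndarray:
    """Left-aligned rolling mean: out[t] = mean(values[t : t + k]).

    Incomplete trailing windows are dropped, so the output has
    ``len(values) - k + 1`` entries.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise ValueError("expected a 1-d series")
    if k < 1:
        raise ValueError("window length must be >= 1")
    if len(v) < k:
        raise ValueError(f"series of length {len(v)} is shorter than k={k}")
    window = np.lib.stride_tricks.sliding_window_view(v, k)
    return window.mean(axis=1)


def drop_post_spinup(values, n: int = 30):
    """Remove the first n years immediately following spin-up."""
    if isinstance(values, RateSeries):
        if n == 0:
            return values
        return values.drop_post_spinup(n)
    v = np.asarray(values)
    if len(v) <= n:
        raise ValueError(f"series has <= {n} entries; nothing would remain")
    return v[n:]


def equilibrium_stats(series, window: tuple[int, int]) -> pd.DataFrame:
    """Mean/sd/quantiles of annual (unsmoothed) values over a year window.

    ``series`` may be a StandSeries, RateSeries or DataFrame with a ``year``
    column; the window is inclusive on both ends. Non-finite entries (e.g.
    infinite turnover times) are excluded per variable, with the excluded
    count reported in the ``n_nonfinite`` column.
    """
    if isinstance(series, (StandSeries, RateSeries)):
        df = series.data
    else:
        df = series
    if "year" not in df.columns:
        raise MissingColumnError("year", "equilibrium statistics")
    lo, hi = window
    if lo > hi:
        raise ValueError("empty equilibrium window")
    sel = df[(df["year"] >= lo) & (df["year"] <= hi)]
    if sel.empty:
        raise ValueError("equilibrium window outside the series span")
    rows = {}
    for col in sel.columns:
        if col == "year" or not np.issubdtype(sel[col].dtype, np.number):
            continue
        v = sel[col].to_numpy(dtype=float)
        finite = np.isfinite(v)
        n_bad = int((~finite).sum())
        if n_bad:
            log.info("excluding %d non-finite values of %s from equilibrium "
                     "statistics", n_bad, col)
        vv = v[finite]
        if len(vv) == 0:
            rows[col] = dict(mean=np.nan, sd=np.nan, p10=np.nan, median=np.nan,
                             p90=np.nan, n=0, n_nonfinite=n_bad)
            continue
        rows[col] = dict(
            mean=float(np.mean(vv)),
            sd=float(np.std(vv, ddof=1)) if len(vv) > 1 else 0.0,
            p10=float(np.percentile(vv, 10)),
            median=float(np.percentile(vv, 50)),
            p90=float(np.percentile(vv, 90)),
            n=len(vv),
            n_nonfinite=n_bad,
        )
    return pd.DataFrame.from_dict(rows, orient="index")
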