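"""Self-thinning detection and slope estimation in mass-density space.

Crowded even-aged stands shed stems along a power law between mean individual
biomass M and stem density N, ``M = k * N**p``; in log-log "thinning space"
the trajectory is a line of slope p. This module transforms an annual stand
series (plus its size structure) into thinning space, isolates the years in
which the stand is actually thinning — by one of four detection methods — and
fits the slope by ordinary least squares:

* Method 1: years whose *dedicated self-thinning mortality-rate diagnostic*
  strictly exceeds its 95th percentile over the whole run (for models that
  report such a diagnostic).
* Method 2: years whose *total* fractional mortality rate lies in the top 5%
  of annual values, same percentile convention.
* Method 3: the consecutive run of years spanning the maximum density decline
  (from the high-density to the low-density extreme of the trajectory).
* Method 4: a literal, manually chosen year range; always wins when supplied.

Small trees are excluded before the transform (classes below 10 cm dbh),
because suppressed saplings and fresh recruits distort the mean individual
mass of the thinning cohort. The fitted slope is conventionally compared
against the band [-2.612, -1]: the steepest slope observed in managed-stand
compilations and the theoretically shallowest one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io import MissingColumnError, SizeStructure, StandSeries
from .simulate import M2_PER_HA

__all__ = [
    "SLOPE_LOWER_BOUND",
    "SLOPE_UPPER_BOUND",
    "ThinningResult",
    "to_thinning_space",
    "detect_m1",
    "detect_m2",
    "detect_m3",
    "detect_m4",
    "fit_slope",
    "SelfThinningModel",
    "SelfThinningResults",
]

log = logging.getLogger(__name__)

#: steepest observed and shallowest theoretical self-thinning exponents;
#: the classical reference value is -3/2, between the two.
SLOPE_LOWER_BOUND = -2.612
SLOPE_UPPER_BOUND = -1.0

#: dbh classes with lower edge below this (cm) are dropped before the
#: thinning-space transform.
DEFAULT_MIN_DBH = 10.0


@dataclass
class ThinningResult:
    """Fitted self-thinning line for one detection-method run."""

    method: int                       # 1..4
    selected_years: tuple[int, ...]
    duration: int
    slope: float
    intercept: float                  # ln k
    r_squared: float
    slope_stderr: float
    within_bounds: bool               # slope in [-2.612, -1], inclusive
    used_size_structure: bool = True

    @property
    def k(self) -> float:
        return float(np.exp(self.intercept))


def to_thinning_space(series: StandSeries,
                      structure: SizeStructure | None = None,
                      min_dbh: float = DEFAULT_MIN_DBH) -> pd.DataFrame:
    """Per-year (lnN, lnM) points: ln stem density and ln mean individual mass.

    With a size structure, N and the aboveground carbon are summed over the
    dbh classes whose lower edge is at or above ``min_dbh``; mean individual
    mass (kgC per tree) is the summed per-m2 carbon times 1e4 m2/ha divided
    by N. Without a structure the stand totals are used and the deviation is
    recorded in the frame's ``attrs`` (the small-tree exclusion cannot be
    applied; some models cannot output the size split).

    Years with zero density after filtering are skipped with a log entry.
    """
    if structure is not None:
        scheme = structure.scheme
        keep = [lab for lab in scheme.labels
                if scheme.lower_edge(lab) >= min_dbh]
        sub = structure.data[structure.data["class_label"].isin(keep)]
        agg = sub.groupby("year")[["nstem_size", "cwood_size"]].sum()
        n = agg["nstem_size"].to_numpy(dtype=float)
        c = agg["cwood_size"].to_numpy(dtype=float)
        years = agg.index.to_numpy()
        used_structure = True
    else:
        years = series.years
        n = series.column("nstem")
        c = series.column("cwood")
        used_structure = False
        log.warning("no size structure supplied: thinning space computed "
                    "from stand totals without the %.0f cm exclusion", min_dbh)
    ok = n > 0
    n_skipped = int((~ok).sum())
    if n_skipped:
        log.info("skipping %d years with zero stem density in thinning space",
                 n_skipped)
    with np.errstate(divide="ignore", invalid="ignore"):
        ln_n = np.log(n[ok])
        mass = c[ok] * M2_PER_HA / n[ok]
        ln_m = np.log(mass)
    finite = np.isfinite(ln_n) & np.isfinite(ln_m)
    points = pd.DataFrame({
        "year": years[ok][finite].astype(int),
        "lnN": ln_n[finite],
        "lnM": ln_m[finite],
    })
    points.attrs["used_size_structure"] = used_structure
    points.attrs["min_dbh"] = min_dbh if used_structure else None
    return points


def _percentile95(values: np.ndarray) -> float:
    # linear-interpolation percentile (R type 7), numpy's default
    return float(np.percentile(values, 95))


def detect_m1(selfthin_rate: pd.Series | np.ndarray,
              years: np.ndarray | None = None) -> np.ndarray:
    """Method 1: years whose self-thinning mortality-rate diagnostic strictly
    exceeds the 95th percentile of that diagnostic over the whole run."""
    if isinstance(selfthin_rate, pd.Series):
        if years is None:
            years = selfthin_rate.index.to_numpy()
        selfthin_rate = selfthin_rate.to_numpy(dtype=float)
    else:
        selfthin_rate = np.asarray(selfthin_rate, dtype=float)
        if years is None:
            years = np.arange(len(selfthin_rate))
    thr = _percentile95(selfthin_rate)
    return np.asarray(years)[selfthin_rate > thr]


def detect_m2(cmort_rate: pd.Series | np.ndarray,
              years: np.ndarray | None = None) -> np.ndarray:
    """Method 2: years with the top 5% of the *total* mortality rate."""
    if isinstance(cmort_rate, pd.Series):
        if years is None:
            years = cmort_rate.index.to_numpy()
        cmort_rate = cmort_rate.to_numpy(dtype=float)
    else:
        cmort_rate = np.asarray(cmort_rate, dtype=float)
        if years is None:
            years = np.arange(len(cmort_rate))
    thr = _percentile95(cmort_rate)
    sel = np.asarray(years)[cmort_rate > thr]
    if len(sel) == 0:
        log.warning("method 2 selected no years (rate series may be constant)")
    return sel


def detect_m3(points: pd.DataFrame) -> np.ndarray:
    """Method 3: the consecutive run spanning the maximum density decline.

    Scans all ordered pairs (i, j), i < j, of thinning-space points and
    selects the run [i..j] maximising the density drop lnN[i] - lnN[j];
    ties prefer the earliest start and then the longest run. Runs with no
    decline yield an empty selection with a warning.
    """
    if len(points) < 3:
        raise ValueError("method 3 needs at least 3 thinning-space points")
    ln_n = points["lnN"].to_numpy()
    years = points["year"].to_numpy()
    best = (-np.inf, 0, 0)   # (drop, start, stop)
    run_max = ln_n[0]
    run_start = 0
    for j in range(1, len(ln_n)):
        drop = run_max - ln_n[j]
        better = (drop > best[0] + 1e-15
                  or (abs(drop - best[0]) <= 1e-15
                      and (run_start < best[1]
                           or (run_start == best[1] and j > best[2]))))
        if better:
            best = (drop, run_start, j)
        if ln_n[j] > run_max:
            run_max = ln_n[j]
            run_start = j
    drop, i, j = best
    if drop <= 0:
        log.warning("method 3: density never declines; empty selection")
        return np.asarray([], dtype=int)
    return years[i:j + 1]


def detect_m4(year_range: tuple[int, int],
              years: np.ndarray | None = None) -> np.ndarray:
    """Method 4: a literal manual year range [start, end], inclusive.

    Provenance is the caller's responsibility; the range must not be
    reversed and, when the available years are supplied, must overlap them.
    """
    a, b = year_range
    if a > b:
        raise ValueError(f"reversed or empty manual range ({a}, {b})")
    sel = np.arange(int(a), int(b) + 1)
    if years is not None:
        avail = np.asarray(years)
        sel = sel[np.isin(sel, avail)]
        if len(sel) == 0:
            raise ValueError("manual range lies outside the series")
    return sel


def fit_slope(points: pd.DataFrame, method: int = 0,
              selected_years: np.ndarray | None = None) -> ThinningResult:
    """OLS fit of lnM on lnN over the selected years.

    Slope is the self-thinning exponent p and intercept is ln k; both are
    invariant to mass-unit rescaling up to the intercept shift. Requires at
    least 3 points with non-degenerate density variance.
    """
    if selected_years is not None:
        pts = points[points["year"].isin(np.asarray(selected_years))]
    else:
        pts = points
    if len(pts) < 3:
        raise ValueError("insufficient thinning trajectory: fewer than 3 points")
    x = pts["lnN"].to_numpy()
    y = pts["lnM"].to_numpy()
    if np.ptp(x) == 0 or np.var(x) == 0:
        raise ValueError("insufficient thinning trajectory: no density variance")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    slope = float(res.params[1])
    intercept = float(res.params[0])
    stderr = float(res.bse[1])
    r2 = float(res.rsquared)
    # boundary values are inclusive; allow rounding error at the edges
    within = (SLOPE_LOWER_BOUND - 1e-9) <= slope <= (SLOPE_UPPER_BOUND + 1e-9)
    return ThinningResult(
        method=method,
        selected_years=tuple(int(y_) for y_ in pts["year"]),
        duration=int(len(pts)),
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        slope_stderr=stderr,
        within_bounds=bool(within),
        used_size_structure=bool(points.attrs.get("used_size_structure", True)),
    )


class SelfThinningModel:
    """Self-thinning slope estimator for one stand run.

    Parameters
    ----------
    series : StandSeries
        Annual stand-level output (must carry nstem and cwood).
    structure : SizeStructure, optional
        Per-class stems and carbon; enables the small-tree exclusion.
    min_dbh : float
        Lower dbh edge (cm) below which classes are dropped (default 10).

    ``fit`` selects the thinning period by one of the four methods and
    returns a :class:`SelfThinningResults` carrying the exponent, its
    standard error, r-squared and the selected years.
    """

    def __init__(self, series: StandSeries,
                 structure: SizeStructure | None = None,
                 min_dbh: float = DEFAULT_MIN_DBH):
        self.series = series
        self.structure = structure
        self.min_dbh = min_dbh
        self.points = to_thinning_space(series, structure, min_dbh)

    def fit(self, method: int = 3,
            manual_range: tuple[int, int] | None = None) -> "SelfThinningResults":
        if manual_range is not None:
            method = 4
        if method == 1:
            if "selfthin_mort_rate" in self.series.absent \
                    or "selfthin_mort_rate" not in self.series.data.columns:
                raise MissingColumnError(
                    "selfthin_mort_rate",
                    "method 1 needs a self-thinning mortality diagnostic; "
                    "use methods 2-4 instead")
            rate = self.series.column("selfthin_mort_rate")
            years = detect_m1(rate, self.series.years)
        elif method == 2:
            from .demographics import compute_rates
            rates = compute_rates(self.series)
            years = detect_m2(rates.column("cmort_rate"), rates.years)
        elif method == 3:
            years = detect_m3(self.points)
        elif method == 4:
            if manual_range is None:
                raise ValueError("method 4 needs an explicit year range")
            years = detect_m4(manual_range, self.points["year"].to_numpy())
        else:
            raise ValueError(f"unknown detection method {method!r}")
        result = fit_slope(self.points, method=method, selected_years=years)
        return SelfThinningResults(self, result)


class SelfThinningResults:
    """Results wrapper: exponent estimate, uncertainty and diagnostics."""

    def __init__(self, model: SelfThinningModel, result: ThinningResult):
        self.model = model
        self._result = result

    @property
    def result(self) -> ThinningResult:
        return self._result

    @property
    def slope(self) -> float:
        return self._result.slope

    @property
    def intercept(self) -> float:
        return self._result.intercept

    @property
    def k(self) -> float:
        return self._result.k

    @property
    def rsquared(self) -> float:
        return self._result.r_squared

    @property
    def duration(self) -> int:
        return self._result.duration

    @property
    def selected_years(self) -> tuple[int, ...]:
        return self._result.selected_years

    def to_frame(self) -> pd.DataFrame:
        r = self._result
        return pd.DataFrame([{
            "method": r.method,
            "duration": r.duration,
            "slope": r.slope,
            "slope_stderr": r.slope_stderr,
            "intercept_lnk": r.intercept,
            "r_squared": r.r_squared,
            "within_bounds": r.within_bounds,
            "used_size_structure": r.used_size_structure,
            "first_year": min(r.selected_years),
            "last_year": max(r.selected_years),
        }])

    def summary(self) -> str:
        r = self._result
        lines = [
            "Self-thinning line fit (OLS of lnM on lnN)",
            "------------------------------------------",
            f"detection method     : {r.method}",
            f"selected years       : {min(r.selected_years)}-"
            f"{max(r.selected_years)}  (n = {r.duration})",
            f"slope p              : {r.slope:.6f}  (se {r.slope_stderr:.2e})",
            f"intercept ln k       : {r.intercept:.6f}",
            f"r-squared            : {r.r_squared:.6f}",
            f"within [-2.612, -1]  : {r.within_bounds}",
            f"size structure used  : {r.used_size_structure}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Thinning-space scatter with the fitted line (needs matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        pts = self.model.points
        ax.plot(pts["lnN"], pts["lnM"], ".", color="0.6", label="all years")
        sel = pts[pts["year"].isin(self.selected_years)]
        ax.plot(sel["lnN"], sel["lnM"], "o", label="thinning period")
        xs = np.linspace(sel["lnN"].min(), sel["lnN"].max(), 20)
        ax.plot(xs, self.intercept + self.slope * xs, "-",
                label=f"slope {self.slope:.2f}")
        ax.set_xlabel("ln N (stems ha$^{-1}$)")
        ax.set_ylabel("ln M (kgC per tree)")
        ax.legend()
        return ax
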