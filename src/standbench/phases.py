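"""Forest recovery-phase classification and phase-aligned comparison.

Regrowth after a stand-replacing disturbance progresses through four
qualitative phases, each recognisable from a small set of stand variables
acting together:

* ``open_grass``    — open canopy with a substantial grass share of C_veg and
  little tree-tree competition;
* ``open_growth``   — open canopy, woody share rising rapidly, stem numbers
  roughly stable;
* ``closed_thinning`` — canopy closed (CA near 10 000 m2 ha-1), a mortality
  spike and a steep stem-number decline as self-thinning removes suppressed
  individuals;
* ``closed_late``   — mortality back near its equilibrium level, stem numbers
  flattened; the stand drifts towards a dynamic equilibrium.

Different demographic models begin regrowth at different phases; the *start
group* labels this: P1 starts in grass coexistence, P2 in open-canopy
growth, P3 directly in closed-canopy self-thinning. Aligning runs on a
common phase onset makes their growth and mortality dynamics comparable.

The phase definitions are qualitative; every numeric threshold here is a
configuration value with a documented default, and the mortality spike is
judged against the run's own equilibrium tail so the classifier is
insensitive to a model's absolute rate level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .demographics import RateSeries
from .io import MissingColumnError, StandSeries

__all__ = [
    "PHASES",
    "PhaseConfig",
    "PhaseTimeline",
    "classify_phases",
    "start_group",
    "align_on_phase",
]

log = logging.getLogger(__name__)

PHASES = ("open_grass", "open_growth", "closed_thinning", "closed_late")
_RANK = {name: i for i, name in enumerate(PHASES)}


@dataclass
class PhaseConfig:
    """Thresholds for the rule-based phase classifier.

    grass_frac_min : grass share of C_veg above which the stand is still in
        grass coexistence (default 0.10).
    ca_closure : canopy area at which the canopy counts as closed
        (default 10 000 m2 ha-1, i.e. crowns covering the ground once over).
    mort_spike_factor : multiple of the equilibrium-tail mean mortality rate
        that counts as a self-thinning spike (default 1.5); the same factor
        bounds the band for having returned to equilibrium.
    equilibrium_tail : number of final years whose mean mortality rate serves
        as the equilibrium reference (default 100).
    trend_halfwidth / flat_tol : the stem-number decline and flattening tests
        compare 5-yr centred rolling means two years apart; a relative change
        smaller than ``flat_tol`` counts as flat (default 0.05, i.e. about
        1%/yr).
    smooth_years : centred smoothing applied to canopy area and grass share
        before thresholding, to keep boundary years stable under noise.
    """

    grass_frac_min: float = 0.10
    ca_closure: float = 10_000.0
    mort_spike_factor: float = 1.5
    equilibrium_tail: int = 100
    trend_halfwidth: int = 2
    flat_tol: float = 0.05
    smooth_years: int = 3

    def __post_init__(self):
        if not (0 < self.grass_frac_min < 1):
            raise ValueError("grass_frac_min must be in (0, 1)")
        for name in ("ca_closure", "mort_spike_factor", "equilibrium_tail"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.mort_spike_factor <= 1:
            raise ValueError("mort_spike_factor must exceed 1")


@dataclass
class PhaseTimeline:
    """Per-year phase labels with onset years and the start group."""

    labels: pd.Series              # index: year, values: phase names
    boundaries: dict               # phase -> onset year (phases present only)
    start_group: str               # "P1" | "P2" | "P3"
    equilibrium_rate: float        # tail-mean cmort_rate used as reference
    notes: tuple[str, ...] = ()

    @property
    def years(self) -> np.ndarray:
        return self.labels.index.to_numpy()

    def onset(self, phase: str) -> int | None:
        return self.boundaries.get(phase)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"year": self.labels.index,
                             "phase": self.labels.to_numpy()})


def _centered_mean(v: np.ndarray, k: int) -> np.ndarray:
    if k <= 1:
        return v.astype(float)
    s = pd.Series(v)
    return s.rolling(k, center=True, min_periods=1).mean().to_numpy()


def classify_phases(series: StandSeries, rates: RateSeries,
                    config: PhaseConfig | None = None) -> PhaseTimeline:
    """Label every year of a run with its recovery phase.

    The classifier is a forward-only state machine over the four phases:
    a year's rule-based candidate can move the state forward but never
    backward; a candidate that would move backward (e.g. a noisy canopy-area
    dip) is forward-filled and logged. Missing grass share starts the
    classification at open_growth with a caveat; missing canopy area (and
    crown area index) is an error.
    """
    cfg = config or PhaseConfig()
    notes: list[str] = []
    years = series.years
    n = len(years)

    if "ca" in series.data.columns:
        ca = _centered_mean(series.column("ca"), cfg.smooth_years)
        closed = ca >= cfg.ca_closure
    elif "cai" in series.data.columns and "cai" not in series.absent:
        cai = _centered_mean(series.column("cai"), cfg.smooth_years)
        closed = cai >= 1.0
        notes.append("canopy closure judged from CAI >= 1 (CA absent)")
    else:
        raise MissingColumnError("ca", "phase classification needs CA or CAI")

    grass = series.grass_fraction()
    if grass is None:
        grass = np.zeros(n)
        notes.append("grass share absent: classification starts at open_growth")
        log.warning("no cveg_frac_grass column; open_grass cannot be detected")
    else:
        grass = _centered_mean(grass, cfg.smooth_years)

    rate = np.asarray(
        pd.Series(rates.column("cmort_rate"), index=rates.years)
        .reindex(years).to_numpy(), dtype=float)

    tail = min(cfg.equilibrium_tail, n)
    tail_rate = rate[-tail:]
    tail_rate = tail_rate[np.isfinite(tail_rate)]
    if len(tail_rate) == 0:
        raise ValueError("no finite mortality rates in the equilibrium tail")
    eq_rate = float(np.mean(tail_rate))
    spike_thr = cfg.mort_spike_factor * eq_rate
    band_lo = (2.0 - cfg.mort_spike_factor) * eq_rate
    band_hi = cfg.mort_spike_factor * eq_rate

    # stem-number trend from 5-yr centred means, compared 2*halfwidth apart
    nstem_s = _centered_mean(series.column("nstem"), 2 * cfg.trend_halfwidth + 1)
    h = cfg.trend_halfwidth
    # centred difference over a 2h-yr span; near the ends the window is
    # shifted, not shrunk, so the trend test keeps its full span (and its
    # noise tolerance) in the first and last years of the run
    idx_lo = np.clip(np.arange(n) - h, 0, max(n - 1 - 2 * h, 0))
    idx_hi = np.minimum(idx_lo + 2 * h, n - 1)
    mid = nstem_s[np.clip(np.arange(n), 0, n - 1)]
    with np.errstate(divide="ignore", invalid="ignore"):
        rel_change = np.where(mid > 0,
                              (nstem_s[idx_hi] - nstem_s[idx_lo]) / mid, 0.0)
    declining = rel_change < -0.005
    # no backward baseline exists in the first trend window: a run that
    # starts mid-thinning shows its spike immediately, so do not demand an
    # observed decline there
    declining[: 2 * h + 1] = True
    flat = np.abs(rel_change) <= cfg.flat_tol

    spike = np.isfinite(rate) & (rate >= spike_thr)
    in_band = np.isfinite(rate) & (rate >= band_lo) & (rate <= band_hi)
    # a self-thinning spike still to come: an open-canopy state must not jump
    # straight to late-successional past it (closure can read a year early
    # under noise, before the mortality spike has begun)
    spike_ahead = np.flip(np.logical_or.accumulate(np.flip(spike)))

    labels = np.empty(n, dtype=object)
    state = None
    n_backward = 0
    for i in range(n):
        if not closed[i]:
            cand = "open_grass" if grass[i] >= cfg.grass_frac_min \
                else "open_growth"
        elif spike[i] and declining[i]:
            cand = "closed_thinning"
        elif in_band[i] and flat[i]:
            cand = "closed_late"
            if ((state is None or _RANK[state] < _RANK["closed_thinning"])
                    and spike_ahead[i]):
                cand = None
        else:
            cand = None   # closed but ambiguous: hold the current state
        if state is None:
            if cand is not None:
                state = cand
            else:
                # closed canopy, no verdict yet: still pre-thinning if a
                # spike lies ahead, otherwise a mature late-successional run
                state = "open_growth" if spike_ahead[i] else "closed_late"
        elif cand is not None:
            if _RANK[cand] >= _RANK[state]:
                state = cand
            else:
                n_backward += 1
        labels[i] = state
    if n_backward:
        notes.append(f"{n_backward} backward phase proposals forward-filled")
        log.info("forward-filled %d backward phase proposals", n_backward)

    boundaries: dict[str, int] = {}
    for i, lab in enumerate(labels):
        if lab not in boundaries:
            boundaries[lab] = int(years[i])

    first = labels[0]
    group = {"open_grass": "P1", "open_growth": "P2",
             "closed_thinning": "P3"}.get(first, "none")
    timeline = PhaseTimeline(
        labels=pd.Series(labels, index=pd.Index(years, name="year"),
                         name="phase"),
        boundaries=boundaries,
        start_group=group,
        equilibrium_rate=eq_rate,
        notes=tuple(notes),
    )
    return timeline


def start_group(timeline: PhaseTimeline,
                rates: RateSeries | None = None) -> str:
    """P1/P2/P3 from the first phase label (pure function of that label)."""
    first = timeline.labels.iloc[0]
    if first == "closed_late":
        raise ValueError("no recovery trajectory present: run starts in the "
                         "late-successional phase")
    return {"open_grass": "P1", "open_growth": "P2",
            "closed_thinning": "P3"}[first]


def align_on_phase(runs: Mapping[str, tuple[PhaseTimeline, pd.DataFrame]],
                   anchor: str = "closed_thinning",
                   ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Time-shift runs so the anchor-phase onset is year 0.

    ``runs`` maps a run name to (timeline, annual table with a ``year``
    column). Returns a long table with ``aligned_year = year - onset`` plus
    the shift applied per run; runs lacking the anchor phase are excluded
    with a log entry.
    """
    if anchor not in PHASES:
        raise ValueError(f"unknown phase {anchor!r}")
    shifts: dict[str, int] = {}
    parts = []
    for name, (timeline, table) in runs.items():
        onset = timeline.onset(anchor)
        if onset is None:
            log.warning("run %s lacks phase %s; excluded from alignment",
                        name, anchor)
            continue
        if "year" not in table.columns:
            raise MissingColumnError("year", f"alignment table for {name}")
        part = table.copy()
        part.insert(0, "run", name)
        part.insert(2, "aligned_year", part["year"] - onset)
        shifts[name] = int(onset)
        parts.append(part)
    if not parts:
        return pd.DataFrame(columns=["run", "year", "aligned_year"]), shifts
    return pd.concat(parts, ignore_index=True), shifts
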