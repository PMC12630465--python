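"""Synthetic cohort-demography generator with exact embedded ground truth.

The generator prescribes a single even-aged woody cohort through four scripted
forest-recovery phases (grass coexistence, open-canopy growth, closed-canopy
self-thinning, late-successional equilibrium) and derives the carbon fluxes so
the woody carbon budget closes *exactly*:

    Cwood(t+1) = Cwood(t) + WBgrowth(t) - Cmort(t)

Within the thinning window the mass-density trajectory obeys the self-thinning
power law M = k * N**p exactly (noise-free), with N declining geometrically;
everything downstream of the generator can therefore be tested against known
values of the exponent p, the intercept k, the phase boundary years and the
start group.

Noise, when requested, is multiplicative lognormal and is applied only to
observational copies (stem density, canopy area, aboveground carbon, the size
structure, PFT shares). The conserved pool and flux columns stay noise-free,
so the budget check always has a clean pass case. One noise factor per year is
shared between a stand-level column and its size-structure counterpart, so the
structure totals remain exactly consistent with the stand series.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .io import (DBH_SCHEME, DbhScheme, SizeStructure, StandSeries,
                 write_key_value)

__all__ = [
    "SimConfig",
    "GroundTruth",
    "PlotStemMap",
    "simulate_stand",
    "simulate_chronosequence",
    "simulate_plot",
]

#: m2 per hectare; converts between per-m2 pools and per-ha densities.
M2_PER_HA = 1.0e4

#: canopy area (m2 ha-1) at which the scripted canopy saturates, slightly
#: above the closure threshold so the closure crossing is sharp.
CA_MAX = 10800.0

#: grass share at which the scripted grass-coexistence phase ends.
GRASS_EXIT_SHARE = 0.10


@dataclass
class SimConfig:
    """Study conditions for one synthetic stand run.

    Defaults describe a 420-yr post-disturbance recovery (the shortest run
    length used for model intercomparison at the sites emulated here), with a
    grass-coexistence phase to year 12, canopy closure at year 48 and
    self-thinning with exponent -3/2 until year 130, after which the stand
    sits in dynamic equilibrium.
    """

    years: int = 420
    seed: int = 0
    # individual allometry  M_ind = a * dbh**b  (kgC per tree, dbh in cm)
    allometry_a: float = 0.15
    allometry_b: float = 2.4
    growth_rate: float = 0.05          # relative dbh increment per yr
    background_mort: float = 0.015     # fraction of Cwood per yr
    thinning_exponent: float = -1.5    # p in M = k * N**p (must be < 0)
    thinning_window: tuple[int, int] | None = None   # defaults to scripted window
    thinning_decline: float = 0.8      # fraction of stems lost across the window
    recruit_mode: str = "restocking"   # "restocking" | "emergent"
    initial_density: float = 2000.0    # stems ha-1
    initial_dbh: float = 1.0           # cm
    initial_grass_frac: float = 0.6    # grass share of C_veg at year 0
    grass_decay_yr: float | None = None  # derived from phase_boundaries if None
    canopy_closure_yr: int | None = None  # defaults to phase_boundaries[1]
    phase_boundaries: tuple[int, int, int] = (12, 48, 130)
    ag_frac: float = 0.75              # aboveground share of Cwood
    noise_sd: float = 0.0              # relative sd of observational noise

    def __post_init__(self):
        b1, b2, b3 = self.phase_boundaries
        if not (0 <= b1 <= b2 <= b3 <= self.years):
            raise ValueError("phase boundaries must be ordered within [0, years]")
        if self.recruit_mode not in ("restocking", "emergent"):
            raise ValueError(f"unknown recruit_mode {self.recruit_mode!r}")
        for name in ("allometry_a", "allometry_b", "growth_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.thinning_exponent >= 0:
            raise ValueError("thinning exponent p must be negative")
        for name in ("background_mort", "initial_grass_frac", "ag_frac",
                     "thinning_decline"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be a fraction in [0, 1]")
        tw = self.thinning_window
        if tw is not None:
            t0, t1 = tw
            if not (0 <= t0 < t1 <= self.years):
                raise ValueError("thinning_window must lie within [0, years]")
            if t0 < self.closure_year:
                raise ValueError(
                    "thinning_window precedes canopy closure: self-thinning "
                    "requires a closed canopy")
        if b1 > 0 and self.initial_grass_frac < GRASS_EXIT_SHARE:
            raise ValueError(
                "a scripted grass-coexistence phase needs initial_grass_frac "
                f">= {GRASS_EXIT_SHARE}")

    @property
    def closure_year(self) -> int:
        return (self.canopy_closure_yr if self.canopy_closure_yr is not None
                else self.phase_boundaries[1])

    @property
    def window(self) -> tuple[int, int]:
        if self.thinning_window is not None:
            return self.thinning_window
        return (self.phase_boundaries[1], self.phase_boundaries[2])


@dataclass
class GroundTruth:
    """Quantities embedded in a generated run, for recovery tests."""

    p: float
    k: float                      # intercept of M_ag = k * N**p, kgC per tree
    phase_boundaries: tuple[int, int, int]
    start_group: str              # "P1" | "P2" | "P3"
    thinning_window: tuple[int, int]
    equilibrium_nstem: float
    equilibrium_cwood: float
    background_mort: float
    seed: int

    def to_dict(self) -> dict:
        return asdict(self)

    def write(self, path) -> None:
        d = self.to_dict()
        d["phase_boundaries"] = ",".join(str(b) for b in self.phase_boundaries)
        d["thinning_window"] = ",".join(str(b) for b in self.thinning_window)
        write_key_value(d, path)


@dataclass
class PlotStemMap:
    """Stem map of a rectangular plot: positions (m), dbh (cm), mass (kgC)."""

    width: float
    height: float
    stems: pd.DataFrame  # columns x, y, dbh, mass

    def __post_init__(self):
        if self.width <= 0 or self.height <= 0:
            raise ValueError("plot dimensions must be positive")
        df = self.stems
        if len(df):
            inside = ((df["x"] >= 0) & (df["x"] <= self.width)
                      & (df["y"] >= 0) & (df["y"] <= self.height))
            if not inside.all():
                raise ValueError("stems outside plot bounds")
            if (df["dbh"] <= 0).any():
                raise ValueError("dbh must be positive")

    @property
    def area_ha(self) -> float:
        return self.width * self.height / M2_PER_HA


def _start_group(cfg: SimConfig) -> str:
    b1, b2, _ = cfg.phase_boundaries
    if b1 > 0:
        return "P1"
    if b2 > 0:
        return "P2"
    return "P3"


def simulate_stand(config: SimConfig,
                   scheme: DbhScheme = DBH_SCHEME,
                   ) -> tuple[StandSeries, SizeStructure, GroundTruth]:
    """Generate an annual stand series, its size structure and ground truth.

    The woody population is one even-aged cohort. Stem density is constant
    (restocking) or saturating (emergent) before the thinning window, declines
    geometrically inside it, and is constant after; mean aboveground
    individual mass follows allometric dbh growth before the window and the
    power law M = k * N**p inside it, with k fixed by continuity at the
    window start. Fluxes are derived so the budget closes exactly.
    """
    cfg = config
    n_years = cfg.years
    if n_years < 2:
        raise ValueError("need at least 2 years")
    t = np.arange(n_years)
    b1, b2, b3 = cfg.phase_boundaries
    tw0, tw1 = cfg.window
    tw1 = min(tw1, n_years)
    if tw0 >= n_years - 1:
        raise ValueError("thinning window starts beyond the simulated span")

    # --- stem density -----------------------------------------------------
    nstem = np.empty(n_years)
    if cfg.recruit_mode == "restocking":
        nstem[:tw0] = cfg.initial_density
        n_at_start = cfg.initial_density
    else:  # emergent establishment ramp
        ramp = cfg.initial_density * (1.0 - np.exp(-(t[:tw0] + 1.0) / 8.0))
        nstem[:tw0] = ramp
        n_at_start = (ramp[-1] if tw0 > 0 else cfg.initial_density)
        if tw0 == 0:
            n_at_start = cfg.initial_density
    span = max(tw1 - tw0, 1)
    survive = (1.0 - cfg.thinning_decline) ** (1.0 / span)
    in_win = (t >= tw0) & (t < tw1)
    nstem[in_win] = n_at_start * survive ** (t[in_win] - tw0)
    nstem[t >= tw1] = n_at_start * (1.0 - cfg.thinning_decline)

    # --- mean individual mass --------------------------------------------
    a, b = cfg.allometry_a, cfg.allometry_b
    dbh_growth = cfg.initial_dbh * (1.0 + cfg.growth_rate) ** t
    m_ind = a * dbh_growth ** b                       # total kgC per tree
    m_start = a * (cfg.initial_dbh * (1.0 + cfg.growth_rate) ** tw0) ** b
    p = cfg.thinning_exponent
    k_ag = cfg.ag_frac * m_start * n_at_start ** (-p)  # M_ag = k_ag * N**p
    m_ind[in_win] = (k_ag * nstem[in_win] ** p) / cfg.ag_frac
    m_end = (k_ag * (n_at_start * (1.0 - cfg.thinning_decline)) ** p) / cfg.ag_frac
    m_ind[t >= tw1] = m_end

    # --- conserved pools and fluxes --------------------------------------
    cwood = nstem * m_ind / M2_PER_HA
    cwood_ag = cfg.ag_frac * cwood
    d_n = np.zeros(n_years)
    d_n[:-1] = np.maximum(nstem[:-1] - nstem[1:], 0.0)
    thin_flux = d_n * m_ind / M2_PER_HA
    cmort = thin_flux + cfg.background_mort * cwood
    wbgrowth = np.empty(n_years)
    wbgrowth[:-1] = cwood[1:] - cwood[:-1] + cmort[:-1]
    wbgrowth[-1] = cmort[-1]          # final year held at equilibrium
    selfthin_rate = np.divide(100.0 * thin_flux, cwood,
                              out=np.zeros(n_years), where=cwood > 0)

    # --- canopy area ------------------------------------------------------
    cy = cfg.closure_year
    if cy <= 0:
        ca = np.full(n_years, CA_MAX)
    else:
        ca = np.minimum(CA_MAX, M2_PER_HA * t / cy)

    # --- grass share ------------------------------------------------------
    g0 = cfg.initial_grass_frac
    if b1 > 0 and g0 >= GRASS_EXIT_SHARE:
        if cfg.grass_decay_yr is not None:
            tau_g = cfg.grass_decay_yr
        else:
            # cross the exit share half a year before the scripted boundary
            tau_g = max(b1 - 0.5, 0.5) / np.log(g0 / GRASS_EXIT_SHARE)
        grass = g0 * np.exp(-t / tau_g)
    else:
        grass = np.zeros(n_years)

    # --- observational noise ---------------------------------------------
    rng = np.random.default_rng(cfg.seed)
    if cfg.noise_sd > 0:
        sd = cfg.noise_sd

        def eps(clip_hi=None):
            e = rng.lognormal(mean=0.0, sigma=sd, size=n_years)
            if clip_hi is not None:
                e = np.minimum(e, clip_hi)
            return e

        eps_n = eps()
        # keep the noisy aboveground pool below the conserved total pool
        eps_c = eps(clip_hi=0.999 / cfg.ag_frac)
        eps_ca = eps()
        eps_g = eps()
    else:
        eps_n = eps_c = eps_ca = eps_g = np.ones(n_years)

    nstem_obs = nstem * eps_n
    cwood_ag_obs = cwood_ag * eps_c
    ca_obs = ca * eps_ca
    grass_obs = np.clip(grass * eps_g, 0.0, 1.0)

    series_df = pd.DataFrame({
        "year": t,
        "cwood": cwood,
        "cwood_ag": cwood_ag_obs,
        "cmort": cmort,
        "wbgrowth": wbgrowth,
        "nstem": nstem_obs,
        "ca": ca_obs,
        "cai": ca_obs / M2_PER_HA,
        "selfthin_mort_rate": selfthin_rate,
        "cveg_frac_grass": grass_obs,
        "cveg_frac_woody": 1.0 - grass_obs,
    })
    series = StandSeries(series_df)

    # --- size structure: the cohort occupies exactly one class per year ---
    dbh = (m_ind / a) ** (1.0 / b)
    labels = scheme.bin(dbh)
    all_labels = scheme.labels
    frame = pd.DataFrame({
        "year": np.repeat(t, scheme.n_classes),
        "class_label": np.tile(np.asarray(all_labels, dtype=object), n_years),
        "nstem_size": 0.0,
        "cwood_size": 0.0,
    })
    col_idx = {lab: i for i, lab in enumerate(all_labels)}
    rows = t * scheme.n_classes + np.array([col_idx[l] for l in labels])
    frame.loc[rows, "nstem_size"] = nstem_obs
    frame.loc[rows, "cwood_size"] = cwood_ag_obs
    structure = SizeStructure(frame, scheme=scheme)

    truth = GroundTruth(
        p=p,
        k=k_ag,
        phase_boundaries=(b1, b2, b3),
        start_group=_start_group(cfg),
        thinning_window=(tw0, tw1),
        equilibrium_nstem=n_at_start * (1.0 - cfg.thinning_decline),
        equilibrium_cwood=float(cwood[-1]),
        background_mort=cfg.background_mort,
        seed=cfg.seed,
    )
    return series, structure, truth


def simulate_chronosequence(n_sites: int, max_age: float, noise_sd: float,
                            seed: int, asymptote: float = 12.0,
                            timescale: float = 50.0) -> pd.DataFrame:
    """Space-for-time sample of (stand age, aboveground woody carbon).

    Ages are uniform on [0, max_age]; carbon follows a saturating regrowth
    curve ``A * (1 - exp(-age / timescale))`` with multiplicative lognormal
    noise. Deterministic for a fixed seed.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng(seed)
    age = rng.uniform(0.0, max_age, size=n_sites)
    curve = asymptote * (1.0 - np.exp(-age / timescale))
    if noise_sd > 0:
        curve = curve * rng.lognormal(0.0, noise_sd, size=n_sites)
    return pd.DataFrame({"age": age, "cwood_ag": curve})


def simulate_plot(density: float, width: float, height: float,
                  dbh_distribution: float | Callable | None = None,
                  seed: int = 0, allometry_a: float = 0.15,
                  allometry_b: float = 2.4) -> PlotStemMap:
    """Poisson-scattered stem map of a rectangular plot.

    ``dbh_distribution`` may be a constant (cm), a callable ``f(rng, n)``
    returning n diameters, or None for a lognormal(ln 20 cm, 0.35) default.
    """
    if width <= 0 or height <= 0:
        raise ValueError("plot dimensions must be positive")
    rng = np.random.default_rng(seed)
    area_ha = width * height / M2_PER_HA
    n = int(rng.poisson(max(density, 0.0) * area_ha))
    x = rng.uniform(0.0, width, size=n)
    y = rng.uniform(0.0, height, size=n)
    if dbh_distribution is None:
        dbh = rng.lognormal(np.log(20.0), 0.35, size=n)
    elif callable(dbh_distribution):
        dbh = np.asarray(dbh_distribution(rng, n), dtype=float)
    else:
        dbh = np.full(n, float(dbh_distribution))
    mass = allometry_a * dbh ** allometry_b
    stems = pd.DataFrame({"x": x, "y": y, "dbh": dbh, "mass": mass})
    return PlotStemMap(width=width, height=height, stems=stems)
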