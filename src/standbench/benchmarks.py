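"""Observation envelopes and model-vs-envelope scoring.

Observational references for stand-level benchmarking come in three
flavours, each summarised as a per-cell (median, low, high, n) envelope:

* chronosequence regrowth curves — records of (stand age, aboveground woody
  carbon) grouped into 20-yr age bins, reported as median / 10th / 90th
  percentile, keeping only bins with at least 20 observations;
* spatial bootstrap of a large stem-mapped plot — square subplots (default
  6.25 ha) placed uniformly at random, totals per dbh class scaled to
  per-area units, summarised as the bootstrap median and a central 95%
  interval;
* min-max across a small set of plots — cellwise median with the extreme
  values as bounds.

Quantiles use linear interpolation (R type 7) throughout. A model run is
scored cell by cell as inside / below / above the envelope, with inclusive
bounds and signed distances to the nearest bound.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import DBH_SCHEME, bin_dbh
from .simulate import M2_PER_HA, PlotStemMap

__all__ = [
    "BenchmarkEnvelope",
    "ScoreCard",
    "age_bin_label",
    "bin_chronosequence",
    "bootstrap_plot",
    "minmax_envelope",
    "model_to_age_bins",
    "score",
]

log = logging.getLogger(__name__)

DEFAULT_BIN_WIDTH = 20
DEFAULT_MIN_N = 20
DEFAULT_SUBPLOT_HA = 6.25
DEFAULT_N_BOOT = 1000
DEFAULT_CI = 95.0


def age_bin_label(age, width: int = DEFAULT_BIN_WIDTH):
    """Half-open age-bin label: 37 -> '[20,40)' for 20-yr bins."""
    age = np.asarray(age, dtype=float)
    lo = (np.floor(age / width) * width).astype(int)
    labels = np.array([f"[{l},{l + width})" for l in np.atleast_1d(lo)],
                      dtype=object)
    return labels if age.ndim else str(labels[0])


@dataclass
class BenchmarkEnvelope:
    """Per-cell observational range: low <= median <= high plus sample size.

    ``axis`` names the cell dimension ('age_bin', 'dbh_class' or 'scalar');
    ``provenance`` records how the bounds were derived. ``cells`` has columns
    (variable, cell, low, median, high, n).
    """

    axis: str
    cells: pd.DataFrame
    provenance: str

    def __post_init__(self):
        df = self.cells.reset_index(drop=True)
        need = ("variable", "cell", "low", "median", "high", "n")
        for col in need:
            if col not in df.columns:
                raise ValueError(f"envelope cells need column '{col}'")
        bad = (df["low"] > df["median"]) | (df["median"] > df["high"])
        if bad.any():
            raise ValueError("envelope ordering violated: need low <= median "
                             "<= high in every cell")
        self.cells = df

    def for_variable(self, variable: str) -> pd.DataFrame:
        return self.cells[self.cells["variable"] == variable]

    def __len__(self) -> int:
        return len(self.cells)


def bin_chronosequence(records: pd.DataFrame,
                       width: int = DEFAULT_BIN_WIDTH,
                       min_n: int = DEFAULT_MIN_N,
                       value_column: str = "cwood_ag",
                       age_column: str = "age") -> BenchmarkEnvelope:
    """Median / 10th / 90th percentile envelope over half-open age bins.

    Bins with fewer than ``min_n`` records are dropped (an under-sampled bin
    says more about the sample than the forest); an empty result is returned
    with a warning when no bin qualifies.
    """
    if records.empty:
        raise ValueError("no chronosequence records")
    df = records[[age_column, value_column]].dropna()
    binned = df.assign(cell=age_bin_label(df[age_column].to_numpy(), width))
    rows = []
    for cell, grp in binned.groupby("cell", sort=False):
        v = grp[value_column].to_numpy(dtype=float)
        if len(v) < min_n:
            continue
        rows.append({
            "variable": value_column,
            "cell": cell,
            "low": float(np.percentile(v, 10)),
            "median": float(np.percentile(v, 50)),
            "high": float(np.percentile(v, 90)),
            "n": int(len(v)),
        })
    if not rows:
        log.warning("all age bins have fewer than %d records; empty envelope",
                    min_n)
        cells = pd.DataFrame(columns=["variable", "cell", "low", "median",
                                      "high", "n"])
    else:
        order = sorted(rows, key=lambda r: int(r["cell"].split(",")[0][1:]))
        cells = pd.DataFrame(order)
    return BenchmarkEnvelope(axis="age_bin", cells=cells,
                             provenance="percentile(10,90)")


def bootstrap_plot(stem_map: PlotStemMap,
                   subplot_area: float = DEFAULT_SUBPLOT_HA,
                   n_boot: int = DEFAULT_N_BOOT,
                   ci: float = DEFAULT_CI,
                   seed: int = 0,
                   scheme=DBH_SCHEME) -> BenchmarkEnvelope:
    """Spatial bootstrap envelope of a stem-mapped plot.

    Places ``n_boot`` square subplots of ``subplot_area`` ha uniformly at
    random (fully contained, no wrap), computes per-subplot stem density
    (stems ha-1) and aboveground carbon (kgC m-2) per dbh class and in
    total, and reports the bootstrap median with the central ``ci``%
    interval per cell.
    """
    side = float(np.sqrt(subplot_area * M2_PER_HA))
    if side > stem_map.width or side > stem_map.height:
        raise ValueError(
            f"subplot of {subplot_area} ha ({side:.0f} m square) does not fit "
            f"inside the {stem_map.width:.0f} x {stem_map.height:.0f} m plot")
    rng = np.random.default_rng(seed)
    x0 = rng.uniform(0.0, stem_map.width - side, size=n_boot)
    y0 = rng.uniform(0.0, stem_map.height - side, size=n_boot)

    stems = stem_map.stems
    sx = stems["x"].to_numpy()
    sy = stems["y"].to_numpy()
    mass = stems["mass"].to_numpy()
    labels = (bin_dbh(stems["dbh"].to_numpy(), scheme) if len(stems)
              else np.asarray([], dtype=object))
    class_labels = list(scheme.labels)
    class_idx = np.array([class_labels.index(l) for l in labels], dtype=int) \
        if len(stems) else np.asarray([], dtype=int)

    n_cls = scheme.n_classes
    dens = np.zeros((n_boot, n_cls + 1))     # stems ha-1; last column = total
    carb = np.zeros((n_boot, n_cls + 1))     # kgC m-2
    area_m2 = subplot_area * M2_PER_HA
    for b in range(n_boot):
        inside = ((sx >= x0[b]) & (sx < x0[b] + side)
                  & (sy >= y0[b]) & (sy < y0[b] + side))
        if inside.any():
            cnt = np.bincount(class_idx[inside], minlength=n_cls)
            msum = np.bincount(class_idx[inside], weights=mass[inside],
                               minlength=n_cls)
            dens[b, :n_cls] = cnt / subplot_area
            carb[b, :n_cls] = msum / area_m2
            dens[b, n_cls] = inside.sum() / subplot_area
            carb[b, n_cls] = mass[inside].sum() / area_m2

    half = (100.0 - ci) / 2.0
    cell_names = class_labels + ["total"]
    rows = []
    for var, mat in (("nstem_size", dens), ("cwood_size", carb)):
        for j, cell in enumerate(cell_names):
            v = mat[:, j]
            rows.append({
                "variable": var,
                "cell": cell,
                "low": float(np.percentile(v, half)),
                "median": float(np.percentile(v, 50)),
                "high": float(np.percentile(v, 100.0 - half)),
                "n": int(n_boot),
            })
    return BenchmarkEnvelope(axis="dbh_class", cells=pd.DataFrame(rows),
                             provenance=f"bootstrap CI({ci:g})")


def minmax_envelope(per_plot: pd.DataFrame,
                    value_column: str = "value",
                    cell_column: str = "cell",
                    variable: str | None = None) -> BenchmarkEnvelope:
    """Cellwise median with min-max bounds across a small set of plots.

    ``per_plot`` is long-format with one row per (plot, cell): suited to a
    handful of censused plots where percentiles would be meaningless.
    """
    if per_plot.empty:
        raise ValueError("need at least one plot")
    var = variable or value_column
    rows = []
    for cell, grp in per_plot.groupby(cell_column, sort=False):
        v = grp[value_column].to_numpy(dtype=float)
        rows.append({
            "variable": var,
            "cell": cell,
            "low": float(np.min(v)),
            "median": float(np.percentile(v, 50)),
            "high": float(np.max(v)),
            "n": int(len(v)),
        })
    return BenchmarkEnvelope(axis="dbh_class", cells=pd.DataFrame(rows),
                             provenance="min-max")


def model_to_age_bins(years, values, width: int = DEFAULT_BIN_WIDTH,
                      variable: str = "cwood_ag") -> pd.DataFrame:
    """Mean of annual model values within each age bin (the model-side cell).

    Years are taken as stand age since the start of regrowth, so the model
    mean over [0,20) is compared against the observational [0,20) bin.
    """
    df = pd.DataFrame({"cell": age_bin_label(np.asarray(years), width),
                       "value": np.asarray(values, dtype=float)})
    out = df.groupby("cell", sort=False)["value"].mean().reset_index()
    out.insert(0, "variable", variable)
    return out


@dataclass
class ScoreCard:
    """Cell-by-cell classification of a model against an envelope."""

    table: pd.DataFrame        # variable, cell, value, low, median, high,
                               # status, distance
    fractions: dict            # per variable: {inside, below, above}

    def summary(self) -> str:
        lines = ["Model vs observational envelope", "-" * 32]
        for var, fr in self.fractions.items():
            lines.append(
                f"{var}: inside {fr['inside']:.2f}  below {fr['below']:.2f}  "
                f"above {fr['above']:.2f}  (n cells = {fr['n']})")
        return "\n".join(lines)


def score(model_cells: pd.DataFrame,
          envelope: BenchmarkEnvelope) -> ScoreCard:
    """Classify model cells as inside / below / above the envelope.

    ``model_cells`` is long-format (variable, cell, value); bounds are
    inclusive, the distance is signed (negative below the low bound,
    positive above the high bound, 0 inside). Model and envelope must share
    at least one cell.
    """
    need = ("variable", "cell", "value")
    for col in need:
        if col not in model_cells.columns:
            raise ValueError(f"model cells need column '{col}'")
    merged = model_cells.merge(envelope.cells, on=["variable", "cell"],
                               how="inner")
    if merged.empty:
        raise ValueError("model cells and envelope cells are disjoint")
    v = merged["value"].to_numpy(dtype=float)
    lo = merged["low"].to_numpy(dtype=float)
    hi = merged["high"].to_numpy(dtype=float)
    status = np.where(v < lo, "below", np.where(v > hi, "above", "inside"))
    distance = np.where(v < lo, v - lo, np.where(v > hi, v - hi, 0.0))
    merged["status"] = status
    merged["distance"] = distance
    fractions = {}
    for var, grp in merged.groupby("variable", sort=False):
        n = len(grp)
        fractions[var] = {
            "inside": float((grp["status"] == "inside").sum() / n),
            "below": float((grp["status"] == "below").sum() / n),
            "above": float((grp["status"] == "above").sum() / n),
            "n": n,
        }
    return ScoreCard(table=merged, fractions=fractions)
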