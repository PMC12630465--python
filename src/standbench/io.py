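"""Table dialect and containers for stand-level demographic model output.

The on-disk dialect is deliberately plain: UTF-8 comma-separated tables with
one header row, preceded by ``#``-prefixed metadata lines carrying per-column
units. Two table kinds exist: an annual *stand series* (pools, fluxes, stem
density, canopy variables, per-PFT vegetation-carbon shares) and a
*size structure* (stems and aboveground woody carbon per dbh class and year).

Units are fixed in storage: carbon pools in kgC m-2, fluxes in kgC m-2 yr-1,
stem density in stems ha-1, canopy area in m2 ha-1. The 1e4 m2-per-ha factor
is applied only inside computations that mix the per-m2 and per-ha bases,
never in storage.
"""

from __future__ import annotations

import hashlib
import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "DbenError",
    "FormatError",
    "MissingColumnError",
    "DbhScheme",
    "DBH_SCHEME",
    "bin_dbh",
    "StandSeries",
    "SizeStructure",
    "read_stand_series",
    "write_stand_series",
    "read_size_structure",
    "write_size_structure",
    "read_key_value",
    "write_key_value",
    "load_config",
    "config_hash",
]


class DbenError(Exception):
    """Base class for dialect errors."""


class FormatError(DbenError):
    """Malformed table: bad time axis, negative pools, unknown labels, ..."""


class MissingColumnError(DbenError):
    """A required column is absent."""

    def __init__(self, column: str, context: str = ""):
        self.column = column
        msg = f"required column '{column}' is missing"
        if context:
            msg += f" ({context})"
        super().__init__(msg)


# ---------------------------------------------------------------------------
# dbh-class scheme
# ---------------------------------------------------------------------------

_UPPER_EDGES = (1.0, 5.0, 10.0, 15.0, 20.0, 30.0, 40.0, 50.0,
                60.0, 70.0, 80.0, 90.0, 100.0, 150.0, 200.0)


@dataclass(frozen=True)
class DbhScheme:
    """Fixed diameter-class scheme: half-open [lower, upper) intervals.

    Labels are literal: ``"<5"`` is the class [1, 5) cm, and the open top
    class ``">=200"`` is [200, inf). Sixteen classes in total.
    """

    upper_edges: tuple[float, ...] = _UPPER_EDGES
    top_label: str = ">=200"

    def __post_init__(self):
        edges = np.asarray(self.upper_edges, dtype=float)
        if edges.ndim != 1 or len(edges) == 0 or np.any(np.diff(edges) <= 0):
            raise ValueError("upper edges must be strictly increasing")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(f"<{e:g}" for e in self.upper_edges) + (self.top_label,)

    @property
    def n_classes(self) -> int:
        return len(self.upper_edges) + 1

    def lower_edge(self, label: str) -> float:
        lo, _ = self.interval(label)
        return lo

    def interval(self, label: str) -> tuple[float, float]:
        """Map a class label back to its unique [lower, upper) interval."""
        labels = self.labels
        if label not in labels:
            raise FormatError(f"unknown dbh class label {label!r}")
        i = labels.index(label)
        lo = 0.0 if i == 0 else float(self.upper_edges[i - 1])
        hi = math.inf if i == len(self.upper_edges) else float(self.upper_edges[i])
        return lo, hi

    def bin(self, dbh):
        """Assign dbh (cm, scalar or array) to class labels; negative dbh errors."""
        arr = np.asarray(dbh, dtype=float)
        if np.any(arr < 0) or np.any(~np.isfinite(arr)):
            raise ValueError("dbh must be finite and >= 0")
        idx = np.searchsorted(np.asarray(self.upper_edges), arr, side="right")
        labels = np.asarray(self.labels, dtype=object)
        out = labels[idx]
        if np.isscalar(dbh) or arr.ndim == 0:
            return str(out if arr.ndim == 0 else out[0])
        return out


DBH_SCHEME = DbhScheme()


def bin_dbh(dbh, scheme: DbhScheme = DBH_SCHEME):
    """Bin stem diameters (cm) into the fixed class scheme (half-open bins)."""
    return scheme.bin(dbh)


# ---------------------------------------------------------------------------
# stand series container
# ---------------------------------------------------------------------------

STAND_REQUIRED = ("year", "cwood", "cwood_ag", "cmort", "wbgrowth", "nstem", "ca")
STAND_OPTIONAL = ("cai", "selfthin_mort_rate")
PFT_FRAC_PREFIX = "cveg_frac_"

STAND_UNITS = {
    "year": "yr",
    "cwood": "kgC m-2",
    "cwood_ag": "kgC m-2",
    "cmort": "kgC m-2 yr-1",
    "wbgrowth": "kgC m-2 yr-1",
    "nstem": "stems ha-1",
    "ca": "m2 ha-1",
    "cai": "-",
    "selfthin_mort_rate": "% yr-1",
}

_POOLS = ("cwood", "cwood_ag")
_FLUXES = ("cmort", "wbgrowth")


@dataclass
class StandSeries:
    """Annual stand-level output for one model/site run.

    Wraps a tidy DataFrame (one row per year). Required columns: year, cwood,
    cwood_ag, cmort, wbgrowth, nstem, ca. Optional: cai, selfthin_mort_rate
    and any number of ``cveg_frac_<pft>`` share columns. Missing optional
    columns are flagged in :attr:`absent`, not invented.
    """

    data: pd.DataFrame
    meta: dict = field(default_factory=dict)
    absent: tuple[str, ...] = ()

    def __post_init__(self):
        df = self.data.reset_index(drop=True).copy()
        for col in STAND_REQUIRED:
            if col not in df.columns:
                raise MissingColumnError(col, "stand series")
        years = df["year"].to_numpy()
        if len(years) == 0:
            raise FormatError("empty stand series")
        steps = np.diff(years)
        if len(steps) and (np.any(steps != 1)):
            if np.any(steps == 0):
                raise FormatError("non-annual time axis: duplicated years")
            raise FormatError("non-annual time axis")
        for col in _POOLS:
            if np.any(df[col].to_numpy() < 0):
                raise FormatError(f"negative pool values in '{col}'")
        clamped: dict[str, list[int]] = {}
        for col in _FLUXES:
            v = df[col].to_numpy(dtype=float)
            bad = v < 0
            if np.any(bad):
                clamped[col] = [int(y) for y in years[bad]]
                df[col] = np.where(bad, 0.0, v)
        if clamped:
            warnings.warn(
                f"negative flux values clamped to zero: {clamped}",
                UserWarning, stacklevel=2,
            )
            self.meta = {**self.meta, "clamped_fluxes": clamped}
        fr = self.pft_fraction_columns
        if fr:
            total = df[list(fr)].sum(axis=1).to_numpy()
            if np.any(total > 1.0 + 1e-6):
                raise FormatError("cveg_frac columns sum to more than 1")
        if np.any(df["cwood_ag"].to_numpy() > df["cwood"].to_numpy() * (1 + 1e-9)):
            raise FormatError("cwood_ag exceeds cwood")
        self.absent = tuple(c for c in STAND_OPTIONAL if c not in df.columns)
        self.data = df

    # -- convenience accessors -------------------------------------------
    @property
    def years(self) -> np.ndarray:
        return self.data["year"].to_numpy()

    @property
    def pft_fraction_columns(self) -> tuple[str, ...]:
        return tuple(c for c in self.data.columns if c.startswith(PFT_FRAC_PREFIX))

    def column(self, name: str) -> np.ndarray:
        if name not in self.data.columns:
            raise MissingColumnError(name, "stand series")
        return self.data[name].to_numpy(dtype=float)

    def grass_fraction(self) -> np.ndarray | None:
        """Grass share of C_veg, or None when no grass PFT column is present."""
        col = PFT_FRAC_PREFIX + "grass"
        if col in self.data.columns:
            return self.data[col].to_numpy(dtype=float)
        return None

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class SizeStructure:
    """Stems and aboveground woody carbon per dbh class and year (long format)."""

    data: pd.DataFrame
    scheme: DbhScheme = DBH_SCHEME

    def __post_init__(self):
        df = self.data.reset_index(drop=True).copy()
        for col in ("year", "class_label", "nstem_size", "cwood_size"):
            if col not in df.columns:
                raise MissingColumnError(col, "size structure")
        known = set(self.scheme.labels)
        bad = set(df["class_label"].unique()) - known
        if bad:
            raise FormatError(f"unknown dbh class labels: {sorted(bad)}")
        if np.any(df[["nstem_size", "cwood_size"]].to_numpy() < 0):
            raise FormatError("negative size-structure values")
        self.data = df

    def totals(self) -> pd.DataFrame:
        """Per-year sums over classes (should equal nstem and cwood_ag)."""
        return (self.data.groupby("year")[["nstem_size", "cwood_size"]]
                .sum().reset_index())

    def for_year(self, year: int) -> pd.DataFrame:
        return self.data[self.data["year"] == year]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _write_table(df: pd.DataFrame, path, units: Mapping[str, str],
                 kind: str, extra_meta: Mapping[str, str] | None = None) -> None:
    path = Path(path)
    lines = [f"# dialect: dben-csv v1", f"# table: {kind}"]
    unit_parts = [f"{c}={units.get(c, '-')}" for c in df.columns]
    lines.append("# units: " + "; ".join(unit_parts))
    for k, v in (extra_meta or {}).items():
        lines.append(f"# {k}: {v}")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("\n".join(lines) + "\n")
        df.to_csv(fh, index=False)


def _read_table(path) -> tuple[pd.DataFrame, dict]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            m = re.match(r"#\s*([^:]+):\s*(.*)", line)
            if m:
                meta[m.group(1).strip()] = m.group(2).strip()
    df = pd.read_csv(path, comment="#")
    return df, meta


def write_stand_series(series: StandSeries, path) -> None:
    units = dict(STAND_UNITS)
    for c in series.pft_fraction_columns:
        units[c] = "fraction of C_veg"
    _write_table(series.data, path, units, "stand_series")


def read_stand_series(path) -> StandSeries:
    df, meta = _read_table(path)
    return StandSeries(df, meta=meta)


def write_size_structure(structure: SizeStructure, path) -> None:
    units = {"year": "yr", "class_label": "cm class",
             "nstem_size": "stems ha-1", "cwood_size": "kgC m-2"}
    _write_table(structure.data, path, units, "size_structure")


def read_size_structure(path, scheme: DbhScheme = DBH_SCHEME) -> SizeStructure:
    df, _ = _read_table(path)
    return SizeStructure(df, scheme=scheme)


def write_key_value(mapping: Mapping[str, object], path) -> None:
    """Write a plain ``key = value`` sidecar file (ground truth, run metadata)."""
    with open(path, "w", encoding="utf-8") as fh:
        for k, v in mapping.items():
            if isinstance(v, float):
                fh.write(f"{k} = {v!r}\n")
            elif isinstance(v, (tuple, list)):
                fh.write(f"{k} = {','.join(str(x) for x in v)}\n")
            else:
                fh.write(f"{k} = {v}\n")


def read_key_value(path) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or "=" not in line:
                continue
            k, v = line.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def load_config(path) -> dict:
    """Load a YAML key-value configuration file into a plain dict."""
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise FormatError("configuration file must be a mapping")
    return cfg


def config_hash(cfg: Mapping) -> str:
    """Stable short hash of a configuration mapping, for run provenance logs."""
    canon = yaml.safe_dump(dict(cfg), sort_keys=True)
    return hashlib.sha256(canon.encode("utf-8")).hexdigest()[:12]
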