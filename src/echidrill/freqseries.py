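"""Stage-binned drilling-frequency time series.

Populations are binned by chronostratigraphic stage; per-bin statistics are
unweighted means/medians over population drilling frequencies.  Bins with no
populations are gaps, never zeros — zero-filling would fabricate intervals
of apparently absent drilling.  Sample-standardized means resample a fixed
quota of populations per bin with replacement (bootstrap), removing the
artifact of uneven sampling intensity between bins, and carry empirical
percentile 95% confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .timescale import StageTable

__all__ = ["FrequencySeries", "DiffSeries", "FrequencySeriesError",
           "bin_series", "first_differences", "standardized_means",
           "incomplete_fraction"]


class FrequencySeriesError(ValueError):
    pass


@dataclass
class FrequencySeries:
    """Per-stage drilling-frequency summary on a contiguous stage axis.

    The axis runs oldest -> youngest from the first to the last occupied
    stage; interior stages with no populations are present with
    ``occupied=False`` and NaN statistics.
    """
    bins: list[str]                 # stage names, oldest -> youngest
    occupied: np.ndarray            # bool per bin
    mean_f: np.ndarray              # NaN where unoccupied
    median_f: np.ndarray
    n_pops: np.ndarray              # int per bin (0 where unoccupied)
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None
    standardized: bool = False
    chart_version: str = ""
    source_filter: str = "all"

    def __post_init__(self):
        occ = np.asarray(self.occupied, dtype=bool)
        m = np.asarray(self.mean_f, dtype=float)
        if not len(self.bins) == len(occ) == len(m):
            raise FrequencySeriesError("bin/statistic length mismatch")
        vals = m[occ]
        if len(vals) and (np.nanmin(vals) < 0 or np.nanmax(vals) > 1):
            raise FrequencySeriesError("frequencies outside [0, 1]")

    @property
    def occupied_bins(self) -> list[str]:
        return [b for b, o in zip(self.bins, self.occupied) if o]

    @property
    def occupied_means(self) -> np.ndarray:
        return self.mean_f[self.occupied]

    def to_frame(self, table: StageTable | None = None) -> pd.DataFrame:
        df = pd.DataFrame({
            "stage": self.bins, "occupied": self.occupied,
            "n_pops": self.n_pops, "mean_f": self.mean_f,
            "median_f": self.median_f,
        })
        if self.ci_low is not None:
            df["ci_low"] = self.ci_low
            df["ci_high"] = self.ci_high
        if table is not None:
            stages = [table.stage(b) for b in self.bins]
            df.insert(1, "older_bound_ma", [s.older_bound for s in stages])
            df.insert(2, "younger_bound_ma", [s.younger_bound for s in stages])
            df.insert(3, "midpoint_ma", [s.midpoint for s in stages])
        return df

    def write_csv(self, path: str | Path, table: StageTable | None = None) -> None:
        self.to_frame(table).to_csv(path, index=False, float_format="%.10g")


@dataclass
class DiffSeries:
    """First differences of bin means between consecutive occupied bins."""
    values: np.ndarray              # younger minus older
    spans_gap: np.ndarray           # True where the pair brackets empty bins
    from_bin: list[str]
    to_bin: list[str]

    def __len__(self) -> int:
        return len(self.values)


def _select(populations: pd.DataFrame, source: str | None) -> pd.DataFrame:
    if source is None or source == "all":
        return populations
    if source not in ("EAT", "LIT"):
        raise FrequencySeriesError(f"unknown source filter {source!r}")
    return populations[populations["source"] == source]


def _stage_axis(populations: pd.DataFrame, table: StageTable) -> list:
    """Contiguous stage list spanning the occupied range, oldest first."""
    idx = sorted({table.stage(s).index for s in populations["stage"]})
    if not idx:
        raise FrequencySeriesError("no populations to bin")
    return [table.stages[i] for i in range(idx[0], idx[-1] + 1)]


def bin_series(populations: pd.DataFrame, table: StageTable,
               source: str | None = None) -> FrequencySeries:
    """Raw per-stage mean and median of population drilling frequencies.

    Expects populations already filtered to the minimum-size criterion.
    """
    pops = _select(populations, source)
    if len(pops) == 0:
        raise FrequencySeriesError("no populations to bin")
    axis = _stage_axis(pops, table)
    # sorted values make every downstream statistic invariant to row order
    grouped = {table.stage(s).name: np.sort(g["drilling_frequency"].to_numpy())
               for s, g in pops.groupby("stage")}
    n = len(axis)
    occ = np.zeros(n, bool)
    mean_f = np.full(n, np.nan)
    median_f = np.full(n, np.nan)
    n_pops = np.zeros(n, int)
    for i, s in enumerate(axis):
        f = grouped.get(s.name)
        if f is not None and len(f):
            occ[i] = True
            mean_f[i] = f.mean()
            median_f[i] = float(np.median(f))
            n_pops[i] = len(f)
    return FrequencySeries([s.name for s in axis], occ, mean_f, median_f,
                           n_pops, chart_version=table.chart_version,
                           source_filter=source or "all")


def first_differences(series: FrequencySeries) -> DiffSeries:
    """Pairwise first differences of mean frequency between adjacent
    occupied bins (younger minus older); differences that bridge one or
    more empty bins are flagged ``spans_gap``."""
    occ_idx = np.flatnonzero(series.occupied)
    if len(occ_idx) < 2:
        raise FrequencySeriesError("need at least two occupied bins")
    means = series.mean_f[occ_idx]
    values = np.diff(means)
    spans = np.diff(occ_idx) > 1
    names = [series.bins[i] for i in occ_idx]
    return DiffSeries(values=values, spans_gap=spans,
                      from_bin=names[:-1], to_bin=names[1:])


def standardized_means(populations: pd.DataFrame, table: StageTable,
                       quota: int | None = None, n_reps: int = 1000,
                       alpha: float = 0.05, seed: int | None = None,
                       source: str | None = None) -> FrequencySeries:
    """Bootstrap sample-standardized mean drilling frequencies with CIs.

    Per occupied bin: ``n_reps`` draws of ``quota`` populations with
    replacement; the point estimate is the mean of draw-means and the CI the
    empirical ``alpha/2`` / ``1-alpha/2`` percentiles.  Default quota is the
    smallest per-bin population count among occupied bins; bins holding
    fewer than ``quota`` populations are upsampled with replacement, which
    widens their intervals rather than silently dropping them.
    """
    raw = bin_series(populations, table, source=source)
    if quota is None:
        quota = int(raw.n_pops[raw.occupied].min())
    if quota < 1:
        raise FrequencySeriesError(f"quota must be >= 1, got {quota}")
    pops = _select(populations, source)
    grouped = {table.stage(s).name: np.sort(g["drilling_frequency"].to_numpy())
               for s, g in pops.groupby("stage")}
    rng = np.random.default_rng(seed)
    est = np.full(len(raw.bins), np.nan)
    lo = np.full(len(raw.bins), np.nan)
    hi = np.full(len(raw.bins), np.nan)
    for i, name in enumerate(raw.bins):
        if not raw.occupied[i]:
            continue
        f = grouped[name]
        draws = f[rng.integers(0, len(f), size=(n_reps, quota))].mean(axis=1)
        est[i] = draws.mean()
        lo[i] = float(np.quantile(draws, alpha / 2))
        hi[i] = float(np.quantile(draws, 1 - alpha / 2))
    return FrequencySeries(raw.bins, raw.occupied, est, raw.median_f,
                           raw.n_pops, ci_low=lo, ci_high=hi,
                           standardized=True, chart_version=raw.chart_version,
                           source_filter=source or "all")


def incomplete_fraction(populations: pd.DataFrame) -> float:
    """Proportion of all recorded drill holes that are incomplete
    (failed attacks): sum(incomplete) / sum(complete + incomplete)."""
    inc = int(populations["n_holes_incomplete"].sum())
    tot = inc + int(populations["n_holes_complete"].sum())
    if tot == 0:
        raise FrequencySeriesError("no drill holes recorded")
    return inc / tot
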