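"""Supporting inferences: diversity changepoints and taphonomic partial
correlations.

Changepoint detection dates radiations on predator/prey richness curves by
exhaustive least-squares mean-shift segmentation: with at most ``max_cp``
changepoints and series of a few dozen stages, every boundary placement can
be enumerated, so the optimum is exact rather than approximate.  A linear
penalty per changepoint controls over-segmentation.

Partial correlations quantify taphonomic overprint: the association of
population drilling frequency with mean taphonomic grade, sample age and
sample size, each controlling for the others, via the inverse-correlation-
matrix construction, with two-sided p-values from the t transform.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .timescale import StageTable

__all__ = ["DiversitySeries", "ChangepointResult", "PartialCorrelationResult",
           "AuxStatsError", "read_diversity", "detect_changepoints",
           "partial_correlation", "taphonomy_partial_correlations"]


class AuxStatsError(ValueError):
    pass


@dataclass
class DiversitySeries:
    """Per-stage richness (genus or species counts) for one group."""
    bins: list[str]
    richness: np.ndarray
    group: str

    def __post_init__(self):
        r = np.asarray(self.richness)
        if len(r) != len(self.bins):
            raise AuxStatsError("bins/richness length mismatch")
        if np.any(r < 0):
            raise AuxStatsError("richness must be non-negative")
        self.richness = r.astype(int)


@dataclass
class ChangepointResult:
    """Mean-shift segmentation of a richness series.

    ``cp_indices`` are bin indices where a new segment begins;
    ``interval_start_ma``/``interval_end_ma`` bracket the initial radiation
    event — the earliest segment across whose boundaries the mean rises.
    """
    cp_indices: list[int]
    segment_means: list[float]
    cost: float
    interval_start_ma: float | None = None
    interval_end_ma: float | None = None
    event_start_stage: str | None = None
    event_end_stage: str | None = None


def read_diversity(path: str | Path, group: str | None = None,
                   table: StageTable | None = None) -> list[DiversitySeries]:
    """Read a diversity CSV (columns: group, stage, richness) into one
    series per group, ordered oldest -> youngest."""
    df = pd.read_csv(path)
    for c in ("group", "stage", "richness"):
        if c not in df.columns:
            raise AuxStatsError(f"diversity file {path}: missing column {c!r}")
    out = []
    for g, sub in df.groupby("group", sort=False):
        if group is not None and g != group:
            continue
        if table is not None:
            sub = sub.assign(_i=[table.stage(s).index for s in sub["stage"]])
            sub = sub.sort_values("_i")
        out.append(DiversitySeries(bins=list(sub["stage"]),
                                   richness=sub["richness"].to_numpy(),
                                   group=str(g)))
    return out


def _segment_cost(prefix: np.ndarray, prefix2: np.ndarray, i: int, j: int) -> float:
    """Within-segment SSE for x[i:j] from prefix sums (O(1))."""
    n = j - i
    s = prefix[j] - prefix[i]
    s2 = prefix2[j] - prefix2[i]
    return s2 - s * s / n


def detect_changepoints(series: DiversitySeries, max_cp: int = 2,
                        penalty: float | None = None,
                        table: StageTable | None = None) -> ChangepointResult:
    """Exact mean-shift changepoint detection by exhaustive enumeration.

    Minimizes total within-segment squared error + penalty x (number of
    changepoints) over all placements of 0..``max_cp`` boundaries.  The
    default penalty is ``2 * sigma^2 * log(n)`` with sigma^2 estimated
    robustly from first differences, a BIC-style choice that keeps a
    constant series at zero changepoints.  Ties prefer fewer, then earlier,
    changepoints.
    """
    x = np.asarray(series.richness, dtype=float)
    n = len(x)
    if n < max_cp + 2:
        raise AuxStatsError(f"series of length {n} too short for max_cp={max_cp}")
    if penalty is None:
        sigma2 = float(np.var(np.diff(x)) / 2.0) if n > 1 else 0.0
        penalty = max(2.0 * sigma2 * np.log(n), 1e-9)
    if penalty <= 0:
        raise AuxStatsError("penalty must be positive")
    prefix = np.concatenate([[0.0], np.cumsum(x)])
    prefix2 = np.concatenate([[0.0], np.cumsum(x * x)])

    best_cost = np.inf
    best_cps: tuple[int, ...] = ()
    for r in range(0, max_cp + 1):
        for cps in itertools.combinations(range(1, n), r):
            edges = (0,) + cps + (n,)
            cost = sum(_segment_cost(prefix, prefix2, a, b)
                       for a, b in zip(edges, edges[1:]))
            cost += penalty * r
            if cost < best_cost - 1e-12:
                best_cost = cost
                best_cps = cps
    edges = (0,) + best_cps + (n,)
    means = [float(x[a:b].mean()) for a, b in zip(edges, edges[1:])]

    res = ChangepointResult(cp_indices=list(best_cps), segment_means=means,
                            cost=float(best_cost))
    # initial radiation event: earliest segment across whose boundaries the
    # mean increases
    for si in range(len(means) - 1):
        if means[si + 1] > means[si]:
            ev = si + 1 if len(means) > si + 1 else si
            a, b = edges[ev], edges[ev + 1]
            res.event_start_stage = series.bins[a]
            res.event_end_stage = series.bins[b - 1]
            if table is not None:
                res.interval_start_ma = table.stage_midpoint(series.bins[a])
                res.interval_end_ma = table.stage_midpoint(series.bins[b - 1])
            break
    return res


@dataclass
class PartialCorrelationResult:
    target: str
    covariates: list[str]
    r_partial: dict[str, float]
    p_value: dict[str, float]
    n: int
    n_dropped: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "covariate": self.covariates,
            "r_partial": [self.r_partial[c] for c in self.covariates],
            "p_value": [self.p_value[c] for c in self.covariates],
            "n": self.n,
        })


def partial_correlation(table: pd.DataFrame, target: str,
                        covariates: list[str]) -> PartialCorrelationResult:
    """Partial Pearson correlation of ``target`` with each covariate,
    controlling for the remaining covariates.

    Uses the inverse-correlation-matrix construction
    ``r_ij|rest = -P_ij / sqrt(P_ii P_jj)`` with ``P = R^-1``; two-sided
    p-values from ``t = r sqrt(df / (1 - r^2))`` with
    ``df = n - 2 - (#controlled)``.  Rows with any missing value (e.g.
    literature populations lacking taphonomic grades) are dropped and
    counted.  With no covariates this reduces to the plain Pearson
    correlation.
    """
    cols = [target] + list(covariates)
    sub = table[cols]
    complete = sub.dropna()
    n_dropped = len(sub) - len(complete)
    n = len(complete)
    if n < len(cols) + 2:
        raise AuxStatsError(f"only {n} complete rows for {len(cols)} variables")
    X = complete.to_numpy(dtype=float)

    r_partial, p_value = {}, {}
    if not covariates:
        return PartialCorrelationResult(target, [], {}, {}, n, n_dropped)
    R = np.corrcoef(X, rowvar=False)
    if np.any(~np.isfinite(R)):
        raise AuxStatsError("constant column: correlation undefined")
    # 2x2 case has no controls; handle directly so inv() cornering is avoided
    try:
        P = np.linalg.inv(R)
    except np.linalg.LinAlgError:
        raise AuxStatsError("singular correlation matrix (collinear variables)")
    if np.linalg.cond(R) > 1e10:
        raise AuxStatsError("near-singular correlation matrix (collinear variables)")
    k_controls = len(covariates) - 1
    dof = n - 2 - k_controls
    if dof < 1:
        raise AuxStatsError("insufficient degrees of freedom")
    for j, cov in enumerate(covariates, start=1):
        r = float(-P[0, j] / np.sqrt(P[0, 0] * P[j, j]))
        r = min(1.0, max(-1.0, r))
        t = r * np.sqrt(dof / max(1.0 - r * r, 1e-300))
        p = float(2.0 * stats.t.sf(abs(t), dof))
        r_partial[cov] = r
        p_value[cov] = p
    return PartialCorrelationResult(target, list(covariates), r_partial,
                                    p_value, n, n_dropped)


def taphonomy_partial_correlations(populations: pd.DataFrame,
                                   table: StageTable,
                                   log_size: bool = False,
                                   ) -> PartialCorrelationResult:
    """Drilling frequency vs taphonomic grade, sample age and sample size.

    Sample age is the population's stage midpoint in Ma; sample size is the
    individual count (optionally log-transformed).  Literature populations
    carry no grades and drop out as incomplete cases.
    """
    df = pd.DataFrame({
        "drilling_frequency": populations["drilling_frequency"],
        "mean_taph_grade": populations["mean_taph_grade"],
        "age_ma": [table.stage_midpoint(s) for s in populations["stage"]],
        "sample_size": (np.log(populations["n_individuals"]) if log_size
                        else populations["n_individuals"].astype(float)),
    })
    return partial_correlation(df, "drilling_frequency",
                               ["mean_taph_grade", "age_ma", "sample_size"])
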