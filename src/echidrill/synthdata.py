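"""Synthetic specimen/population/diversity data with known ground truth.

The generator emulates the statistical structure of a museum-survey
compilation of drilling predation on echinoids:

* an uneven number of populations per stage bin (Poisson, rate drifting
  through time);
* population sizes from a shifted negative binomial with a hard minimum
  (survey inclusion floor) and a heavy tail;
* a three-phase true drilling-frequency trajectory — low pre-intensification
  level, a ramp over configurable stages, an elevated and variable
  post-intensification level — with beta-distributed between-population
  overdispersion, so most populations record zero or low drilling while a
  minority are heavily drilled;
* taphonomic grades that worsen with age and a detection-loss function
  delta(grade): the probability a true drill hole goes unrecorded rises
  with abrasion, which induces the negative grade-vs-frequency association
  the taphonomy diagnostics are built to detect;
* rare incomplete drill holes (default 3.4% of holes) and minute host taxa
  whose predatory holes fall under the usual 0.5 mm size cut;
* a literature-style inclusion filter whose probability of reporting a
  population increases with its drilling frequency.

Randomness is split into a *structure* stream and a *detection* stream so
that two runs differing only in detection loss share every other draw:
raising delta can then only remove observed holes, never add them (the
coupling behind the monotone-bias property).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dataset as ds
from .auxstats import DiversitySeries
from .timescale import StageTable, load_timescale

__all__ = ["SynthConfig", "SynthDataset", "generate_dataset",
           "apply_literature_bias", "generate_diversity_series"]

_PRED_OUTLINES = sorted(ds.PREDATORY_OUTLINES)


@dataclass
class SynthConfig:
    """Generator settings; defaults are the package's reference scenario."""

    seed: int = 0
    chart_version: str = "ics2013"
    oldest_stage: str = "Aalenian"
    youngest_stage: str = "Holocene"

    # sampling intensity: expected populations per bin, linear oldest->youngest
    pop_rate_old: float = 4.0
    pop_rate_recent: float = 10.0
    min_pops_per_bin: int = 0

    # population sizes: n = min + NegBin(shape, mean=extra_mean)
    min_individuals: int = 10
    pop_size_extra_mean: float = 120.0
    pop_size_shape: float = 0.7

    # truth trajectory: three phases with a linear ramp between them
    f_pre: float = 0.02
    f_post: float = 0.25
    ramp_start_stage: str = "Lutetian"
    ramp_end_stage: str = "Rupelian"
    #: beta-binomial concentration; 60 puts ~70% of pre-phase populations
    #: at zero drilled individuals for n = 20
    kappa: float = 60.0

    # taphonomy: per-region sub-score ~ Binomial(3, q); q drifts with age
    # and carries a population-level preservation effect (locality regime)
    subscore_p_young: float = 0.15
    subscore_p_old: float = 0.45
    grade_pop_sd: float = 0.15
    #: max probability a true hole goes unobserved (at the worst grade)
    detection_loss_max: float = 0.3

    p_incomplete: float = 0.034
    extra_holes_rate: float = 0.15
    parasitic_rate: float = 0.05

    minute_fraction: float = 0.08
    minute_threshold_mm: float = 10.0

    # literature inclusion: P(report) = logistic(intercept + slope * frequency)
    lit_slope: float = 8.0
    lit_intercept: float = -2.5

    visible_low_fraction: float = 0.05  # share of poorly exposed specimens

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SynthConfig":
        return cls(**json.loads(Path(path).read_text()))

    def validate(self) -> None:
        for name in ("f_pre", "f_post", "p_incomplete", "extra_holes_rate",
                     "parasitic_rate", "minute_fraction", "visible_low_fraction",
                     "detection_loss_max", "subscore_p_young", "subscore_p_old"):
            v = getattr(self, name)
            if name in ("extra_holes_rate",):
                ok = v >= 0
            else:
                ok = 0.0 <= v <= 1.0
            if not ok:
                raise ValueError(f"config field {name}={v} out of range")
        if not self.f_pre < self.f_post:
            raise ValueError("intensification scenario needs f_pre < f_post")
        if not self.kappa > 0:
            raise ValueError("kappa must be positive")
        if self.min_individuals < 1 or self.pop_size_shape <= 0:
            raise ValueError("invalid population size settings")


@dataclass
class SynthDataset:
    specimens: pd.DataFrame
    traces: pd.DataFrame
    populations: pd.DataFrame
    truth: dict
    config: SynthConfig

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        ds.write_specimens(self.specimens, outdir / "specimens.csv")
        ds.write_traces(self.traces, outdir / "traces.csv")
        ds.write_populations(self.populations, outdir / "populations.csv")
        Path(outdir / "truth.json").write_text(
            json.dumps(self.truth, indent=2, sort_keys=True))
        self.config.to_json(outdir / "synth_config.json")


def _truth_trajectory(table: StageTable, cfg: SynthConfig) -> np.ndarray:
    """Per-stage true mean drilling frequency (index-linear ramp).

    The ramp's first stage already sits one step above f_pre and its last
    stage reaches f_post, so the transitional phase is exactly the
    configured stage span.
    """
    rs = table.stage(cfg.ramp_start_stage).index
    re_ = table.stage(cfg.ramp_end_stage).index
    if rs > re_:
        raise ValueError("ramp_start_stage must be older than ramp_end_stage")
    f = np.full(len(table), cfg.f_pre)
    n_ramp = re_ - rs + 1
    for k, i in enumerate(range(rs, re_ + 1), start=1):
        f[i] = cfg.f_pre + (cfg.f_post - cfg.f_pre) * k / n_ramp
    f[re_ + 1:] = cfg.f_post
    return f


def _delta(grade: np.ndarray, cfg: SynthConfig) -> np.ndarray:
    """Detection loss: probability a true hole goes unobserved, linear in
    the summed taphonomic grade (0 at pristine, max at grade 12)."""
    return cfg.detection_loss_max * grade / (4.0 * ds.SCALE_MAX)


def generate_dataset(config: SynthConfig,
                     table: StageTable | None = None) -> SynthDataset:
    """Generate a full synthetic survey: specimens, traces and populations.

    Population records are built by the dataset module's own visibility
    filter and summarizer, so generator output exercises exactly the code
    path real data would.  Deterministic under ``config.seed``.
    """
    config.validate()
    cfg = config
    if table is None:
        table = load_timescale(cfg.chart_version).subset(
            cfg.oldest_stage, cfg.youngest_stage)
    ss = np.random.SeedSequence(cfg.seed)
    s_struct, s_detect = ss.spawn(2)
    rng = np.random.default_rng(s_struct)     # everything except detection
    det = np.random.default_rng(s_detect)     # per-hole detection uniforms

    f_truth = _truth_trajectory(table, cfg)
    lam = np.linspace(cfg.pop_rate_old, cfg.pop_rate_recent, len(table))
    age_scale = table.stages[0].midpoint  # oldest midpoint, for drifts

    spec_rows, trace_rows, pop_records = [], [], []
    truth_pops = {}
    for s in table.stages:
        n_pops = max(int(rng.poisson(lam[s.index])), cfg.min_pops_per_bin)
        q_sub = (cfg.subscore_p_young
                 + (cfg.subscore_p_old - cfg.subscore_p_young)
                 * s.midpoint / age_scale)
        for ip in range(n_pops):
            pid = f"{s.name.replace(' ', '')}_{ip:03d}"
            minute = rng.random() < cfg.minute_fraction
            n = cfg.min_individuals + int(rng.negative_binomial(
                cfg.pop_size_shape,
                cfg.pop_size_shape / (cfg.pop_size_shape + cfg.pop_size_extra_mean)))
            fb = f_truth[s.index]
            p_true = float(rng.beta(cfg.kappa * fb, cfg.kappa * (1.0 - fb)))
            drilled = rng.random(n) < p_true
            visible = np.where(rng.random(n) < cfg.visible_low_fraction,
                               rng.uniform(0.1, 0.5, n),
                               rng.uniform(0.55, 1.0, n))
            # locality-level preservation regime shifts every specimen's
            # abrasion odds together
            q_pop = float(np.clip(q_sub + rng.normal(0.0, cfg.grade_pop_sd),
                                  0.0, 1.0))
            sub = rng.binomial(ds.SCALE_MAX, q_pop, size=(n, 4))
            grade = sub.sum(axis=1)
            mean_diam = 6.0 if minute else 45.0
            test_d = rng.lognormal(np.log(mean_diam), 0.25, n)
            life_habit = "infaunal" if rng.random() < 0.7 else "epifaunal"
            delta = _delta(grade.astype(float), cfg)

            trace_mark = len(trace_rows)
            for j in range(n):
                sid = f"{pid}_s{j:04d}"
                spec_rows.append((sid, pid, float(visible[j]),
                                  int(sub[j, 0]), int(sub[j, 1]),
                                  int(sub[j, 2]), int(sub[j, 3]),
                                  float(test_d[j])))
                if drilled[j]:
                    n_holes = 1 + int(rng.poisson(cfg.extra_holes_rate))
                    for _ in range(n_holes):
                        if minute:
                            d_mm = float(rng.uniform(0.2, 0.45))
                        else:
                            d_mm = max(0.5, float(rng.lognormal(np.log(2.0), 0.5)))
                        outline = _PRED_OUTLINES[int(rng.integers(len(_PRED_OUTLINES)))]
                        complete = int(rng.random() >= cfg.p_incomplete)
                        observed = det.random() >= delta[j]
                        if observed:
                            trace_rows.append((sid, d_mm, outline, complete))
                # parasitic (eulimid) holes on normal-sized hosts; recorded
                # but excluded from frequencies by classification
                if not minute and rng.random() < cfg.parasitic_rate:
                    trace_rows.append((sid, float(rng.uniform(0.1, 0.45)),
                                       "minute", 1))

            pop_spec = pd.DataFrame(
                spec_rows[-n:], columns=ds.SPECIMEN_COLUMNS)
            pop_traces = pd.DataFrame(
                trace_rows[trace_mark:], columns=ds.TRACE_COLUMNS)
            kept = ds.filter_specimens(pop_spec)
            if len(kept) == 0:
                continue
            rec = ds.summarize_population(
                kept, pop_traces, population_id=pid,
                taxon=f"Taxon_{s.name.replace(' ', '')}_{ip}",
                life_habit=life_habit, stage=s.name, source="EAT",
                minute_taxon_threshold=cfg.minute_threshold_mm)
            pop_records.append(rec)
            truth_pops[pid] = {"p_true": p_true, "stage": s.name,
                               "f_bin": float(fb), "n_raw": n}

    specimens = pd.DataFrame(spec_rows, columns=ds.SPECIMEN_COLUMNS)
    traces = pd.DataFrame(trace_rows, columns=ds.TRACE_COLUMNS)
    populations = ds.populations_frame(pop_records)
    truth = {
        "f_by_stage": {s.name: float(f_truth[s.index]) for s in table.stages},
        "ramp_start_stage": cfg.ramp_start_stage,
        "ramp_end_stage": cfg.ramp_end_stage,
        "f_pre": cfg.f_pre, "f_post": cfg.f_post,
        "populations": truth_pops,
        "chart_version": table.chart_version,
    }
    return SynthDataset(specimens=specimens, traces=traces,
                        populations=populations, truth=truth, config=cfg)


def apply_literature_bias(populations: pd.DataFrame, config: SynthConfig,
                          seed: int | None = None) -> pd.DataFrame:
    """Thin a population table the way literature compilation would.

    Each population is reported with probability
    ``logistic(intercept + slope * drilling_frequency)``; retained records
    are relabelled ``source="LIT"`` with taphonomic grades blanked (and ids
    prefixed), emulating reports that carry frequencies but no
    specimen-level preservation scores.  Slope 0 is unbiased thinning.
    """
    if len(populations) == 0:
        return populations.copy()
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    f = populations["drilling_frequency"].to_numpy(dtype=float)
    p_keep = 1.0 / (1.0 + np.exp(-(config.lit_intercept + config.lit_slope * f)))
    keep = rng.random(len(populations)) < p_keep
    out = populations[keep].copy().reset_index(drop=True)
    out["source"] = "LIT"
    out["mean_taph_grade"] = np.nan
    out["population_id"] = "LIT_" + out["population_id"]
    return out


def generate_diversity_series(group: str, changepoints: list[str | int],
                              segment_means: list[float], noise_sd: float,
                              seed: int | None = None,
                              table: StageTable | None = None,
                              ramp: bool = False,
                              ) -> tuple[DiversitySeries, dict]:
    """Synthetic richness series with planted mean shifts.

    ``changepoints`` are stages (names or table indices) where a new segment
    begins; ``segment_means`` has one more entry than ``changepoints``.
    Gaussian noise is added, rounded and floored at zero.  With
    ``ramp=True`` each segment climbs linearly from the previous segment's
    mean to its own.  Returns the series plus a truth dict with the planted
    boundary indices.
    """
    if table is None:
        table = load_timescale()
    if len(segment_means) != len(changepoints) + 1:
        raise ValueError("need one more segment mean than changepoints")
    n = len(table)
    cp_idx = sorted(table.stage(c).index if isinstance(c, str) else int(c)
                    for c in changepoints)
    if any(not 0 < i < n for i in cp_idx):
        raise ValueError("changepoints must be interior table indices")
    mu = np.empty(n)
    edges = [0] + cp_idx + [n]
    for si, (a, b) in enumerate(zip(edges, edges[1:])):
        if ramp and si > 0:
            mu[a:b] = np.linspace(segment_means[si - 1], segment_means[si],
                                  b - a + 1)[1:]
        else:
            mu[a:b] = segment_means[si]
    rng = np.random.default_rng(seed)
    rich = np.maximum(np.rint(mu + rng.normal(0.0, noise_sd, n)), 0).astype(int)
    series = DiversitySeries(bins=table.names, richness=rich, group=group)
    truth = {"cp_indices": cp_idx, "segment_means": list(map(float, segment_means)),
             "noise_sd": noise_sd, "ramp": ramp}
    return series, truth
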