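"""Specimen- and population-level drilling data: model, I/O, filters.

The unit of analysis is the *population*: all individuals of one taxon from
one locality and stratigraphic unit.  A population's drilling frequency is
individual-based — the proportion of individuals bearing at least one
predatory drill hole — which is the standard metric in the drilling-predation
literature (hole-based frequencies would double-count multiply-drilled
tests).

Two data sources coexist: systematically surveyed museum/field material
("EAT", with specimen-level backing and taphonomic grades) and
population-level frequencies compiled from the literature ("LIT", no
specimen backing, no grades).

Trace classification separates predatory cassid drill holes from minute
eulimid parasitic holes by hole size (predatory holes are generally wider
than 0.5 mm) and outline shape, with an exception for minute host taxa whose
predatory holes can fall below the size cut-off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .timescale import StageTable

__all__ = [
    "TraceRecord", "SpecimenRecord", "PopulationRecord", "DatasetError",
    "OUTLINES", "PREDATORY_OUTLINES",
    "read_populations", "read_specimens", "read_traces",
    "write_populations", "write_specimens", "write_traces",
    "taphonomic_grade", "classify_trace", "filter_specimens",
    "filter_populations", "summarize_population", "populations_frame",
]

#: All recognised drill-hole outline shapes.
OUTLINES = frozenset({"circular", "subcircular", "irregular", "rectangular",
                      "elongated", "notched", "minute"})
#: Outline shapes consistent with cassid predation.
PREDATORY_OUTLINES = frozenset({"circular", "subcircular", "irregular",
                                "rectangular", "elongated", "notched"})

#: Default per-region abrasion sub-score scale (each region scored 0..3).
SCALE_MAX = 3
#: Default test diameter (mm) below which a taxon counts as "minute".
MINUTE_TAXON_THRESHOLD_MM = 10.0
#: Minimum predatory hole diameter (mm) on non-minute hosts.
PREDATORY_MIN_DIAMETER_MM = 0.5


class DatasetError(ValueError):
    """Raised for schema violations or records breaking dataset invariants."""


@dataclass(frozen=True)
class TraceRecord:
    """One drill hole on one specimen."""
    diameter: float  # mm
    outline: str
    complete: bool

    def __post_init__(self):
        if not self.diameter > 0:
            raise DatasetError(f"trace diameter must be positive, got {self.diameter}")
        if self.outline not in OUTLINES:
            raise DatasetError(f"unknown outline {self.outline!r}")


@dataclass
class SpecimenRecord:
    """One echinoid test surveyed for traces."""
    specimen_id: str
    population_id: str
    visible_fraction: float
    subscore_ambitus: int
    subscore_periproct: int
    subscore_peristome: int
    subscore_apical: int
    test_diameter: float  # mm
    traces: list[TraceRecord] = field(default_factory=list)

    def __post_init__(self):
        if not (0.0 <= self.visible_fraction <= 1.0):
            raise DatasetError(
                f"specimen {self.specimen_id}: visible_fraction "
                f"{self.visible_fraction} outside [0, 1]")
        for name in ("subscore_ambitus", "subscore_periproct",
                     "subscore_peristome", "subscore_apical"):
            v = getattr(self, name)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                raise DatasetError(f"specimen {self.specimen_id}: missing {name}")
            if not (0 <= int(v) <= SCALE_MAX):
                raise DatasetError(
                    f"specimen {self.specimen_id}: {name}={v} outside 0..{SCALE_MAX}")
        if not self.test_diameter > 0:
            raise DatasetError(f"specimen {self.specimen_id}: non-positive test diameter")


@dataclass
class PopulationRecord:
    """One taxon x locality x stratigraphic unit."""
    population_id: str
    taxon: str
    life_habit: str  # epifaunal | infaunal
    stage: str
    source: str      # EAT | LIT
    n_individuals: int
    n_drilled: int
    n_holes_complete: int = 0
    n_holes_incomplete: int = 0
    mean_taph_grade: float | None = None  # EAT only

    def __post_init__(self):
        if self.n_individuals < 1:
            raise DatasetError(f"population {self.population_id}: n_individuals < 1")
        if not (0 <= self.n_drilled <= self.n_individuals):
            raise DatasetError(
                f"population {self.population_id}: n_drilled={self.n_drilled} "
                f"outside [0, {self.n_individuals}]")
        if self.source not in ("EAT", "LIT"):
            raise DatasetError(f"population {self.population_id}: "
                               f"source must be EAT or LIT, got {self.source!r}")

    @property
    def drilling_frequency(self) -> float:
        return self.n_drilled / self.n_individuals


# ---------------------------------------------------------------------------
# Tabular I/O.  Analysis code works on pandas DataFrames; the record
# dataclasses above define the row contracts the readers enforce.
# ---------------------------------------------------------------------------

POPULATION_COLUMNS = ["population_id", "taxon", "life_habit", "stage", "source",
                      "n_individuals", "n_drilled", "n_holes_complete",
                      "n_holes_incomplete", "mean_taph_grade"]
SPECIMEN_COLUMNS = ["specimen_id", "population_id", "visible_fraction",
                    "subscore_ambitus", "subscore_periproct",
                    "subscore_peristome", "subscore_apical", "test_diameter"]
TRACE_COLUMNS = ["specimen_id", "diameter_mm", "outline", "complete"]


def _require_columns(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise DatasetError(f"{what}: missing column(s) {missing}")


def read_populations(path: str | Path,
                     table: StageTable | None = None) -> pd.DataFrame:
    """Read and validate a populations CSV.

    Checks count consistency row by row, recomputes drilling_frequency, and
    (when a StageTable is given) resolves stage names to canonical spelling.
    """
    df = pd.read_csv(path)
    _require_columns(df, POPULATION_COLUMNS, f"populations file {path}")
    problems = []
    for i, row in df.iterrows():
        rowno = i + 2  # header is line 1
        if row["n_individuals"] < 1:
            problems.append(f"row {rowno}: n_individuals < 1")
        if not (0 <= row["n_drilled"] <= row["n_individuals"]):
            problems.append(f"row {rowno}: n_drilled outside [0, n_individuals]")
        if row["source"] not in ("EAT", "LIT"):
            problems.append(f"row {rowno}: source {row['source']!r} not EAT/LIT")
        if table is not None and row["stage"] not in table:
            problems.append(f"row {rowno}: unresolvable stage {row['stage']!r}")
    if problems:
        raise DatasetError("invalid populations file:\n  " + "\n  ".join(problems))
    if table is not None:
        df["stage"] = [table.stage(s).name for s in df["stage"]]
    for c in ("n_individuals", "n_drilled", "n_holes_complete", "n_holes_incomplete"):
        df[c] = df[c].astype(int)
    df["drilling_frequency"] = df["n_drilled"] / df["n_individuals"]
    return df


def read_specimens(path: str | Path) -> pd.DataFrame:
    """Read and validate a specimens CSV (one row per surveyed test)."""
    df = pd.read_csv(path)
    _require_columns(df, SPECIMEN_COLUMNS, f"specimens file {path}")
    problems = []
    sub = [c for c in SPECIMEN_COLUMNS if c.startswith("subscore_")]
    for i, row in df.iterrows():
        rowno = i + 2
        if not (0.0 <= row["visible_fraction"] <= 1.0):
            problems.append(f"row {rowno}: visible_fraction outside [0, 1]")
        for c in sub:
            if pd.isna(row[c]):
                problems.append(f"row {rowno}: missing {c}")
            elif not (0 <= row[c] <= SCALE_MAX):
                problems.append(f"row {rowno}: {c} outside 0..{SCALE_MAX}")
        if not row["test_diameter"] > 0:
            problems.append(f"row {rowno}: non-positive test_diameter")
    if problems:
        raise DatasetError("invalid specimens file:\n  " + "\n  ".join(problems))
    df[sub] = df[sub].astype(int)
    return df


def read_traces(path: str | Path) -> pd.DataFrame:
    """Read and validate a traces CSV (one row per observed drill hole)."""
    df = pd.read_csv(path)
    _require_columns(df, TRACE_COLUMNS, f"traces file {path}")
    problems = []
    for i, row in df.iterrows():
        rowno = i + 2
        if not row["diameter_mm"] > 0:
            problems.append(f"row {rowno}: non-positive diameter_mm")
        if row["outline"] not in OUTLINES:
            problems.append(f"row {rowno}: unknown outline {row['outline']!r}")
        if row["complete"] not in (0, 1):
            problems.append(f"row {rowno}: complete must be 0/1")
    if problems:
        raise DatasetError("invalid traces file:\n  " + "\n  ".join(problems))
    df["complete"] = df["complete"].astype(int)
    return df


_FLOAT_FMT = "%.10g"  # stable text round-trip for reproducible bundles


def write_populations(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in POPULATION_COLUMNS if c in df.columns]
    df.to_csv(path, index=False, columns=cols, float_format=_FLOAT_FMT)


def write_specimens(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, columns=SPECIMEN_COLUMNS, float_format=_FLOAT_FMT)


def write_traces(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, columns=TRACE_COLUMNS, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def taphonomic_grade(specimen) -> int:
    """Overall taphonomic grade: sum of the four per-region abrasion scores.

    Regions scored separately (ambitus, periproct, peristome, apical disc)
    on a 0..3 ordinal scale and summed; higher = more poorly preserved.
    Missing sub-scores are an error — no imputation.
    """
    vals = []
    for name in ("subscore_ambitus", "subscore_periproct",
                 "subscore_peristome", "subscore_apical"):
        v = specimen[name] if not hasattr(specimen, name) else getattr(specimen, name)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            raise DatasetError(f"missing {name}; cannot grade")
        vals.append(int(v))
    return sum(vals)


def classify_trace(trace: TraceRecord, test_diameter: float,
                   minute_taxon_threshold: float = MINUTE_TAXON_THRESHOLD_MM) -> str:
    """Classify a drill hole as ``predatory``, ``parasitic`` or ``unclassified``.

    Predatory (cassid) holes are >= 0.5 mm across — except on minute host
    taxa, where smaller holes still count — and show a predation-consistent
    outline.  Sub-0.5 mm holes on normal-sized hosts are attributed to
    eulimid parasitism and excluded from drilling frequencies.
    """
    if not (trace.diameter > 0 and test_diameter > 0):
        raise DatasetError("trace and host diameters must be positive")
    size_ok = (trace.diameter >= PREDATORY_MIN_DIAMETER_MM
               or test_diameter < minute_taxon_threshold)
    if size_ok and trace.outline in PREDATORY_OUTLINES:
        return "predatory"
    if (trace.diameter < PREDATORY_MIN_DIAMETER_MM
            and test_diameter >= minute_taxon_threshold):
        return "parasitic"
    return "unclassified"


def filter_specimens(specimens: pd.DataFrame, min_visible: float = 0.5) -> pd.DataFrame:
    """Keep specimens with strictly more than ``min_visible`` of the test visible."""
    return specimens[specimens["visible_fraction"] > min_visible].reset_index(drop=True)


def filter_populations(populations: pd.DataFrame, min_n: int = 10) -> pd.DataFrame:
    """Keep populations with at least ``min_n`` individuals (inclusive)."""
    return populations[populations["n_individuals"] >= min_n].reset_index(drop=True)


def summarize_population(specimens: pd.DataFrame, traces: pd.DataFrame, *,
                         population_id: str, taxon: str, life_habit: str,
                         stage: str, source: str = "EAT",
                         minute_taxon_threshold: float = MINUTE_TAXON_THRESHOLD_MM,
                         ) -> PopulationRecord:
    """Aggregate one population's surveyed specimens into a PopulationRecord.

    ``n_drilled`` counts individuals bearing >= 1 *predatory* trace
    (parasitic and unclassified traces are ignored); hole counts sum
    predatory holes over specimens; ``mean_taph_grade`` averages the summed
    abrasion scores.  Specimens are expected to have passed the visibility
    filter already.
    """
    if len(specimens) == 0:
        raise DatasetError(f"population {population_id}: no specimens to summarize")
    diam = dict(zip(specimens["specimen_id"], specimens["test_diameter"]))
    n_drilled = 0
    holes_c = holes_i = 0
    tr = traces[traces["specimen_id"].isin(diam)]
    pred_by_spec: dict[str, int] = {}
    for row in tr.itertuples(index=False):
        t = TraceRecord(diameter=row.diameter_mm, outline=row.outline,
                        complete=bool(row.complete))
        if classify_trace(t, diam[row.specimen_id], minute_taxon_threshold) == "predatory":
            pred_by_spec[row.specimen_id] = pred_by_spec.get(row.specimen_id, 0) + 1
            if t.complete:
                holes_c += 1
            else:
                holes_i += 1
    n_drilled = sum(1 for v in pred_by_spec.values() if v >= 1)
    grades = [taphonomic_grade(s) for s in specimens.itertuples(index=False)]
    return PopulationRecord(
        population_id=population_id, taxon=taxon, life_habit=life_habit,
        stage=stage, source=source, n_individuals=len(specimens),
        n_drilled=n_drilled, n_holes_complete=holes_c,
        n_holes_incomplete=holes_i,
        mean_taph_grade=float(np.mean(grades)) if source == "EAT" else None)


def populations_frame(records: list[PopulationRecord]) -> pd.DataFrame:
    """Assemble PopulationRecords into the canonical populations DataFrame."""
    if not records:
        df = pd.DataFrame(columns=POPULATION_COLUMNS)
        df["drilling_frequency"] = pd.Series(dtype=float)
        return df
    df = pd.DataFrame([{
        "population_id": r.population_id, "taxon": r.taxon,
        "life_habit": r.life_habit, "stage": r.stage, "source": r.source,
        "n_individuals": r.n_individuals, "n_drilled": r.n_drilled,
        "n_holes_complete": r.n_holes_complete,
        "n_holes_incomplete": r.n_holes_incomplete,
        "mean_taph_grade": (np.nan if r.mean_taph_grade is None
                            else r.mean_taph_grade),
    } for r in records])
    df["drilling_frequency"] = df["n_drilled"] / df["n_individuals"]
    return df
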