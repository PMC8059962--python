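"""Geologic timescale: chronostratigraphic stages, boundary ages, binning.

Every time series in this package lives on an ordered axis of stages
(chronostratigraphic ages), each with an older and a younger boundary age in
Ma.  The packaged chart is pinned to the ICS boundary set whose stage
midpoints match the values quoted throughout the analysis (e.g. Chattian
28.1–23.03 Ma, midpoint 25.6 Ma); the chart version travels with every
output so binned results are reproducible even if newer boundary revisions
appear.

Binning convention: stages are half-open in age, ``older_bound >= age >
younger_bound``, so an age falling exactly on a boundary belongs to the
younger of the two stages.  The terminal Holocene bin additionally contains
age 0.
"""

from __future__ import annotations

import csv
import difflib
from dataclasses import dataclass
from importlib import resources
from typing import Iterator

__all__ = ["StageBin", "StageTable", "TimescaleError", "load_timescale"]

_BOUND_TOL = 1e-9


class TimescaleError(ValueError):
    """Raised for unknown charts/stages or an inconsistent stage table."""


@dataclass(frozen=True)
class StageBin:
    """One chronostratigraphic stage: ``[older_bound, younger_bound)`` Ma."""

    name: str
    older_bound: float
    younger_bound: float
    index: int  # ordinal position, 0 = oldest

    @property
    def midpoint(self) -> float:
        """Arithmetic midpoint age in Ma, reported to 0.1 Myr.

        Very young stages whose midpoint would round outside their own
        bounds (e.g. the Holocene) keep full precision instead.
        """
        mid = (self.older_bound + self.younger_bound) / 2.0
        rounded = round(mid, 1)
        if self.younger_bound < rounded < self.older_bound:
            return rounded
        return mid

    def contains(self, age_ma: float) -> bool:
        if self.younger_bound == 0.0 and age_ma == 0.0:
            return True  # terminal bin is closed at the present day
        return self.older_bound >= age_ma > self.younger_bound


class StageTable:
    """Ordered, gap-free collection of stages (oldest first).

    Supports case-insensitive name lookup with a packaged alias map
    (e.g. "Maestrichtian" -> "Maastrichtian", "Recent" -> "Holocene").
    """

    def __init__(self, stages: list[StageBin], chart_version: str,
                 aliases: dict[str, str] | None = None):
        self.stages = list(stages)
        self.chart_version = chart_version
        self._aliases = {k.casefold(): v for k, v in (aliases or {}).items()}
        self._by_name = {s.name.casefold(): s for s in self.stages}
        self._validate()

    def _validate(self) -> None:
        if len(self.stages) < 2:
            raise TimescaleError("stage table needs at least two stages")
        for prev, cur in zip(self.stages, self.stages[1:]):
            if not (prev.older_bound > prev.younger_bound):
                raise TimescaleError(
                    f"stage {prev.name!r}: older bound {prev.older_bound} "
                    f"not greater than younger bound {prev.younger_bound}")
            if abs(prev.younger_bound - cur.older_bound) > _BOUND_TOL:
                raise TimescaleError(
                    f"stages do not tile time: {prev.name!r} ends at "
                    f"{prev.younger_bound} Ma but {cur.name!r} starts at "
                    f"{cur.older_bound} Ma")
        last = self.stages[-1]
        if last.younger_bound < 0 or not last.older_bound > last.younger_bound:
            raise TimescaleError(f"terminal stage {last.name!r} has invalid bounds")

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.stages)

    def __iter__(self) -> Iterator[StageBin]:
        return iter(self.stages)

    def __contains__(self, name: str) -> bool:
        try:
            self.stage(name)
            return True
        except TimescaleError:
            return False

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.stages]

    @property
    def span(self) -> tuple[float, float]:
        """(oldest older_bound, youngest younger_bound) in Ma."""
        return self.stages[0].older_bound, self.stages[-1].younger_bound

    # -- lookup --------------------------------------------------------------
    def stage(self, name: str) -> StageBin:
        """Resolve a stage by name (case-insensitive, aliases honoured)."""
        key = name.strip().casefold()
        key = self._aliases.get(key, key).casefold()
        try:
            return self._by_name[key]
        except KeyError:
            pool = self.names + [a.title() for a in self._aliases]
            near = difflib.get_close_matches(name.strip().title(), pool, n=3)
            hint = f"; did you mean {', '.join(near)}?" if near else ""
            raise TimescaleError(f"unknown stage {name!r}{hint}") from None

    def stage_midpoint(self, name: str) -> float:
        """Midpoint age of a stage in Ma, to 0.1 Myr."""
        return self.stage(name).midpoint

    def assign_bin(self, record_age_or_stage: float | str) -> StageBin:
        """Map a numeric age (Ma) or a stage name to its StageBin.

        Numeric ages use the half-open convention: an age exactly on a
        boundary belongs to the younger stage.
        """
        if isinstance(record_age_or_stage, str):
            return self.stage(record_age_or_stage)
        age = float(record_age_or_stage)
        old, young = self.span
        if not (old >= age >= young):
            raise TimescaleError(
                f"age {age} Ma outside table span [{young}, {old}] Ma")
        for s in self.stages:
            if s.contains(age):
                return s
        # age == oldest older_bound: belongs to the oldest stage (no older
        # neighbour to hand it to)
        if age == old:
            return self.stages[0]
        raise TimescaleError(f"age {age} Ma could not be binned")  # pragma: no cover

    def subset(self, oldest: str, youngest: str) -> "StageTable":
        """Contiguous sub-table from ``oldest`` through ``youngest``."""
        i0 = self.stage(oldest).index
        i1 = self.stage(youngest).index
        if i0 > i1:
            raise TimescaleError(f"{oldest!r} is younger than {youngest!r}")
        stages = [StageBin(s.name, s.older_bound, s.younger_bound, j)
                  for j, s in enumerate(self.stages[i0:i1 + 1])]
        return StageTable(stages, self.chart_version, dict(self._aliases))


def _read_packaged_csv(filename: str) -> list[dict[str, str]]:
    ref = resources.files("echidrill.data").joinpath(filename)
    with ref.open("r", encoding="utf-8") as fh:
        return list(csv.DictReader(fh))


def load_timescale(chart_version: str = "ics2013") -> StageTable:
    """Load a packaged stage chart and validate its tiling.

    The default ``"ics2013"`` chart spans Aalenian (Middle Jurassic) through
    Holocene, 41 stages, and reproduces the boundary ages behind the stage
    midpoints quoted in the analysis.
    """
    try:
        rows = _read_packaged_csv(f"stages_{chart_version}.csv")
    except FileNotFoundError:
        raise TimescaleError(f"unknown chart version {chart_version!r}") from None
    stages = [
        StageBin(name=r["name"],
                 older_bound=float(r["older_bound_ma"]),
                 younger_bound=float(r["younger_bound_ma"]),
                 index=i)
        for i, r in enumerate(rows)
    ]
    aliases = {r["alias"]: r["canonical"]
               for r in _read_packaged_csv("stage_aliases.csv")}
    return StageTable(stages, chart_version, aliases)
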