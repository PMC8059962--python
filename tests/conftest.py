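import numpy as np
import pandas as pd
import pytest

import echidrill as ed


@pytest.fixture(scope="session")
def table():
    return ed.load_timescale()


@pytest.fixture(scope="session")
def small_table(table):
    """Danian through Holocene: 22 stages, enough for fast phase fits."""
    return table.subset("Danian", "Holocene")


@pytest.fixture(scope="session")
def synth(table):
    """One reference synthetic survey (full Aalenian-Holocene axis)."""
    return ed.generate_dataset(ed.SynthConfig(seed=42))


@pytest.fixture(scope="session")
def synth_pops(synth):
    return ed.filter_populations(synth.populations)


def make_populations(freq_by_stage: dict[str, list[float]],
                     n: int = 20) -> pd.DataFrame:
    """Hand-built populations table: stage -> list of drilling frequencies.

    Each frequency f becomes a population of ``n`` individuals with
    round(f*n) drilled, so drilling_frequency == f exactly when f*n is
    integral.
    """
    recs = []
    i = 0
    for stage, fs in freq_by_stage.items():
        for f in fs:
            k = int(round(f * n))
            recs.append(ed.PopulationRecord(
                population_id=f"p{i}", taxon=f"t{i}", life_habit="infaunal",
                stage=stage, source="EAT", n_individuals=n, n_drilled=k,
                n_holes_complete=k, n_holes_incomplete=0,
                mean_taph_grade=3.0))
            i += 1
    return ed.populations_frame(recs)
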