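"""Record invariants, inclusion filters, grading and trace classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import echidrill as ed
from echidrill.dataset import (DatasetError, PREDATORY_OUTLINES,
                               classify_trace, summarize_population)


# -- taphonomic grading -----------------------------------------------------

@pytest.mark.parametrize("scores,expected", [
    ((0, 0, 0, 0), 0),        # pristine
    ((1, 2, 0, 3), 6),
    ((3, 3, 3, 3), 12),       # worst preservation on the default scale
])
def test_taphonomic_grade_sums_subscores(scores, expected):
    s = ed.SpecimenRecord("s1", "p1", 0.9, *scores, test_diameter=30.0)
    assert ed.taphonomic_grade(s) == expected


def test_missing_subscore_is_an_error():
    with pytest.raises(DatasetError, match="subscore_periproct"):
        ed.taphonomic_grade({"subscore_ambitus": 1, "subscore_periproct": None,
                             "subscore_peristome": 0, "subscore_apical": 0})


# -- trace classification ---------------------------------------------------

@pytest.mark.parametrize("diam,outline,host,expected", [
    (1.2, "circular", 40.0, "predatory"),
    (0.2, "circular", 40.0, "parasitic"),      # eulimid-sized on normal host
    (0.3, "circular", 8.0, "predatory"),       # minute-host exception
    (0.7, "minute", 40.0, "unclassified"),     # minute outline never predatory
    (0.5, "notched", 40.0, "predatory"),       # size cut-off is inclusive
])
def test_classify_trace_cases(diam, outline, host, expected):
    t = ed.TraceRecord(diameter=diam, outline=outline, complete=True)
    assert classify_trace(t, host, minute_taxon_threshold=10.0) == expected


@given(diam=st.floats(0.01, 10.0), host=st.floats(1.0, 200.0),
       outline=st.sampled_from(sorted(ed.dataset.OUTLINES)))
@settings(max_examples=200, deadline=None, derandomize=True)
def test_classification_total_and_deterministic(diam, outline, host):
    t = ed.TraceRecord(diameter=diam, outline=outline, complete=True)
    c1 = classify_trace(t, host)
    c2 = classify_trace(t, host)
    assert c1 == c2
    assert c1 in ("predatory", "parasitic", "unclassified")


# -- inclusion filters ------------------------------------------------------

def _spec_row(sid, visible):
    return {"specimen_id": sid, "population_id": "p", "visible_fraction": visible,
            "subscore_ambitus": 0, "subscore_periproct": 0,
            "subscore_peristome": 0, "subscore_apical": 0, "test_diameter": 30.0}


def test_visibility_filter_is_strict():
    df = pd.DataFrame([_spec_row("a", 0.6), _spec_row("b", 0.5),
                       _spec_row("c", 0.49)])
    kept = ed.filter_specimens(df)
    assert list(kept["specimen_id"]) == ["a"]  # exactly 0.5 is dropped
    assert len(ed.filter_specimens(df.iloc[:0])) == 0


def test_population_filter_is_inclusive(synth):
    pops = synth.populations
    kept = ed.filter_populations(pops, min_n=10)
    assert (kept["n_individuals"] >= 10).all()
    # n == 10 populations survive; min_n=1 is the identity
    assert len(ed.filter_populations(pops, min_n=1)) == len(pops)


# -- population summarization ----------------------------------------------

def _pop_fixture(n=10, drilled=(0, 1, 2), holes_per_drilled=1,
                 parasitic_on=()):
    specs = pd.DataFrame([_spec_row(f"s{i}", 0.9) for i in range(n)])
    rows = []
    for i in drilled:
        for _ in range(holes_per_drilled):
            rows.append({"specimen_id": f"s{i}", "diameter_mm": 1.5,
                         "outline": "circular", "complete": 1})
    for i in parasitic_on:
        rows.append({"specimen_id": f"s{i}", "diameter_mm": 0.2,
                     "outline": "minute", "complete": 1})
    traces = pd.DataFrame(rows, columns=ed.dataset.TRACE_COLUMNS)
    return specs, traces


def test_summarize_counts_individuals_not_holes():
    specs, traces = _pop_fixture(n=10, drilled=(0,), holes_per_drilled=2)
    rec = summarize_population(specs, traces, population_id="p", taxon="t",
                               life_habit="epifaunal", stage="Lutetian")
    assert rec.n_drilled == 1          # one individual, despite two holes
    assert rec.n_holes_complete == 2


def test_summarize_ignores_parasitic_traces():
    specs, traces = _pop_fixture(n=10, drilled=(0, 1, 2),
                                 parasitic_on=(3, 4, 5, 6))
    rec = summarize_population(specs, traces, population_id="p", taxon="t",
                               life_habit="epifaunal", stage="Lutetian")
    assert rec.n_drilled == 3
    assert rec.drilling_frequency == pytest.approx(0.30)


def test_summarize_requires_specimens():
    specs, traces = _pop_fixture()
    with pytest.raises(DatasetError, match="no specimens"):
        summarize_population(specs.iloc[:0], traces, population_id="p",
                             taxon="t", life_habit="epifaunal", stage="Danian")


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=20, deadline=None, derandomize=True)
def test_summarize_matches_bruteforce_recount(seed):
    """Drilling frequency equals a brute-force recount of specimens bearing
    >= 1 predatory trace, on random specimen/trace fixtures."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 30))
    specs = pd.DataFrame([_spec_row(f"s{i}", 0.9) for i in range(n)])
    rows = []
    for i in range(n):
        for _ in range(int(rng.integers(0, 3))):
            rows.append({"specimen_id": f"s{i}",
                         "diameter_mm": float(rng.uniform(0.05, 3.0)),
                         "outline": str(rng.choice(sorted(ed.dataset.OUTLINES))),
                         "complete": int(rng.integers(0, 2))})
    traces = pd.DataFrame(rows, columns=ed.dataset.TRACE_COLUMNS)
    rec = summarize_population(specs, traces, population_id="p", taxon="t",
                               life_habit="infaunal", stage="Danian")
    # independent recount
    drilled = set()
    for r in rows:
        t = ed.TraceRecord(r["diameter_mm"], r["outline"], bool(r["complete"]))
        if classify_trace(t, 30.0) == "predatory":
            drilled.add(r["specimen_id"])
    assert rec.n_drilled == len(drilled)
    assert rec.drilling_frequency == pytest.approx(len(drilled) / n)


# -- I/O round trips and validation ----------------------------------------

def test_population_roundtrip(tmp_path, synth, table):
    path = tmp_path / "pops.csv"
    ed.dataset.write_populations(synth.populations, path)
    back = ed.read_populations(path, table)
    pd.testing.assert_frame_equal(
        back, synth.populations, check_dtype=False, atol=1e-12)


def test_reader_rejects_count_inconsistency(tmp_path):
    path = tmp_path / "bad.csv"
    pd.DataFrame([{
        "population_id": "p", "taxon": "t", "life_habit": "infaunal",
        "stage": "Danian", "source": "EAT", "n_individuals": 5,
        "n_drilled": 9, "n_holes_complete": 9, "n_holes_incomplete": 0,
        "mean_taph_grade": 2.0}]).to_csv(path, index=False)
    with pytest.raises(DatasetError, match="row 2"):
        ed.read_populations(path)


def test_reader_rejects_missing_column(tmp_path):
    path = tmp_path / "bad.csv"
    pd.DataFrame([{"population_id": "p"}]).to_csv(path, index=False)
    with pytest.raises(DatasetError, match="missing column"):
        ed.read_populations(path)


def test_reader_rejects_unknown_stage(tmp_path, table):
    path = tmp_path / "bad.csv"
    pd.DataFrame([{
        "population_id": "p", "taxon": "t", "life_habit": "infaunal",
        "stage": "Atlantis", "source": "EAT", "n_individuals": 12,
        "n_drilled": 1, "n_holes_complete": 1, "n_holes_incomplete": 0,
        "mean_taph_grade": 2.0}]).to_csv(path, index=False)
    with pytest.raises(DatasetError, match="Atlantis"):
        ed.read_populations(path, table)
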