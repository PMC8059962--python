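"""Phase enumeration, Monte Carlo simulation, ranking and reporting."""

import itertools
import json

import numpy as np
import pytest

import echidrill as ed
from conftest import make_populations
from echidrill.phasemodel import (EmptyPhasePoolError, PhaseModelError,
                                  PhaseModelSpec, SSQ_EPSILON)


# -- enumeration ------------------------------------------------------------

def test_enumeration_counts_small():
    assert len(ed.enumerate_phase_models(4, 2)) == 3
    assert len(ed.enumerate_phase_models(4, 3)) == 3
    assert len(ed.enumerate_phase_models(36, 3)) == 595  # C(35, 2)


@pytest.mark.parametrize("k", [2, 3])
def test_enumeration_matches_bruteforce(k):
    """Closed-form counts and exhaustive uniqueness up to 40 bins."""
    for n in range(k, 41):
        specs = ed.enumerate_phase_models(n, k)
        brute = set(itertools.combinations(range(1, n), k - 1))
        assert {s.boundaries for s in specs} == brute
        assert len(specs) == len(brute)


def test_enumeration_too_few_bins():
    with pytest.raises(PhaseModelError):
        ed.enumerate_phase_models(2, 3)


def test_straddling_difference_goes_to_later_phase():
    spec = PhaseModelSpec(5, (2,))
    # transition t joins bins t and t+1; phase follows the later bin
    assert [spec.phase_of_transition(t) for t in range(4)] == [0, 1, 1, 1]
    spec3 = PhaseModelSpec(6, (2, 4))
    assert [spec3.phase_of_transition(t) for t in range(5)] == [0, 1, 1, 2, 2]
    assert spec3.transition_start == 2
    assert spec3.transition_end == 3


# -- simulation --------------------------------------------------------------

def _exact_series(table, stage_means, n=1000):
    """One population per stage with an exactly representable frequency."""
    pops = make_populations({s: [f] for s, f in stage_means.items()}, n=n)
    series = ed.bin_series(pops, table)
    return pops, series


def test_zero_variance_perfect_fit_is_capped(small_table):
    """Identical populations everywhere: every trajectory is exact, SSQ = 0
    and the inverse-SSQ score hits its cap."""
    names = small_table.names[:6]
    pops, series = _exact_series(small_table, {s: 0.25 for s in names})
    fit = ed.simulate_phase_model(pops, series, PhaseModelSpec(6, (3,)),
                                  small_table, n_iter=100, seed=0)
    assert np.all(fit.ssq_per_iter == 0.0)
    assert fit.fit_score == pytest.approx(1.0 / SSQ_EPSILON)
    np.testing.assert_array_equal(fit.band_q25, fit.band_q75)
    # translation diagnostic: shifting a perfect trajectory by c costs c^2*B
    c = 0.07
    assert ((fit.band_q50 + c - series.occupied_means) ** 2).sum() == \
        pytest.approx(c * c * 6)


def test_constant_difference_pool_gives_straight_line(small_table):
    """When every pool difference is exactly d the ensemble median is the
    line start + d * step."""
    names = small_table.names[:6]
    d = 0.05
    pops, series = _exact_series(small_table,
                                 {s: 0.10 + i * d for i, s in enumerate(names)},
                                 n=1000)
    fit = ed.simulate_phase_model(pops, series, PhaseModelSpec(6, (3,)),
                                  small_table, n_iter=200, seed=1)
    expected = 0.10 + d * np.arange(6)
    np.testing.assert_allclose(fit.band_q50, expected, atol=1e-9)
    assert np.all(fit.ssq_per_iter < 1e-18)


def test_simulation_bit_identical_under_seed(small_table, synth_pops, table):
    series = ed.bin_series(synth_pops, table)
    spec = PhaseModelSpec(int(series.occupied.sum()), (10, 20))
    a = ed.simulate_phase_model(synth_pops, series, spec, table,
                                n_iter=300, seed=77)
    b = ed.simulate_phase_model(synth_pops, series, spec, table,
                                n_iter=300, seed=77)
    np.testing.assert_array_equal(a.ssq_per_iter, b.ssq_per_iter)
    np.testing.assert_array_equal(a.band_q50, b.band_q50)
    assert a.fit_score == b.fit_score


def test_empty_phase_pool_raises(small_table):
    names = small_table.names[:5]
    pops, series = _exact_series(small_table,
                                 {s: 0.1 + 0.02 * i for i, s in enumerate(names)})
    with pytest.raises(EmptyPhasePoolError, match="phase 0"):
        ed.simulate_phase_model(pops, series, PhaseModelSpec(5, (1,)),
                                small_table, n_iter=10, seed=0)


def test_bands_are_ordered_and_bounded(synth_pops, table):
    series = ed.bin_series(synth_pops, table)
    spec = PhaseModelSpec(int(series.occupied.sum()), (23, 27))
    fit = ed.simulate_phase_model(synth_pops, series, spec, table,
                                  n_iter=200, seed=5)
    assert np.all(fit.band_q25 <= fit.band_q50 + 1e-15)
    assert np.all(fit.band_q50 <= fit.band_q75 + 1e-15)
    assert fit.band_q25.min() >= 0.0 and fit.band_q75.max() <= 1.0
    assert fit.fit_score > 0


def test_ensemble_mean_matches_cumulative_pool_means(small_table):
    """E[trajectory] = E[start] + cumulative sum of phase-pool means
    (no clamping in this mid-range setting), within 3 SE."""
    rng = np.random.default_rng(8)
    names = small_table.names[:8]
    means = 0.4 + rng.uniform(-0.05, 0.05, 8)
    pops, series = _exact_series(small_table,
                                 {s: round(m, 3) for s, m in zip(names, means)})
    spec = PhaseModelSpec(8, (4,))
    fit = ed.simulate_phase_model(pops, series, spec, small_table,
                                  n_iter=10_000, seed=3)
    obs = series.occupied_means
    diffs = np.diff(obs)
    pool_means = [diffs[:3].mean(), diffs[3:].mean()]  # later-phase rule
    expected = [obs[0]]
    for t in range(7):
        expected.append(expected[-1] + pool_means[spec.phase_of_transition(t)])
    se = fit.traj_sd / np.sqrt(fit.n_iter)
    assert np.all(np.abs(fit.traj_mean - np.array(expected))
                  <= 3 * se + 1e-12)


# -- fitting and ranking ----------------------------------------------------

def test_two_phase_truth_recovered_from_clean_data(small_table):
    """Flat pre-phase then a steady climb from a known stage: the correct
    boundary is the only model whose phase pools are homogeneous, so it
    scores a perfect fit and wins."""
    names = small_table.names
    means = {s: (0.05 if i < 8 else 0.05 + 0.03 * (i - 7))
             for i, s in enumerate(names)}
    pops = make_populations({s: [round(f, 2)] for s, f in means.items()}, n=100)
    series = ed.bin_series(pops, small_table)
    surf = ed.fit_all_models(pops, series, 2, small_table, n_iter=100, seed=2)
    assert surf.best[0].spec.boundaries == (8,)
    assert surf.best[0].fit_score == pytest.approx(1.0 / SSQ_EPSILON)


def test_flat_noiseless_data_ties_break_deterministically(small_table):
    names = small_table.names[:8]
    pops, series = _exact_series(small_table, {s: 0.2 for s in names})
    surf = ed.fit_all_models(pops, series, 3, small_table, n_iter=50, seed=4)
    scores = {f.fit_score for f in surf.fits}
    assert scores == {1.0 / SSQ_EPSILON}       # full symmetry
    # earliest feasible start, then shortest transition, wins the tie
    assert surf.best[0].spec.boundaries == (2, 3)


def test_surface_covers_every_enumerated_model(small_table):
    names = small_table.names[:10]
    pops, series = _exact_series(
        small_table, {s: 0.1 + 0.01 * i for i, s in enumerate(names)})
    surf = ed.fit_all_models(pops, series, 3, small_table, n_iter=20, seed=0)
    assert len(surf.fits) + len(surf.infeasible) == 36  # C(9, 2)
    assert all(sp.boundaries[0] == 1 for sp in surf.infeasible)
    assert len(surf.to_frame()) == len(surf.fits)


def test_ranking_independent_of_simulation_order(small_table):
    """Each spec's score depends only on its own child seed, so the surface
    ranking can be reproduced by simulating specs in any order."""
    names = small_table.names[:9]
    rng = np.random.default_rng(10)
    pops = make_populations(
        {s: list(np.round(rng.uniform(0.1, 0.5, 4), 2)) for s in names}, n=100)
    series = ed.bin_series(pops, small_table)
    surf = ed.fit_all_models(pops, series, 2, small_table, n_iter=60, seed=9)
    specs = ed.enumerate_phase_models(9, 2)
    child = np.random.SeedSequence(9).generate_state(len(specs))
    order = rng.permutation(len(specs))
    rescored = {}
    for i in order:
        try:
            fit = ed.simulate_phase_model(pops, series, specs[i], small_table,
                                          n_iter=60, seed=int(child[i]))
            rescored[specs[i].boundaries] = fit.fit_score
        except EmptyPhasePoolError:
            pass
    for f in surf.fits:
        assert rescored[f.spec.boundaries] == f.fit_score


# -- reporting ---------------------------------------------------------------

def test_report_translates_transition_to_midpoints(table):
    """A planted noiseless Lutetian-Rupelian ramp reports transition
    midpoints 44.5 and 31.0 Ma."""
    sub = table.subset("Danian", "Holocene")
    names = sub.names
    i_lut, i_rup = names.index("Lutetian"), names.index("Rupelian")
    means = {}
    for i, s in enumerate(names):
        if i < i_lut:
            means[s] = 0.05
        elif i <= i_rup:
            means[s] = 0.05 + 0.05 * (i - i_lut + 1)
        else:
            means[s] = 0.05 + 0.05 * (i_rup - i_lut + 1)
    pops, series = _exact_series(sub, means)
    surf = ed.fit_all_models(pops, series, 3, sub, n_iter=60, seed=6)
    rep = ed.best_fit_report(surf, sub)
    assert rep["best"]["transition_start_stage"] == "Lutetian"
    assert rep["best"]["transition_start_midpoint_ma"] == 44.5
    assert rep["best"]["transition_end_stage"] == "Rupelian"
    assert rep["best"]["transition_end_midpoint_ma"] == 31.0
    assert len(rep["five_best"]) == 5
    # report serializes losslessly
    assert json.loads(json.dumps(rep)) == rep


def test_two_phase_report_names_single_boundary(small_table):
    names = small_table.names
    means = {s: (0.05 if i < 8 else round(0.05 + 0.03 * (i - 7), 2))
             for i, s in enumerate(names)}
    pops = make_populations({s: [f, f] for s, f in means.items()}, n=100)
    series = ed.bin_series(pops, small_table)
    surf = ed.fit_all_models(pops, series, 2, small_table, n_iter=60, seed=3)
    rep = ed.best_fit_report(surf, small_table)
    assert rep["k_phases"] == 2
    assert rep["best"]["boundary_stage"] == names[8]
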