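"""Burst search, corrections, stoichiometry, filters and population fits."""

import numpy as np
import pandas as pd
import pytest

import pulsefret as pf
from pulsefret.bursts import (
    CorrectionSet,
    asymmetry_sigma,
    build_burst_table,
    burst_anisotropy,
    call_bursts,
    correct_counts,
    efficiency,
    fit_populations,
    remove_aggregates,
    select_fret_population,
    stoichiometry,
)
from pulsefret.recipes import config_for_scenario
from pulsefret.simulate import SPECIES

TICK = 12.5e-9


def _stream_from_times_us(times_us, detectors=None, nanotimes=None):
    times_us = np.asarray(times_us, dtype=float)
    n = times_us.size
    return pf.PhotonStream(
        timestamps=np.round(times_us * 1e-6 / TICK).astype(np.int64),
        nanotimes=np.zeros(n, dtype=np.int32) if nanotimes is None else nanotimes,
        detectors=np.zeros(n, dtype=np.uint8) if detectors is None else detectors,
    )


# ---------------------------------------------------------------------------
# delta-T burst search
# ---------------------------------------------------------------------------

def test_burst_size_cuts_are_inclusive_30_and_1000():
    """Clusters of 29/30/1000/1001 photons at 10 us gaps, 1 s apart: only
    the 30- and 1000-photon clusters survive the size cut."""
    times = []
    t0 = 0.0
    for size in (29, 30, 1000, 1001):
        times.extend(t0 + 10.0 * np.arange(size))
        t0 += 10.0 * size + 1e6  # 1 s dark gap
    stream = _stream_from_times_us(times)
    bursts = call_bursts(stream, dt_us=100.0, min_photons=30, max_photons=1000)
    sizes = (bursts[:, 1] - bursts[:, 0] + 1).tolist()
    assert sizes == [30, 1000]


def test_no_bursts_when_all_gaps_exceed_dt():
    stream = _stream_from_times_us(np.arange(100) * 200.0)  # 200 us gaps
    assert call_bursts(stream, dt_us=100.0).shape[0] == 0


def test_bursts_are_disjoint_ordered_and_gap_bounded(static_burst_dataset):
    scenario, stream, _, _ = static_burst_dataset
    cleaned, _ = remove_aggregates(stream)
    bursts = call_bursts(cleaned)
    assert np.all(bursts[1:, 0] > bursts[:-1, 1])
    t = cleaned.times_s
    sizes = bursts[:, 1] - bursts[:, 0] + 1
    assert sizes.min() >= 30 and sizes.max() <= 1000
    for i0, i1 in bursts[:50]:
        assert np.all(np.diff(t[i0:i1 + 1]) <= 100e-6 + 1e-12)


# ---------------------------------------------------------------------------
# aggregate removal
# ---------------------------------------------------------------------------

def test_uniform_trace_loses_no_bins():
    rng = np.random.default_rng(0)
    t = np.sort(rng.random(200_000) * 100.0)  # 100 s uniform
    stream = _stream_from_times_us(t * 1e6)
    cleaned, info = remove_aggregates(stream)
    assert info["bins_removed"] == 0
    assert cleaned.n_photons == stream.n_photons


def test_single_hot_bin_removed_exactly():
    # 150 quiet bins plus one bin at ~100x the mean count: with this many
    # bins the outlier dominates neither the mean nor the SD and is cut
    rng = np.random.default_rng(1)
    t = np.sort(rng.random(250_000) * 300.0)
    spike = 7.0 + rng.random(160_000) * 1.0  # inside bin 3 (6-8 s)
    stream = _stream_from_times_us(np.sort(np.concatenate([t, spike])) * 1e6)
    cleaned, info = remove_aggregates(stream, bin_s=2.0, k_sd=6.0)
    assert info["bins_removed"] == 1
    t_clean = cleaned.times_s
    assert not np.any((t_clean >= 6.0) & (t_clean < 8.0))


def test_short_trace_returned_unchanged():
    stream = _stream_from_times_us([0.0, 10.0, 20.0])
    cleaned, info = remove_aggregates(stream)
    assert cleaned.n_photons == 3 and info["bins_removed"] == 0


# ---------------------------------------------------------------------------
# corrections, efficiency, stoichiometry
# ---------------------------------------------------------------------------

def test_identity_corrections_leave_counts_unchanged():
    c = CorrectionSet(leakage=0.0, alpha=0.0, gamma=1.0)
    nd, na, naa, flag = correct_counts(40.0, 25.0, 30.0, 1e-3, c)
    assert (nd, na, naa) == (40.0, 25.0, 30.0)
    assert not flag


def test_leakage_subtraction_cleans_donor_only_burst():
    c = CorrectionSet(leakage=0.05, alpha=0.0)
    nd, na, _, _ = correct_counts(100.0, 5.0, 0.0, 1e-3, c)
    assert na == pytest.approx(0.0)


def test_negative_corrected_counts_floored_and_flagged():
    c = CorrectionSet(leakage=0.5, alpha=0.0)
    _, na, _, flag = correct_counts(100.0, 10.0, 0.0, 1e-3, c)
    assert na == 0.0 and flag


def test_efficiency_values():
    assert efficiency(50, 50) == pytest.approx(0.5)
    assert efficiency(100, 0) == pytest.approx(0.0)
    assert efficiency(17, 33) == pytest.approx(0.66)
    assert np.isnan(efficiency(0, 0))


def test_stoichiometry_limits_and_hand_value():
    # no acceptor-excitation signal: pure donor-only, S = 1
    assert stoichiometry(40, 10, 0) == pytest.approx(1.0)
    # no donor-excitation signal: acceptor-only, S = 0 (gamma_PIE=1, alpha=0)
    assert stoichiometry(0, 0, 80, gamma_pie=1.0, alpha=0.0) == pytest.approx(0.0)
    # independent hand evaluation of the printed formula,
    # delta = 1 * 0.042/0.958, S = (80 - 80 delta)/(160 - 80 delta)
    delta = 0.042 / (1 - 0.042)
    expected = (40 + 40 - delta * 80) / (40 + 40 + 80 - delta * 80)
    assert stoichiometry(40, 40, 80, gamma_pie=1.0, alpha=0.042) == pytest.approx(
        expected, abs=1e-12
    )
    # decimal-arithmetic value of the same expression
    assert expected == pytest.approx(0.48879402347918890, abs=1e-12)


def test_stoichiometry_denominator_variant_differs():
    strict = stoichiometry(40, 40, 80, alpha=0.042, delta_on_naa=False)
    default = stoichiometry(40, 40, 80, alpha=0.042, delta_on_naa=True)
    assert strict != default


def test_delta_is_derived_not_stored():
    c = CorrectionSet(alpha=0.042, gamma_pie=1.3)
    assert c.delta == pytest.approx(1.3 * 0.042 / 0.958)
    assert c.delta_prime == pytest.approx(0.042 / 0.958)


# ---------------------------------------------------------------------------
# asymmetry filter
# ---------------------------------------------------------------------------

def test_asymmetry_sigma_printed_formula_value():
    # T = 1000 us, N_D = N_A = 50: 1000/(2 sqrt 3) * sqrt(0.04) = 57.735 us
    assert asymmetry_sigma(1000.0, 50, 50) == pytest.approx(57.7350269, abs=1e-6)


def test_bleach_like_burst_rejected():
    """All acceptor photons before all donor photons (acceptor bleached)."""
    cmap = pf.ChannelMap()
    n = 60
    times = 10.0 * np.arange(n)  # 10 us apart, T ~ 0.6 ms
    det = np.concatenate([
        np.full(30, cmap.acceptor_parallel),
        np.full(30, cmap.donor_parallel),
    ]).astype(np.uint8)
    nanot = np.full(n, 100, dtype=np.int32)  # all in the donor gate
    stream = _stream_from_times_us(times, detectors=det, nanotimes=nanot)
    bursts = call_bursts(stream, min_photons=30)
    table = build_burst_table(stream, bursts, CorrectionSet(alpha=0.0))
    assert len(table) == 1
    assert not bool(table["asym_dex_pass"].iloc[0])


def test_null_rejection_rate_matches_two_sided_normal_tail(static_burst_dataset):
    """Homogeneous bursts: the 1.5-SD cut rejects ~2 Phi(-1.5) = 13.4%."""
    _, _, _, table = static_burst_dataset
    nonvac = ~table["asym_vacuous"]
    rate = 1.0 - table.loc[nonvac, "asym_dex_pass"].mean()
    n = int(nonvac.sum())
    se = np.sqrt(0.134 * 0.866 / n)
    assert abs(rate - 0.1336) < 4 * se + 0.01


def test_vacuous_asymmetry_passes_but_flagged():
    sig = asymmetry_sigma(1000.0, 0, 50)
    assert not np.isfinite(sig)


# ---------------------------------------------------------------------------
# anisotropy
# ---------------------------------------------------------------------------

def test_anisotropy_values():
    assert burst_anisotropy(40.0, 40.0, 1.0) == pytest.approx(0.0)
    assert burst_anisotropy(50.0, 0.0, 1.0) == pytest.approx(1.0)
    assert burst_anisotropy(60.0, 40.0, 1.0) == pytest.approx(20.0 / 140.0)
    # g-factor rescales the perpendicular channel
    assert burst_anisotropy(60.0, 30.0, 2.0) == pytest.approx(0.0)


def test_simulated_anisotropy_recovered(static_burst_dataset):
    scenario, _, _, table = static_burst_dataset
    mask = select_fret_population(table)
    r = table.loc[mask, "r_anisotropy"].dropna()
    assert abs(r.mean() - scenario.anisotropy) < 0.02


# ---------------------------------------------------------------------------
# FRET population selection
# ---------------------------------------------------------------------------

def test_donor_only_dataset_yields_empty_fret_selection():
    sc = pf.SimScenario(n_bursts=600, true_e=0.5, donor_only_fraction=1.0,
                        rng_seed=3)
    stream, _ = pf.simulate_burst_dataset(sc)
    table, _ = pf.analyze_stream(stream, config_for_scenario(sc))
    mask = select_fret_population(table, (0.3, 0.7))
    assert mask.sum() / max(len(table), 1) < 0.02  # only rare bg-contaminated bursts


def test_wide_window_selection_equals_asymmetry_passing_set(static_burst_dataset):
    _, _, _, table = static_burst_dataset
    wide = select_fret_population(table, (-0.5, 1.5))
    expected = (
        table["asym_dex_pass"] & table["asym_pie_pass"] & table["e_valid"]
    ).to_numpy()
    np.testing.assert_array_equal(wide, expected)


def test_stoichiometry_window_separates_species_with_ground_truth():
    """Among asymmetry-passing bursts, the S window recovers FRET pairs with
    high recall and precision against the generator labels."""
    sc = pf.SimScenario(n_bursts=3000, true_e=0.6, donor_only_fraction=0.3,
                        rng_seed=10)
    stream, truth = pf.simulate_burst_dataset(sc)
    cfg = config_for_scenario(sc)
    cleaned, _ = remove_aggregates(stream)
    bursts = call_bursts(cleaned)
    table = build_burst_table(cleaned, bursts, sc.correction_set())
    labels = truth.photon_burst

    def majority_species(i0, i1):
        lab = labels[i0:i1 + 1]
        lab = lab[lab >= 0]
        return truth.species[np.bincount(lab).argmax()] if lab.size else -1

    species = np.array([
        majority_species(r.i_first, r.i_last) for r in table.itertuples()
    ])
    passing = (table["asym_dex_pass"] & table["asym_pie_pass"]).to_numpy()
    in_window = ((table["S"] >= 0.3) & (table["S"] <= 0.7)).to_numpy()
    is_fret = species == SPECIES["fret_pair"]
    sel = passing & in_window
    ref = passing & is_fret
    tp = (sel & ref).sum()
    precision = tp / max(sel.sum(), 1)
    recall = tp / max(ref.sum(), 1)
    assert precision >= 0.9 and recall >= 0.9


def test_donor_only_bursts_have_s_near_one_and_e_near_zero():
    sc = pf.SimScenario(n_bursts=1200, true_e=0.5, donor_only_fraction=1.0,
                        rng_seed=6)
    stream, _ = pf.simulate_burst_dataset(sc)
    table, _ = pf.analyze_stream(stream, config_for_scenario(sc))
    assert table["S"].median() > 0.9
    assert abs(table["E"].median()) < 0.05


# ---------------------------------------------------------------------------
# population fits
# ---------------------------------------------------------------------------

def test_single_gaussian_fit_recovers_mean():
    rng = np.random.default_rng(0)
    x = rng.normal(0.66, 0.08, 5000)
    fit = fit_populations(x, n_components=1)
    assert abs(fit.means[0] - 0.66) < 0.02
    assert abs(fit.sds[0] - 0.08) < 0.01


def test_pinned_mixture_recovers_fret_component():
    rng = np.random.default_rng(1)
    x = np.concatenate([
        rng.normal(0.0, 0.05, 1500),
        rng.normal(0.30, 0.08, 3500),
    ])
    fit = fit_populations(x, n_components=2, pin_donor_only=True)
    assert fit.donor_only_component == 0
    assert abs(fit.means[0]) <= 0.05
    assert abs(fit.fret_mean - 0.30) < 0.02
    assert abs(fit.weights[0] - 0.3) < 0.03
    assert fit.weights.sum() == pytest.approx(1.0)


def test_degenerate_sample_hits_sd_floor():
    x = np.full(500, 0.42)
    fit = fit_populations(x, n_components=1, sd_floor=0.025)
    assert fit.means[0] == pytest.approx(0.42, abs=1e-6)
    assert fit.sds[0] == pytest.approx(0.025, abs=1e-6)


def test_too_few_bursts_rejected():
    with pytest.raises(ValueError, match="need >= 100"):
        fit_populations(np.random.default_rng(0).normal(0.5, 0.1, 50))


def test_pipeline_is_deterministic(static_burst_dataset):
    scenario, stream, _, table = static_burst_dataset
    table2, _ = pf.analyze_stream(stream, config_for_scenario(scenario))
    pd.testing.assert_frame_equal(table, table2)
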