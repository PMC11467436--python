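"""Ground-truth properties of the synthetic photon-stream generators."""

import numpy as np
import pytest
from scipy import optimize

import pulsefret as pf
from pulsefret.bursts import remove_aggregates
from pulsefret.photons import PHOTON_CLASSES
from pulsefret.simulate import AGGREGATE_LABEL, SPECIES, simulate_titration


def _plain_scenario(**kw):
    """Corrections off, no background: raw counts reflect E directly."""
    base = dict(
        n_bursts=800, true_e=0.5, leakage=0.0, alpha=0.0, gamma=1.0,
        background_rates_hz=(0.0, 0.0, 0.0, 0.0), rng_seed=123,
    )
    base.update(kw)
    return pf.SimScenario(**base)


def test_stream_is_ordered_and_microtimes_in_period(static_burst_dataset):
    _, stream, _, _ = static_burst_dataset
    stream.validate()
    assert np.all(np.diff(stream.timestamps) >= 0)
    period_ch = stream.channel_map.pie_period_ns * 1e-9 / stream.nanotime_resolution
    assert stream.nanotimes.min() >= 0
    assert stream.nanotimes.max() < period_ch


def test_raw_acceptor_fraction_equals_true_e_without_corrections():
    """With leakage/alpha off and gamma 1, the DA fraction of donor-excitation
    photons is binomial around the ground-truth efficiency."""
    sc = _plain_scenario(true_e=0.37)
    stream, truth = pf.simulate_burst_dataset(sc)
    cls = stream.photon_classes()
    signal = truth.photon_burst >= 0
    n_da = int(((cls == PHOTON_CLASSES["DA"]) & signal).sum())
    n_dd = int(((cls == PHOTON_CLASSES["DD"]) & signal).sum())
    n = n_da + n_dd
    frac = n_da / n
    sd = np.sqrt(0.37 * 0.63 / n)
    assert abs(frac - 0.37) < 3 * sd


def test_donor_only_dataset_has_no_acceptor_excitation_signal():
    sc = _plain_scenario(donor_only_fraction=1.0)
    stream, _ = pf.simulate_burst_dataset(sc)
    cls = stream.photon_classes()
    assert (cls == PHOTON_CLASSES["AA"]).sum() == 0  # background is off
    assert (cls == PHOTON_CLASSES["DA"]).sum() == 0  # no FRET, no leakage


def test_donor_microtime_mean_matches_lifetime():
    """Donor-only microtimes are exponential(tau_D) truncated to the gate."""
    sc = _plain_scenario(donor_only_fraction=1.0, n_bursts=1500, tau_d_ns=3.5)
    stream, truth = pf.simulate_burst_dataset(sc)
    cls = stream.photon_classes()
    t = stream.nanotimes_ns[(cls == PHOTON_CLASSES["DD"]) & (truth.photon_burst >= 0)]
    assert t.size > 1e5
    gate_w = 25.0
    truncated_mean = 3.5 - gate_w / np.expm1(gate_w / 3.5)
    se = t.std() / np.sqrt(t.size)
    assert abs(t.mean() - truncated_mean) < 3 * se
    assert abs(t.mean() - 3.5) < 0.05


def test_expected_burst_size_below_one_photon_rejected():
    with pytest.raises(ValueError, match="burst size"):
        pf.SimScenario(mean_brightness_d=0.5, mean_burst_duration_ms=1.0)


def test_exactly_one_of_true_e_and_chain():
    with pytest.raises(ValueError, match="exactly one"):
        pf.SimScenario(true_e=0.5, chain=pf.ChainModel(7.0))
    with pytest.raises(ValueError, match="exactly one"):
        pf.SimScenario(true_e=None, chain=None)


def test_dynamic_chain_burst_means_center_on_quadrature_mean():
    """Fast-exchange chain: burst-mean raw E centers on the <E> integral."""
    # pick the chain whose quadrature mean is 0.3
    def gap(rms):
        return pf.chain_moments(pf.ChainModel(rms, 6.0))[0] - 0.3
    rms = optimize.brentq(gap, 4.0, 20.0)
    chain = pf.ChainModel(rms, 6.0)
    sc = _plain_scenario(true_e=None, chain=chain, n_bursts=1200, rng_seed=5)
    stream, truth = pf.simulate_dynamic_chain_bursts(sc)
    cls = stream.photon_classes()
    signal = truth.photon_burst >= 0
    n_da = ((cls == PHOTON_CLASSES["DA"]) & signal).sum()
    n_dd = ((cls == PHOTON_CLASSES["DD"]) & signal).sum()
    frac = n_da / (n_da + n_dd)
    assert abs(frac - 0.3) < 0.01
    # and the Monte-Carlo chain sampler agrees with the quadrature oracle
    e_draws = chain.sample_efficiency(np.random.default_rng(0), 10**6)
    mean_q, var_q = pf.chain_moments(chain)
    se = e_draws.std() / 1e3
    assert abs(e_draws.mean() - mean_q) < 3 * se


def test_forster_midpoint_reduces_chain_to_static_half():
    assert pf.lifetime.forster_efficiency(6.0, 6.0) == pytest.approx(0.5)
    assert pf.dynamic_line(0.5, 0.0) == pf.static_line(0.5)


def test_injected_aggregates_are_removed_with_signal_retained():
    """Spike photons vanish; >= 99% of single-molecule signal survives."""
    sc = pf.SimScenario(n_bursts=10000, burst_rate_hz=25.0, true_e=0.5,
                        n_aggregates=1, rng_seed=4)
    stream, truth = pf.simulate_burst_dataset(sc)
    cleaned, info = remove_aggregates(stream)
    n_agg = int((truth.photon_burst == AGGREGATE_LABEL).sum())
    n_signal = int((truth.photon_burst >= 0).sum())
    assert n_agg > 10000
    removed = stream.n_photons - cleaned.n_photons
    # everything removed beyond the aggregate photons came out of signal+bg
    assert removed >= 0.999 * n_agg
    assert (removed - n_agg) <= 0.01 * n_signal
    assert info["bins_removed"] >= 1


def test_photon_labels_cover_all_signal():
    sc = _plain_scenario(n_bursts=300)
    stream, truth = pf.simulate_burst_dataset(sc)
    assert truth.photon_burst.size == stream.n_photons
    assert (truth.photon_burst >= 0).all()  # background off: all photons labeled
    assert truth.species.size == sc.n_bursts
    assert set(np.unique(truth.species)) <= set(SPECIES.values())


# ---------------------------------------------------------------------------
# titrations
# ---------------------------------------------------------------------------

def test_noiseless_titration_reproduces_isotherm_bitwise():
    conc = np.logspace(-2, 2, 12)
    series = simulate_titration(1.9, 0.5, conc, readout="fret", noise_sd=0.0)
    expected = pf.isotherm_theta(0.5, conc, 1.9)
    np.testing.assert_array_equal(series.data["theta"].to_numpy(), expected)
    # zero-protein endpoint maps exactly onto the free readout value
    series0 = simulate_titration(1.9, 0.5, np.array([0.0, 1.0, 2.0, 5.0, 10.0]),
                                 readout="anisotropy", noise_sd=0.0)
    assert series0.data["readout"].iloc[0] == series0.endpoints[0]


def test_noiseless_titration_fit_residuals_vanish():
    conc = np.logspace(-2, 2, 12)
    series = simulate_titration(1.9, 0.5, conc, readout="anisotropy", noise_sd=0.0)
    fit = pf.fit_kd(series, endpoints="fixed")
    assert np.all(np.abs(fit.residuals) < 1e-10)
    assert fit.kd_nm == pytest.approx(1.9, abs=1e-6)


def test_negative_noise_rejected():
    with pytest.raises(ValueError, match="noise_sd"):
        simulate_titration(1.9, 0.5, np.array([1.0, 2.0]), noise_sd=-0.1)


# ---------------------------------------------------------------------------
# diffusion scenario validation
# ---------------------------------------------------------------------------

def test_diffusion_scenario_guards():
    with pytest.raises(ValueError, match="10x the focal waist"):
        pf.DiffusionScenario(box_size_um=1.0)
    with pytest.raises(ValueError, match="too coarse"):
        pf.DiffusionScenario(time_step_us=100.0)
    with pytest.raises(ValueError, match="below tau_T"):
        pf.DiffusionScenario(triplet_fraction=0.2, tau_t_us=2.0, time_step_us=2.0)


def test_low_photon_budget_warns():
    sc = pf.DiffusionScenario(duration_s=0.2, rng_seed=0)
    with pytest.warns(UserWarning, match="< 1e5"):
        pf.simulate_diffusion_trace(sc)
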