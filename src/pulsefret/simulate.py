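"""Synthetic photon streams and titration series with known ground truth.

No single-molecule photon data accompanies the measurements this package
reanalyzes, so every downstream stage is validated against simulations whose
ground truth is known exactly.  Two generators are provided:

* a **burst-level generator** (:func:`simulate_burst_dataset`): bursts of a
  diffusing labeled species are laid down directly as photon clusters with
  exponential durations (mean 1 ms) and Poisson photon counts, which is fast
  enough to generate thousands of bursts in seconds.  Used for FRET,
  stoichiometry, anisotropy and lifetime tests.
* a **trace-level Brownian generator** (:func:`simulate_diffusion_trace`):
  molecules perform reflecting Brownian motion through a 3D Gaussian
  detection volume and photons are emitted by inhomogeneous Poisson
  thinning.  Slower but physically faithful in its intensity fluctuations;
  used for burst-calling and FCS tests.

The forward model of the burst generator is the exact inverse of the
analysis correction chain: given a per-photon instantaneous efficiency E, a
donor-excitation photon lands in the donor channel with probability
proportional to (1-E), in the acceptor channel with probability proportional
to gamma*E (detection-efficiency imbalance), donor photons additionally leak
into the acceptor channel with probability l per detected donor photon, and
direct acceptor excitation adds acceptor-channel photons at rate
alpha/(1-alpha) times the acceptor-excitation rate.  Donor microtimes are
exponential with mean tau_D (1 - E) inside the donor PIE gate, so FRET also
shortens the apparent donor lifetime exactly as in the instrument.

Titration series are generated from the exact 2:1 binding isotherm with
Gaussian noise on the bound fraction and a linear map to the configured
free/bound readout endpoints.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binding import TitrationSeries, isotherm_theta
from .bursts import CorrectionSet
from .lifetime import ChainModel
from .photons import ChannelMap, PhotonStream

__all__ = [
    "SimScenario",
    "DiffusionScenario",
    "GroundTruth",
    "SPECIES",
    "simulate_burst_dataset",
    "simulate_dynamic_chain_bursts",
    "simulate_diffusion_trace",
    "simulate_titration",
    "READOUT_ENDPOINTS",
]

#: ground-truth species codes
SPECIES = {"fret_pair": 0, "donor_only": 1, "acceptor_only": 2}

#: photon ground-truth label for background photons
BACKGROUND_LABEL = -1
#: photon ground-truth label for injected aggregate photons
AGGREGATE_LABEL = -2


@dataclass
class SimScenario:
    """Ground-truth parameters for the burst-level generator.

    Brightnesses are candidate photon rates at the detector (photons/ms);
    ``true_e`` and ``chain`` are mutually exclusive ways of specifying the
    FRET ground truth (a fixed efficiency versus a Gaussian-chain distance
    distribution sampled per photon, i.e. the fast-exchange limit).
    Correction factors (leakage, alpha, gamma, gamma_pie) and per-channel
    background rates are part of the ground truth; the matching
    :class:`CorrectionSet` for analysis comes from :meth:`correction_set`.
    """

    n_bursts: int = 3000
    burst_rate_hz: float = 25.0            # bursts per second of trace
    mean_burst_duration_ms: float = 1.0
    mean_brightness_d: float = 100.0       # photons/ms, donor-excitation cycle
    mean_brightness_a: float = 100.0       # photons/ms, acceptor-excitation cycle
    true_e: float | None = 0.5
    chain: ChainModel | None = None
    donor_only_fraction: float = 0.0
    acceptor_only_fraction: float = 0.0
    tau_d_ns: float = 3.5                  # donor-only fluorescence lifetime
    tau_a_ns: float = 1.0                  # acceptor fluorescence lifetime
    background_rates_hz: tuple[float, float, float, float] = (500.0, 500.0, 500.0, 500.0)
    pie_period_ns: float = 50.0            # 20 MHz interleaved repetition
    leakage: float = 0.05
    alpha: float = 0.042
    gamma: float = 1.0
    gamma_pie: float = 1.0
    triplet_fraction: float = 0.0
    tau_t_us: float = 2.0
    anisotropy: float = 0.15               # donor emission anisotropy (g = 1)
    bleach_fraction: float = 0.0           # bursts with mid-burst acceptor bleach
    n_aggregates: int = 0                  # injected slow-aggregate spikes
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("donor_only_fraction", "acceptor_only_fraction",
                     "triplet_fraction", "bleach_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        if self.donor_only_fraction + self.acceptor_only_fraction > 1.0:
            raise ValueError("species fractions sum to more than 1")
        for name in ("burst_rate_hz", "mean_burst_duration_ms", "tau_d_ns",
                     "tau_a_ns", "pie_period_ns", "tau_t_us", "gamma",
                     "gamma_pie"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if (self.true_e is None) == (self.chain is None):
            raise ValueError("exactly one of true_e / chain must be set")
        if self.true_e is not None and not (0.0 <= self.true_e <= 1.0):
            raise ValueError("true_e must lie in [0, 1]")
        if not (0 <= self.alpha < 1):
            raise ValueError("alpha must lie in [0, 1)")
        if self.leakage < 0:
            raise ValueError("leakage must be >= 0")
        if any(r < 0 for r in self.background_rates_hz):
            raise ValueError("background rates must be >= 0")
        expected = self.mean_brightness_d * self.mean_burst_duration_ms
        if expected < 1.0:
            raise ValueError(
                f"expected burst size {expected:.2f} photons < 1; "
                "increase brightness or duration"
            )

    def channel_map(self) -> ChannelMap:
        half = self.pie_period_ns / 2.0
        return ChannelMap(
            donor_gate_ns=(0.0, half),
            acceptor_gate_ns=(half, self.pie_period_ns),
            pie_period_ns=self.pie_period_ns,
        )

    def correction_set(self) -> CorrectionSet:
        """The CorrectionSet that exactly inverts this scenario's distortions.

        Per-class background rates follow from the per-channel rates and the
        fraction of the PIE period covered by each gate (background microtimes
        are uniform over the period).
        """
        cmap = self.channel_map()
        d_frac = (cmap.donor_gate_ns[1] - cmap.donor_gate_ns[0]) / cmap.pie_period_ns
        a_frac = (cmap.acceptor_gate_ns[1] - cmap.acceptor_gate_ns[0]) / cmap.pie_period_ns
        bg = self.background_rates_hz
        return CorrectionSet(
            background_dd_hz=(bg[0] + bg[1]) * d_frac,
            background_da_hz=(bg[2] + bg[3]) * d_frac,
            background_aa_hz=(bg[2] + bg[3]) * a_frac,
            leakage=self.leakage,
            alpha=self.alpha,
            gamma=self.gamma,
            gamma_pie=self.gamma_pie,
        )


@dataclass
class GroundTruth:
    """Everything the generator knows that the analysis must recover."""

    burst_start_s: np.ndarray
    burst_stop_s: np.ndarray
    species: np.ndarray                 # codes per SPECIES
    true_e: np.ndarray                  # per burst (photon-mean for chains); NaN if no donor
    photon_burst: np.ndarray            # per photon: burst index, -1 bg, -2 aggregate
    photon_e: np.ndarray                # per photon instantaneous E (NaN for bg/Aex)
    rng_seed: int = 0

    def burst_dataframe(self) -> pd.DataFrame:
        names = {v: k for k, v in SPECIES.items()}
        return pd.DataFrame({
            "burst_start_s": self.burst_start_s,
            "burst_stop_s": self.burst_stop_s,
            "species": [names[s] for s in self.species],
            "true_e": self.true_e,
        })

    def to_csv(self, path) -> None:
        df = self.burst_dataframe()
        with open(path, "w") as fh:
            fh.write(f"# rng_seed={self.rng_seed}\n")
            df.to_csv(fh, index=False)


def _truncated_exp(rng, scale, width, size=None):
    """Exponential with mean ``scale`` truncated to [0, width) (inverse CDF)."""
    scale = np.asarray(scale, dtype=float)
    u = rng.random(size if size is not None else scale.shape)
    cdf_w = -np.expm1(-width / scale)
    return -scale * np.log1p(-u * cdf_w)


def _telegraph_dark_mask(rng, times, duration, dark_fraction, tau_dark):
    """Two-state blinking: True where a photon falls in a dark dwell.

    Stationary dark probability ``dark_fraction``; mean dark dwell
    ``tau_dark``; mean bright dwell follows from detailed balance.
    """
    if dark_fraction <= 0 or times.size == 0:
        return np.zeros(times.size, dtype=bool)
    tau_bright = tau_dark * (1.0 - dark_fraction) / dark_fraction
    # build alternating dwell edges covering [0, duration]
    edges = [0.0]
    state_dark = [rng.random() < dark_fraction]
    t_now, s = 0.0, state_dark[0]
    while t_now < duration:
        dwell = rng.exponential(tau_dark if s else tau_bright)
        t_now += dwell
        edges.append(t_now)
        s = not s
    edges = np.asarray(edges)
    idx = np.searchsorted(edges, times, side="right") - 1
    first_dark = state_dark[0]
    dark = (idx % 2 == 0) if first_dark else (idx % 2 == 1)
    return dark


def simulate_burst_dataset(scenario: SimScenario) -> tuple[PhotonStream, GroundTruth]:
    """Generate a photon stream of diffusing-molecule bursts plus ground truth.

    Burst durations are exponential (mean ``mean_burst_duration_ms``); burst
    starts are separated by exponential dark gaps at ``burst_rate_hz`` so
    bursts never overlap.  Photon counts per excitation cycle are Poisson in
    the burst duration.  Background photons form a homogeneous Poisson
    process per channel across the whole trace with microtimes uniform over
    the PIE period.  The returned stream is strictly time-ordered.
    """
    scenario.validate()
    rng = np.random.default_rng(scenario.rng_seed)
    n = scenario.n_bursts
    cmap = scenario.channel_map()
    gate_w = cmap.donor_gate_ns[1] - cmap.donor_gate_ns[0]
    aex_start = cmap.acceptor_gate_ns[0]
    aex_w = cmap.acceptor_gate_ns[1] - cmap.acceptor_gate_ns[0]

    # --- burst scaffold ----------------------------------------------------
    durations = rng.exponential(scenario.mean_burst_duration_ms * 1e-3, n)
    gaps = rng.exponential(1.0 / scenario.burst_rate_hz, n)
    starts = np.cumsum(gaps) + np.concatenate(([0.0], np.cumsum(durations[:-1])))
    stops = starts + durations
    total_duration = stops[-1] + rng.exponential(1.0 / scenario.burst_rate_hz)

    u = rng.random(n)
    species = np.full(n, SPECIES["fret_pair"], dtype=np.int8)
    species[u < scenario.donor_only_fraction] = SPECIES["donor_only"]
    species[(u >= scenario.donor_only_fraction)
            & (u < scenario.donor_only_fraction + scenario.acceptor_only_fraction)
            ] = SPECIES["acceptor_only"]
    has_donor = species != SPECIES["acceptor_only"]
    has_acceptor = species != SPECIES["donor_only"]

    bleach_burst = (rng.random(n) < scenario.bleach_fraction) & (
        species == SPECIES["fret_pair"]
    )
    bleach_time = np.where(bleach_burst, rng.random(n) * durations, np.inf)

    times_parts: list[np.ndarray] = []
    micro_parts: list[np.ndarray] = []
    det_parts: list[np.ndarray] = []
    label_parts: list[np.ndarray] = []
    e_parts: list[np.ndarray] = []

    k_norm = 1.0 / ((1.0 + scenario.leakage) * max(1.0, scenario.gamma))

    # --- donor-excitation photons ------------------------------------------
    rate_d = scenario.mean_brightness_d * 1e3  # photons/s
    n_dex = rng.poisson(rate_d * durations * has_donor)
    total_dex = int(n_dex.sum())
    if total_dex:
        burst_id = np.repeat(np.arange(n), n_dex)
        t_rel = rng.random(total_dex) * durations[burst_id]
        t_abs = starts[burst_id] + t_rel
        if scenario.chain is not None:
            e_photon = scenario.chain.sample_efficiency(rng, total_dex)
        else:
            e_photon = np.full(total_dex, float(scenario.true_e))
        e_photon = np.where(
            species[burst_id] == SPECIES["donor_only"], 0.0, e_photon
        )
        # acceptor bleached mid-burst: photons after the bleach have E = 0
        e_photon = np.where(t_rel > bleach_time[burst_id], 0.0, e_photon)

        # outcome: DD / DA(fret) / DA(leak) / undetected
        p_dd = (1.0 - e_photon) * k_norm
        p_leak = p_dd * scenario.leakage
        p_fret = e_photon * k_norm * scenario.gamma
        v = rng.random(total_dex)
        cat_dd = v < p_dd
        cat_leak = (~cat_dd) & (v < p_dd + p_leak)
        cat_fret = (~cat_dd) & (~cat_leak) & (v < p_dd + p_leak + p_fret)
        keep = cat_dd | cat_leak | cat_fret

        tau_eff = scenario.tau_d_ns * np.maximum(1.0 - e_photon, 1e-3)
        micro = np.empty(total_dex)
        donor_em = cat_dd | cat_leak
        micro[donor_em] = _truncated_exp(rng, tau_eff[donor_em], gate_w)
        if np.any(cat_fret):
            # donor excited-state dwell then acceptor decay, kept inside the gate
            m = (
                rng.exponential(1.0, cat_fret.sum()) * tau_eff[cat_fret]
                + rng.exponential(scenario.tau_a_ns, cat_fret.sum())
            )
            redraw = m >= gate_w
            while np.any(redraw):
                k = int(redraw.sum())
                m[redraw] = (
                    rng.exponential(1.0, k) * tau_eff[cat_fret][redraw]
                    + rng.exponential(scenario.tau_a_ns, k)
                )
                redraw = m >= gate_w
            micro[cat_fret] = m

        det = np.empty(total_dex, dtype=np.uint8)
        p_par = (1.0 + 2.0 * scenario.anisotropy) / (2.0 + scenario.anisotropy)
        par = rng.random(total_dex) < p_par
        det[donor_em] = np.where(
            par[donor_em], cmap.donor_parallel, cmap.donor_perpendicular
        )
        det[cat_leak] = np.where(
            par[cat_leak], cmap.acceptor_parallel, cmap.acceptor_perpendicular
        )
        acc = cat_fret
        det[acc] = np.where(
            rng.random(total_dex)[acc] < 0.5,
            cmap.acceptor_parallel, cmap.acceptor_perpendicular,
        )

        times_parts.append(t_abs[keep])
        micro_parts.append(micro[keep])
        det_parts.append(det[keep])
        label_parts.append(burst_id[keep])
        e_parts.append(e_photon[keep])

    # --- acceptor-excitation photons (AA) ----------------------------------
    rate_a = scenario.mean_brightness_a * 1e3
    acc_time = np.where(has_acceptor, np.minimum(durations, bleach_time), 0.0)
    n_aa = rng.poisson(rate_a * acc_time)
    total_aa = int(n_aa.sum())
    if total_aa:
        burst_id = np.repeat(np.arange(n), n_aa)
        t_abs = starts[burst_id] + rng.random(total_aa) * acc_time[burst_id]
        micro = aex_start + _truncated_exp(
            rng, np.full(total_aa, scenario.tau_a_ns), aex_w
        )
        det = np.where(
            rng.random(total_aa) < 0.5,
            cmap.acceptor_parallel, cmap.acceptor_perpendicular,
        ).astype(np.uint8)
        times_parts.append(t_abs)
        micro_parts.append(micro)
        det_parts.append(det)
        label_parts.append(burst_id)
        e_parts.append(np.full(total_aa, np.nan))

    # --- direct acceptor excitation by the donor laser ---------------------
    delta_prime = scenario.alpha / (1.0 - scenario.alpha)
    n_direct = rng.poisson(delta_prime * rate_a * acc_time)
    total_dir = int(n_direct.sum())
    if total_dir:
        burst_id = np.repeat(np.arange(n), n_direct)
        t_abs = starts[burst_id] + rng.random(total_dir) * acc_time[burst_id]
        micro = _truncated_exp(rng, np.full(total_dir, scenario.tau_a_ns), gate_w)
        det = np.where(
            rng.random(total_dir) < 0.5,
            cmap.acceptor_parallel, cmap.acceptor_perpendicular,
        ).astype(np.uint8)
        times_parts.append(t_abs)
        micro_parts.append(micro)
        det_parts.append(det)
        label_parts.append(burst_id)
        e_parts.append(np.full(total_dir, np.nan))

    # --- triplet blinking: drop signal photons in dark dwells ---------------
    if scenario.triplet_fraction > 0 and times_parts:
        times_all = np.concatenate(times_parts)
        labels_all = np.concatenate(label_parts)
        drop = np.zeros(times_all.size, dtype=bool)
        for b in range(n):
            sel = labels_all == b
            if not np.any(sel):
                continue
            drop[sel] = _telegraph_dark_mask(
                rng, times_all[sel] - starts[b], durations[b],
                scenario.triplet_fraction, scenario.tau_t_us * 1e-6,
            )
        keep = ~drop
        times_parts = [times_all[keep]]
        micro_parts = [np.concatenate(micro_parts)[keep]]
        det_parts = [np.concatenate(det_parts)[keep]]
        label_parts = [labels_all[keep]]
        e_parts = [np.concatenate(e_parts)[keep]]

    # --- injected aggregates -------------------------------------------------
    for _ in range(scenario.n_aggregates):
        t0 = rng.random() * max(total_duration - 0.3, 0.0)
        dur = 0.2
        n_agg = rng.poisson(200e3 * dur)  # 200 photons/ms: far above any burst
        t_abs = t0 + rng.random(n_agg) * dur
        micro = rng.random(n_agg) * scenario.pie_period_ns
        det = rng.integers(0, 4, n_agg).astype(np.uint8)
        times_parts.append(t_abs)
        micro_parts.append(micro)
        det_parts.append(det)
        label_parts.append(np.full(n_agg, AGGREGATE_LABEL, dtype=np.int64))
        e_parts.append(np.full(n_agg, np.nan))

    # --- background ----------------------------------------------------------
    for ch, rate in enumerate(scenario.background_rates_hz):
        if rate <= 0:
            continue
        n_bg = rng.poisson(rate * total_duration)
        t_abs = rng.random(n_bg) * total_duration
        micro = rng.random(n_bg) * scenario.pie_period_ns
        times_parts.append(t_abs)
        micro_parts.append(micro)
        det_parts.append(np.full(n_bg, ch, dtype=np.uint8))
        label_parts.append(np.full(n_bg, BACKGROUND_LABEL, dtype=np.int64))
        e_parts.append(np.full(n_bg, np.nan))

    # --- assemble, sort, quantize -------------------------------------------
    times = np.concatenate(times_parts) if times_parts else np.empty(0)
    micro = np.concatenate(micro_parts) if micro_parts else np.empty(0)
    det = np.concatenate(det_parts) if det_parts else np.empty(0, dtype=np.uint8)
    labels = np.concatenate(label_parts) if label_parts else np.empty(0, dtype=np.int64)
    e_phot = np.concatenate(e_parts) if e_parts else np.empty(0)
    order = np.argsort(times, kind="stable")
    times, micro, det = times[order], micro[order], det[order]
    labels, e_phot = labels[order], e_phot[order]

    ts_res, nt_res = 12.5e-9, 16e-12
    stream = PhotonStream(
        timestamps=np.round(times / ts_res).astype(np.int64),
        nanotimes=np.minimum(
            (micro * 1e-9 / nt_res).astype(np.int32),
            int(scenario.pie_period_ns * 1e-9 / nt_res) - 1,
        ),
        detectors=det,
        timestamp_resolution=ts_res,
        nanotime_resolution=nt_res,
        channel_map=cmap,
        metadata={"generator": "simulate_burst_dataset",
                  "rng_seed": scenario.rng_seed},
    )

    # per-burst true E: photon-mean for chains, scenario value for static
    true_e = np.full(n, np.nan)
    if scenario.chain is not None:
        sums = np.zeros(n)
        cnts = np.zeros(n)
        sig = labels >= 0
        good = sig & np.isfinite(e_phot)
        np.add.at(sums, labels[good], e_phot[good])
        np.add.at(cnts, labels[good], 1.0)
        with np.errstate(invalid="ignore"):
            true_e = np.where(cnts > 0, sums / cnts, np.nan)
    else:
        true_e[species == SPECIES["fret_pair"]] = float(scenario.true_e)
        true_e[species == SPECIES["donor_only"]] = 0.0

    truth = GroundTruth(
        burst_start_s=starts,
        burst_stop_s=stops,
        species=species,
        true_e=true_e,
        photon_burst=labels,
        photon_e=e_phot,
        rng_seed=scenario.rng_seed,
    )
    return stream, truth


def simulate_dynamic_chain_bursts(
    scenario: SimScenario,
) -> tuple[PhotonStream, GroundTruth]:
    """Burst dataset for a dynamically averaged Gaussian chain.

    Each photon's instantaneous efficiency is redrawn from the chain's E(r)
    distribution (fast-exchange limit: distance dynamics much faster than
    the burst duration), and the donor microtime is drawn with that photon's
    efficiency.  Requires ``scenario.chain``.
    """
    if scenario.chain is None:
        raise ValueError("scenario.chain must be set for a dynamic-chain dataset")
    return simulate_burst_dataset(scenario)


# ---------------------------------------------------------------------------
# Brownian trace generator (FCS ground truth)
# ---------------------------------------------------------------------------

@dataclass
class DiffusionScenario:
    """Ground truth for the Brownian trace generator.

    The detection profile is a 3D Gaussian, exp(-2 rho^2/w_xy^2 -
    2 z^2/(s w_xy)^2); the theoretical diffusion time is w_xy^2 / (4 D).
    Molecules move by reflecting Brownian motion in a box of ``box_size_um``
    per lateral side and ``box_size_um * aspect_ratio`` axially.
    """

    n_molecules: int = 25
    box_size_um: float = 3.0
    diffusion_um2_s: float = 90.0
    w_xy_um: float = 0.3
    aspect_ratio: float = 3.0
    duration_s: float = 4.0
    time_step_us: float = 2.0
    brightness_at_center: float = 1000.0   # photons/ms at the focus center
    triplet_fraction: float = 0.0
    tau_t_us: float = 5.0
    background_rates_hz: tuple[float, float, float, float] = (200.0, 0.0, 200.0, 0.0)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_molecules < 1:
            raise ValueError("need at least one molecule")
        for name in ("box_size_um", "diffusion_um2_s", "w_xy_um",
                     "aspect_ratio", "duration_s", "time_step_us",
                     "brightness_at_center", "tau_t_us"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not (0 <= self.triplet_fraction < 1):
            raise ValueError("triplet_fraction must lie in [0, 1)")
        dt = self.time_step_us * 1e-6
        tau_diff = self.w_xy_um**2 / (4.0 * self.diffusion_um2_s)
        if dt > tau_diff / 20.0:
            raise ValueError(
                f"time_step {self.time_step_us} us too coarse for the "
                f"diffusion time {tau_diff * 1e3:.3g} ms"
            )
        if self.triplet_fraction > 0 and dt > self.tau_t_us * 1e-6 / 2.0:
            raise ValueError("time_step must be well below tau_T")
        if self.box_size_um < 10.0 * self.w_xy_um:
            raise ValueError("box must be at least 10x the focal waist")

    @property
    def theory_diffusion_time_s(self) -> float:
        return self.w_xy_um**2 / (4.0 * self.diffusion_um2_s)

    def expected_photons(self) -> float:
        """Expected signal photons over the trace (closed-form mean intensity)."""
        wz = self.aspect_ratio * self.w_xy_um
        vol_box = self.box_size_um**2 * (self.box_size_um * self.aspect_ratio)
        conc = self.n_molecules / vol_box
        integral = (np.pi / 2.0) ** 1.5 * self.w_xy_um**2 * wz
        return self.brightness_at_center * 1e3 * conc * integral * self.duration_s


def _fold(x, width):
    """Reflect coordinates into [0, width] (triangle wave)."""
    y = np.mod(x, 2.0 * width)
    return width - np.abs(y - width)


def simulate_diffusion_trace(scenario: DiffusionScenario) -> PhotonStream:
    """Photon stream from molecules diffusing through a Gaussian focus.

    Photons are drawn per time step by Poisson thinning of the summed
    molecular intensities, split evenly between the donor and acceptor
    detection channels (a doubly labeled species, so the two channels
    cross-correlate).  Triplet blinking is a per-molecule two-state
    telegraph with mean dark dwell tau_T.
    """
    scenario.validate()
    if scenario.expected_photons() < 1e5:
        warnings.warn(
            f"expected signal photons {scenario.expected_photons():.3g} < 1e5; "
            "correlation curves will be noisy", stacklevel=2,
        )
    rng = np.random.default_rng(scenario.rng_seed)
    dt = scenario.time_step_us * 1e-6
    n_steps = int(round(scenario.duration_s / dt))
    n_mol = scenario.n_molecules
    lx = ly = scenario.box_size_um
    lz = scenario.box_size_um * scenario.aspect_ratio
    widths = np.array([lx, ly, lz])
    center = widths / 2.0
    w2 = scenario.w_xy_um**2
    wz2 = (scenario.aspect_ratio * scenario.w_xy_um) ** 2
    step_sd = np.sqrt(2.0 * scenario.diffusion_um2_s * dt)
    rate_per_step = scenario.brightness_at_center * 1e3 * dt

    # per-molecule triplet switching times over the whole trace
    dark_edges: list[np.ndarray] = []
    dark_first: list[bool] = []
    if scenario.triplet_fraction > 0:
        tau_dark = scenario.tau_t_us * 1e-6
        tau_bright = tau_dark * (1 - scenario.triplet_fraction) / scenario.triplet_fraction
        for _ in range(n_mol):
            first = bool(rng.random() < scenario.triplet_fraction)
            edges, t_now, s = [0.0], 0.0, first
            while t_now < scenario.duration_s:
                t_now += rng.exponential(tau_dark if s else tau_bright)
                edges.append(t_now)
                s = not s
            dark_edges.append(np.asarray(edges))
            dark_first.append(first)

    pos = (rng.random((n_mol, 3)) * widths).astype(np.float32)
    widths = widths.astype(np.float32)
    center = center.astype(np.float32)
    chunk = 100_000
    times_list: list[np.ndarray] = []
    for c0 in range(0, n_steps, chunk):
        cs = min(chunk, n_steps - c0)
        disp = rng.standard_normal((cs, n_mol, 3), dtype=np.float32)
        disp *= np.float32(step_sd)
        traj = pos + np.cumsum(disp, axis=0)
        for ax in range(3):
            traj[:, :, ax] = _fold(traj[:, :, ax], widths[ax])
        pos = traj[-1].copy()
        rel = traj - center
        inten = np.exp(
            -2.0 * (rel[:, :, 0] ** 2 + rel[:, :, 1] ** 2) / w2
            - 2.0 * rel[:, :, 2] ** 2 / wz2
        )
        if scenario.triplet_fraction > 0:
            t_steps = (c0 + np.arange(cs)) * dt
            for m in range(n_mol):
                idx = np.searchsorted(dark_edges[m], t_steps, side="right") - 1
                dark = (idx % 2 == 0) if dark_first[m] else (idx % 2 == 1)
                inten[dark, m] = 0.0
        counts = rng.poisson(inten * rate_per_step)
        tot = counts.sum(axis=1)
        nz = np.nonzero(tot)[0]
        if nz.size:
            step_idx = np.repeat(nz, tot[nz])
            t_abs = (c0 + step_idx) * dt + rng.random(step_idx.size) * dt
            times_list.append(t_abs)

    times = np.concatenate(times_list) if times_list else np.empty(0)
    cmap = ChannelMap()
    donor_half = rng.random(times.size) < 0.5
    det = np.where(donor_half, cmap.donor_parallel, cmap.acceptor_parallel).astype(np.uint8)
    gate_w = cmap.donor_gate_ns[1] - cmap.donor_gate_ns[0]
    micro = np.where(
        donor_half,
        rng.random(times.size) * gate_w,
        cmap.acceptor_gate_ns[0] + rng.random(times.size) * gate_w,
    )

    bg_t, bg_d, bg_m = [times], [det], [micro]
    for ch, rate in enumerate(scenario.background_rates_hz):
        if rate <= 0:
            continue
        n_bg = rng.poisson(rate * scenario.duration_s)
        bg_t.append(rng.random(n_bg) * scenario.duration_s)
        bg_d.append(np.full(n_bg, ch, dtype=np.uint8))
        bg_m.append(rng.random(n_bg) * cmap.pie_period_ns)
    times = np.concatenate(bg_t)
    det = np.concatenate(bg_d)
    micro = np.concatenate(bg_m)
    order = np.argsort(times, kind="stable")

    ts_res, nt_res = 12.5e-9, 16e-12
    return PhotonStream(
        timestamps=np.round(times[order] / ts_res).astype(np.int64),
        nanotimes=np.minimum(
            (micro[order] * 1e-9 / nt_res).astype(np.int32),
            int(cmap.pie_period_ns * 1e-9 / nt_res) - 1,
        ),
        detectors=det[order],
        timestamp_resolution=ts_res,
        nanotime_resolution=nt_res,
        channel_map=cmap,
        metadata={
            "generator": "simulate_diffusion_trace",
            "rng_seed": scenario.rng_seed,
            "theory_diffusion_time_s": scenario.theory_diffusion_time_s,
        },
    )


# ---------------------------------------------------------------------------
# titrations
# ---------------------------------------------------------------------------

#: (free, bound) readout endpoints per readout kind; anisotropy and FRET
#: shift are dimensionless, FCS diffusion times are in ms
READOUT_ENDPOINTS = {
    "anisotropy": (0.05, 0.20),
    "fret": (0.50, 0.75),
    "fcs": (0.35, 0.60),
}


def simulate_titration(
    kd_nm: float,
    c_dna_nm: float,
    concentrations_nm,
    readout: str = "anisotropy",
    noise_sd: float = 0.0,
    rng_seed: int = 0,
    endpoints: tuple[float, float] | None = None,
) -> TitrationSeries:
    """Titration series obeying the exact 2:1 isotherm plus Gaussian noise.

    The bound fraction theta at each protein concentration comes from
    :func:`pulsefret.binding.isotherm_theta`; Gaussian noise of SD
    ``noise_sd`` is added to theta, then mapped linearly onto the readout's
    (free, bound) endpoints.  With ``noise_sd=0`` the stored theta values are
    bitwise equal to ``isotherm_theta``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if readout not in READOUT_ENDPOINTS:
        raise ValueError(f"readout must be one of {sorted(READOUT_ENDPOINTS)}")
    conc = np.asarray(concentrations_nm, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentrations must be nonnegative")
    if np.any(np.diff(conc) < 0):
        raise ValueError("concentrations must be sorted ascending")
    rng = np.random.default_rng(rng_seed)
    theta = isotherm_theta(c_dna_nm, conc, kd_nm)
    if noise_sd > 0:
        theta = theta + rng.normal(0.0, noise_sd, conc.size)
    x_free, x_bound = endpoints or READOUT_ENDPOINTS[readout]
    values = x_free + (x_bound - x_free) * theta
    data = pd.DataFrame({"c_mitf_nm": conc, "theta": theta, "readout": values})
    return TitrationSeries(
        data=data,
        c_dna_nm=c_dna_nm,
        readout=readout,
        endpoints=(x_free, x_bound),
        metadata={"true_kd_nm": kd_nm, "noise_sd": noise_sd, "rng_seed": rng_seed},
    )
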