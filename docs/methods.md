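# Methods

This note documents the models implemented in pulsefret, the conventions
adopted where the field's notation is loose, the default parameters and why
they were chosen, what the synthetic-data generators do and do not emulate,
and the numerical choices that matter when reproducing results.

## Photon data model

A measurement is a strictly time-ordered photon list. Macrotimes are integer
ticks at 12.5 ns (an 80 MHz clock, a common convention for counting
hardware); microtimes are integer TCSPC channels at 16 ps over a 50 ns sync
period, matching pulsed interleaved excitation at 20 MHz. The donor laser
fires at the start of the period and the acceptor laser half-way through, so
the PIE gates default to [0, 25) ns (donor excitation) and [25, 50) ns
(acceptor excitation). Four detectors split the emission by polarization and
color. Gate membership is resolved in integer channel units by truncation,
so a boundary channel belongs to the later gate — the same convention a
TCSPC card applies when it quantizes arrival times; without this, photons
emitted at exactly the gate edge are systematically misclassified.

Files round-trip through either a Photon-HDF5-style HDF5 layout
(`/photon_data/{timestamps,nanotimes,detectors}` plus resolution and
channel-map metadata) or a gzipped columnar text file with the same metadata
in header lines. Every output embeds the package version, the configuration
hash and the RNG seed.

## Burst pipeline

**Aggregate removal.** The trace is cut into 2 s bins; bins whose count
exceeds the trace mean by more than 6 SD are dropped. Both statistics are
computed once, on the input, in a single pass — removing a bin does not
trigger re-thresholding. Note an intrinsic property of this rule: with
fewer than ~40 bins no bin can mathematically exceed mean + 6 SD (the
maximum attainable z-score of one outlier among N values is ≈ √N), so short
traces pass through unchanged; the rule is designed for traces of minutes.

**Burst search.** Delta-T over *all* photons, not donor-excitation photons
only, because the PIE stoichiometry needs the acceptor-excitation (AA)
photons of the same molecule inside the same burst. A burst is a maximal run
of photons with all inter-photon gaps ≤ dT (default 100 µs); runs with fewer
than 30 or more than 1000 photons are discarded, both bounds inclusive.

**Corrections.** The correction chain runs in a fixed order: background
(rate × duration per excitation-gate/detection-color class), donor leakage
(n_DA ← n_DA − l·n_DD), direct acceptor excitation
(n_DA ← n_DA − α/(1−α)·n_AA), then the detection-efficiency ratio
(n′_D = γ·n_DD). The order matters only at the percent level for realistic
factors, but it is part of the contract and the simulator inverts exactly
this chain. Negative intermediate counts are floored at zero and flagged
per burst. Defaults: α = 0.042, l = 0, γ = γ_PIE = 1; measured values must
be supplied for real data.

**Stoichiometry.** S = (n_DA + n_DD − δ·n_AA)/(n_DA + n_DD + γ_PIE·n_AA −
δ·n_AA) with δ = γ_PIE·α/(1−α), evaluated on background-subtracted counts.
δ is always derived, never stored. The δ term in the denominator multiplies
n_AA (symmetric with the numerator); a variant multiplying n_DA instead is
available via `stoich_delta_on_naa = false` for comparison with analyses
that use that reading. FRET pairs are selected with S in [0.3, 0.7] — the
window is a convention for "around 0.5" and is configurable.

**Asymmetry filter.** For N photons uniform over a burst of duration T, the
mean arrival time has variance T²/(12N); the difference between the donor
and acceptor mean arrival times therefore has null SD
σ = T/(2√3)·√(1/N_D + 1/N_A). The filter statistic is |⟨t_A⟩ − ⟨t_D⟩|/σ,
cut at 1.5. Applied twice: to donor-excitation donor vs acceptor emission
(acceptor photobleaching makes acceptor photons arrive early) and to
acceptor-excitation acceptor vs donor-excitation donor emission. Bursts
with an empty photon class pass vacuously but carry a flag. A consequence
worth stating: by construction the cut rejects ≈ 2Φ(−1.5) ≈ 13% of
*genuine* bursts per test (~21% for both), which bounds the recall of any
downstream selection; this is the filter working as designed, not a loss
of efficiency to be tuned away.

**Anisotropy.** r = (I_∥ − g·I_⊥)/(I_∥ + 2g·I_⊥) on donor-excitation donor
photons — the standard steady-state relation, adopted here as a documented
convention (g defaults to 1 and must be calibrated for real optics).

**Population fits.** Maximum-likelihood Gaussian mixtures (one or two
components) on unbinned per-burst E, optimized by L-BFGS-B on (means,
log-SDs, logit weight) with the donor-only mean constrained to
[−0.05, 0.05] when pinned. Component SDs are floored at the histogram bin
width (0.025) so a degenerate sample cannot collapse the likelihood; the
0.025-wide histogram on [−0.1, 1.1] is for display only. Mean errors are
reported as 2 SD from the inverse observed information (numerical Hessian).
Three deterministic restarts with jittered initial means guard against the
label-swap local optimum. E values of bursts are *not* clipped to [0, 1]:
shot noise legitimately places them slightly outside.

## Lifetime-versus-efficiency analysis

The per-burst donor lifetime is estimated as the mean microtime of
donor-channel donor-excitation photons, minus a fixed instrument-response
offset (no IRF deconvolution — a deliberate non-goal; the offset default is
0). Because background photons inside a burst carry microtimes uniform over
the gate, the estimator subtracts their expected contribution
(rate × duration photons at the gate midpoint); at 1 kHz total donor-channel
background this bias would otherwise be ≈ +0.05 ns. The intrinsic donor
lifetime τ_D comes from the donor-only population (S ≥ 0.8, at least 50
bursts), and the per-burst ratio ρ = ⟨t_D⟩/τ_D is plotted against E.

For a fixed distance, ρ = 1 − E. For distances fluctuating much faster than
the burst duration (fast exchange), photons are preferentially emitted while
the pair is far apart, and with x = 1 − E(r):

    E[x²]/E[x] = E[x] + Var(x)/E[x]  ⇒  ρ = 1 − ⟨E⟩ + σ²/(1 − ⟨E⟩)

which the simulator reproduces exactly by construction (per-photon E
redraw), and the burst generator's donor microtimes, exponential with mean
τ_D(1 − E_photon), realize physically.

The distance distribution is the 3D Gaussian chain,
P(r) ∝ r² exp(−3r²/2⟨r²⟩) — the standard model for an intrinsically
disordered segment; self-avoiding-walk and worm-like-chain distributions
are out of scope. E(r) = 1/(1 + (r/R₀)⁶). Moments ⟨E⟩ and σ² are computed
by adaptive quadrature on (0, 10√⟨r²⟩] with absolute tolerance 1e−8 (the
integrand is smooth; a break point at R₀ helps the subdivision). The
Förster radius is not determined by the analysis and defaults to 6.0 nm, a
plausible value for bright red/far-red dye pairs; it is configurable and
recorded in output metadata. σ² ≤ ⟨E⟩(1 − ⟨E⟩) always (a [0,1]-valued
variable), so the dynamic line is bounded. As ⟨E⟩ → 1 the dynamic ratio
diverges; it is capped (default 10) and capped values should be treated as
flagged.

## FCS

The correlator is multi-tau: counts are binned at the smallest requested
lag, correlated at 16 lags per octave by direct dot products, then rebinned
by 2. Normalization is ⟨n_i⟩⟨n_j⟩ over the overlapping windows (symmetric);
the ⟨n_i⟩² variant found in some method descriptions is available as
`normalization="donor_squared"` — for channels with equal mean rates the
two coincide. Standard errors come from splitting the trace into segments
(default 4) and correlating each independently; lags beyond 10% of the
trace duration are rejected as badly biased. At 16 points per octave the
triangular smoothing of coarsened bins stays below ~0.5% relative for a
diffusion-shaped decay.

The fit model is single-component 3D diffusion with one triplet term,

    G(τ) = 1 + a(1 + n_T e^(−τ/τ_T)) / ((1 + τ/τ_D)·√(1 + τ/(s²τ_D)))

weighted least squares (lmfit), with the axial-to-lateral aspect ratio s
fixed by default: s is an instrument property that photon data of this kind
cannot usefully constrain. When the fitted triplet amplitude is within one
SD of zero, τ_T is unidentifiable and flagged. The normalized diffusion-time
shift between free and bound endpoints, (τ_sample − τ_free)/(τ_bound −
τ_free), is clipped to [0, 1] with a flag.

## Binding isotherm

For a probe at concentration c_DNA comparable to K_D, the bound fraction is
the exact quadratic solution of 2:1 mass action (the protein dimer treated
as one binding entity; whether supplied concentrations are monomer or dimer
units is input metadata, default "as supplied"):

    θ = (c_DNA + K_D + c_P − √((c_DNA + c_P + K_D)² − 4·c_DNA·c_P)) / (2·c_DNA)

evaluated as θ = 2c_P/(b + √(b² − 4·c_DNA·c_P)), b = c_DNA + c_P + K_D,
which avoids catastrophic cancellation when K_D ≪ concentrations (verified
stable at K_D ten orders of magnitude below the concentrations; the only
residual noise is O(√ε) at the exact stoichiometric corner K_D = 0,
c_P = c_DNA). Readouts are assumed linear in θ between a free and a bound
endpoint; endpoints may be fixed or co-fitted with K_D (both modes provided
— published figures rarely state which was used). Errors are 2 SD from the
fit covariance. Fits with K_D below half the probe concentration are
flagged "too tight to compare accurately": below that the titration shape
is dominated by probe depletion and carries little information about K_D.

## Synthetic data: what it emulates and what it does not

**Burst-level generator** (fast; used for FRET/stoichiometry/lifetime/
anisotropy tests). Bursts have exponential durations (mean 1 ms) and are
laid down sequentially with exponential dark gaps (default 25 bursts/s), so
they never overlap. Photon counts per excitation cycle are Poisson;
per-photon channel assignment inverts the correction chain exactly: a
donor-excitation photon with instantaneous efficiency E lands in the donor
channel with probability ∝ (1−E), in the acceptor channel with probability
∝ γE, donor photons leak with probability l each, and direct excitation
adds acceptor-channel photons at α/(1−α) times the AA rate. Brightness
parameters (default 100 photons/ms per excitation cycle) are candidate
rates; detected rates carry a factor 1/((1+l)·max(1,γ)) so probabilities
stay below one. Donor microtimes are exponential with mean τ_D(1 −
E_photon) (default τ_D = 3.5 ns, typical of bright green-excited donors),
truncated to the gate by inverse-CDF sampling — the truncation biases the
mean by −0.02 ns at τ_D = 3.5 ns and 25 ns gates, below the estimator
tolerances used here. Acceptor decays use τ_A = 1.0 ns. Background is
homogeneous Poisson per channel (default 500 Hz each) with microtimes
uniform over the period. Optional: donor-only/acceptor-only species
fractions, per-burst triplet telegraph blinking, mid-burst acceptor
bleaching (to exercise the asymmetry filter), and injected 0.2 s aggregate
spikes (to exercise aggregate removal). Static E and fast-exchange chain
modes are mutually exclusive; the chain mode redraws E per photon, i.e. it
represents only the fast-exchange limit — slower exchange regimes are out
of scope. Ground truth (per-burst species, true E, boundaries; per-photon
burst labels and instantaneous E) is returned alongside.

What it does not emulate: diffusion-shaped burst intensity profiles,
detector afterpulsing and dead time, IRF shape beyond a fixed offset,
photobleaching kinetics (bleaching is an explicit scenario flag instead),
spectral crosstalk beyond a single leakage factor. Passing tests therefore
show the *analysis chain* is correct and unbiased under the stated model,
not that it is robust to every instrument artifact.

**Brownian trace generator** (faithful; used for burst-calling and FCS
tests). Molecules perform reflecting Brownian motion (float32 increments;
accumulated position error ~1e−5 µm per chunk, far below the step size) in
a box of 3 µm laterally and 3·s µm axially, ≥10× the focal waist; emission
follows a 3D Gaussian detection profile with lateral waist 0.3 µm and
aspect ratio s = 3, and photons are drawn by Poisson thinning per 2 µs step
(well below both the diffusion time and triplet dwell). Defaults — 25
molecules, 1000 photons/ms center brightness, 4 s — give ≈ 2×10⁵ photons,
amplitude ≈ 7, and a 0.25 ms diffusion time (D = 90 µm²/s), sized so a
trace simulates in seconds on one CPU; the generator warns below 10⁵
expected photons. Photons split evenly between donor and acceptor channels
(a doubly labeled species), so the two channels cross-correlate. Triplet
blinking is a per-molecule two-state telegraph with the stationary dark
fraction and mean dark dwell requested.

**Titrations.** θ from the exact isotherm plus Gaussian noise on θ
(default SD 0.03, matching per-point scatter of averaged single-molecule
readouts), mapped linearly onto readout endpoints: anisotropy 0.05 → 0.20,
FRET shift 0.50 → 0.75, diffusion time 0.35 → 0.60 ms — representative
magnitudes for a ~100 kDa dimer binding a 16 bp probe. With zero noise the
stored bound fractions are bitwise equal to the isotherm values.

All randomness in a scenario flows from one integer seed; every output
records it.

## Problem sizes used in validation

End-to-end efficiency recoveries use 4000–5000 simulated bursts (≈ 3000
survive filtering), which puts the Gaussian-mean standard error near 0.001
— comfortably inside the ±0.02 tolerance asserted. Titration fits use 12
points over 0.01–100 nM at 0.5 nM probe. FCS checks use 2.5–3 s traces
(≈ 1.2–1.5×10⁵ photons), where the fitted diffusion time scatters by
~5–15% about truth; tolerances are set at 20%. The isotherm closed form is
checked against an independent mass-action root-finder on 10⁴ random
parameter draws at 1e−10 absolute.

## Known limitations

- No IRF deconvolution; lifetime estimates are mean-microtime based and
  assume the offset is calibrated.
- Single-component diffusion and a single triplet term in FCS; no flow,
  no multi-species fits, no concentration calibration.
- The Gaussian chain is the only distance-distribution family.
- Gamma factors default to 1 and must be measured for real data; the
  package provides no gamma-calibration routine.
- The aggregate filter is insensitive on traces shorter than ~80 s (see
  above) and removes whole 2 s bins, costing that bin's signal.
- Vendor raw formats (.ptu/.ht3) are not read; conversion is upstream.
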