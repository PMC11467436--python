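# pulsefret

Single-molecule fluorescence analysis for freely diffusing, dual-labeled
biomolecules measured on a confocal instrument with pulsed interleaved
excitation (PIE): burst-wise Förster resonance energy transfer (smFRET),
donor-lifetime dynamics, burst anisotropy, fluorescence correlation
spectroscopy (FCS), and equilibrium DNA-binding titrations.

It was built to re-implement, as a tested and reusable pipeline, the kind of
analysis used to characterize the dimeric transcription factor MITF: the
proximity and microsecond dynamics of its C-terminal intrinsically disordered
regions (inter- and intramolecular smFRET with mean efficiencies near 0.66
and 0.30), and its affinity for M-box DNA (low-nanomolar dissociation
constants from anisotropy, FRET and FCS titrations fit with the exact 2:1
binding isotherm). Because the underlying photon data are not public, the
package ships first-class synthetic-data generators with exact ground truth,
so every stage is verifiable end to end.

## What it computes

**Burst pipeline.** From a time-tagged photon stream (macrotime, microtime,
detector), the pipeline removes aggregates (2 s bins above mean + 6 SD),
calls bursts by the delta-T criterion (all inter-photon gaps ≤ 100 µs,
30–1000 photons), counts photons per excitation gate and detection channel
(n_DD, n_DA, n_AA), and applies the correction chain — background, donor
leakage *l*, direct acceptor excitation α (default 0.042), detection
efficiency γ — to form the corrected transfer efficiency

    E = n′_A / (n′_A + n′_D)

PIE stoichiometry

    S = (n_DA + n_DD − δ·n_AA) / (n_DA + n_DD + γ_PIE·n_AA − δ·n_AA),
    δ = γ_PIE·α/(1 − α)

separates FRET pairs (S ≈ 0.5) from donor-only (S ≈ 1) and acceptor-only
(S ≈ 0) species. Photobleaching is filtered by the asymmetry confidence
|⟨t_A⟩ − ⟨t_D⟩| / σ with σ = T/(2√3)·√(1/N_D + 1/N_A), cut at 1.5.
Population means come from maximum-likelihood Gaussian mixtures on the
unbinned E values, optionally with one component pinned near E = 0 for the
residual donor-only population.

**Lifetime dynamics.** Per burst, the mean donor microtime normalized by the
donor-only lifetime is plotted against E. A fixed donor–acceptor distance
gives τ_DA/τ_D = 1 − E (static line); a rapidly fluctuating distance with
distribution P(r) gives τ_DA/τ_D = 1 − ⟨E⟩ + σ²/(1 − ⟨E⟩) (dynamic line),
with ⟨E⟩ and σ² integrated over a Gaussian-chain P(r) and
E(r) = 1/(1 + (r/R₀)⁶).

**FCS.** Donor–acceptor cross-correlation by a multi-tau estimator, fit with
the single-component 3D diffusion + triplet model
G(τ) = 1 + a(1 + n_T e^(−τ/τ_T)) / ((1 + τ/τ_D)·√(1 + τ/(s²τ_D))).

**Binding.** Titration readouts (anisotropy, FRET or diffusion-time shifts)
are normalized to bound fractions and fit with the exact quadratic 2:1
isotherm

    θ = (c_DNA + K_D + c_P − √((c_DNA + c_P + K_D)² − 4·c_DNA·c_P)) / (2·c_DNA)

valid when the probe concentration is comparable to K_D (the package
evaluates the cancellation-free algebraic form and flags fits too tight to
quantify, K_D < c_DNA/2).

## Worked example

Simulate 3000 bursts of a FRET species at ground-truth E = 0.66 with 20%
donor-only molecules, 5% donor leakage, α = 0.042 and 500 Hz background per
channel, then analyze the stream blind:

```sh
$ echo '{"n_bursts": 3000, "true_e": 0.66, "donor_only_fraction": 0.2}' > scen.json
$ pulsefret simulate bursts --config scen.json --seed 1 --out demo.h5
wrote 783832 photons to demo.h5 (seed 1)

$ printf 'leakage = 0.05\nbackground_dd_hz = 500\nbackground_da_hz = 500\nbackground_aa_hz = 500\n' > cfg.toml
$ pulsefret fret demo.h5 --config cfg.toml --out fret.json
population means: [0.6594] -> fret.json

$ pulsefret lifetime demo.h5 --config cfg.toml --out lifetime.json
tau_D(donor-only) = 3.484 ns -> lifetime.json
```

The FRET population mean (0.6594) recovers the ground truth 0.66 within the
shot-noise error of the fit; the donor-only lifetime estimate (3.484 ns)
recovers the simulated 3.5 ns. The lifetime summary reports a mean deviation
from the static line of −0.001 ± 0.136 (SD) over 1400 bursts — this is a
static-distance simulation, so the burst cloud sits on ρ = 1 − E; a
fast-exchange Gaussian-chain simulation instead sits on the dynamic line
(see `tests/test_lifetime.py`).

Titrations run the same way:

```sh
$ pulsefret simulate titration --kd 1.9 --seed 7 --out titr.csv
$ pulsefret bind titr.csv --c-dna 0.5 --out bind.json
K_D = 1.86 +/- 0.29 nM (2 SD)
```

The same workflows are available as library calls (`pulsefret.simulate_*`,
`pulsefret.analyze_stream`, `pulsefret.fit_populations`, `pulsefret.fit_kd`,
…); `pulsefret.recipes` bundles the standard simulate-then-recover loops.

## Layout

- `src/pulsefret/photons.py` — photon-stream data model, channel map, PIE gates
- `src/pulsefret/io.py` — Photon-HDF5-style HDF5 and gzipped columnar text I/O
- `src/pulsefret/config.py` — TOML analysis configuration with validated defaults
- `src/pulsefret/simulate.py` — burst-level and Brownian-trace generators, titrations
- `src/pulsefret/bursts.py` — aggregate removal, burst search, corrections, filters, mixture fits
- `src/pulsefret/lifetime.py` — Gaussian-chain model, static/dynamic lines, burst classification
- `src/pulsefret/fcs.py` — multi-tau correlator and diffusion+triplet fits
- `src/pulsefret/binding.py` — exact 2:1 isotherm and K_D fitting
- `src/pulsefret/cli.py` — `pulsefret` command-line front end
- `docs/methods.md` — models, conventions, parameter defaults and limitations
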