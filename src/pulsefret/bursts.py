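"""Photons to transfer-efficiency histograms: the burst analysis pipeline.

Stages, in order:

1. **Aggregate removal** — the trace is cut into 2 s bins; bins whose photon
   count exceeds the trace mean by more than 6 SD (statistics computed once,
   on the input) are dropped wholesale.  Slowly diffusing aggregates produce
   such bins; single molecules do not.
2. **Burst search** — the delta-T criterion: a burst is a maximal run of
   consecutive photons (all channels; PIE analysis needs the
   acceptor-excitation photons inside the same burst) whose inter-photon gaps
   are all <= dT (default 100 us).  Runs with fewer than 30 or more than 1000
   photons are discarded.
3. **Counting** — per burst, raw counts n_DD, n_DA, n_AA (excitation gate ->
   detection color) and polarization-resolved donor counts.
4. **Corrections** — background (rate x duration per class), donor leakage
   into the acceptor channel (n_DA -= l n_DD), direct acceptor excitation
   (n_DA -= alpha/(1-alpha) n_AA), and the detection-efficiency ratio gamma
   (n'_D = gamma n_DD).  The corrected transfer efficiency is
   E = n'_A / (n'_A + n'_D).
5. **Stoichiometry** — S = (n_DA + n_DD - delta n_AA) /
   (n_DA + n_DD + gamma_PIE n_AA - delta n_AA) with
   delta = gamma_PIE alpha / (1 - alpha).  FRET pairs sit near S = 0.5,
   donor-only molecules near 1, acceptor-only near 0.
6. **Asymmetry filtering** — photobleaching inside a burst makes the acceptor
   photons arrive systematically earlier or later than the donor photons.
   The confidence statistic is |mean arrival(A) - mean arrival(D)| / sigma
   with sigma = T/(2 sqrt(3)) sqrt(1/N_D + 1/N_A), the null SD of that
   difference for photons uniform over the burst; bursts with statistic
   > 1.5 are rejected.  Applied to donor-excitation D vs A emission and,
   separately, to acceptor-excitation acceptor vs donor-excitation donor
   emission.
7. **Population fitting** — maximum-likelihood Gaussian mixture (one or two
   components) on the unbinned per-burst E values, optionally with one
   component pinned near E = 0 for the residual donor-only population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .config import AnalysisConfig
from .photons import PHOTON_CLASSES, PhotonStream

__all__ = [
    "CorrectionSet",
    "remove_aggregates",
    "call_bursts",
    "build_burst_table",
    "correct_counts",
    "efficiency",
    "stoichiometry",
    "asymmetry_sigma",
    "burst_anisotropy",
    "select_fret_population",
    "PopulationFit",
    "fit_populations",
    "analyze_stream",
]


@dataclass(frozen=True)
class CorrectionSet:
    """Correction factors turning raw burst counts into corrected counts.

    Background rates are in Hz *within the corresponding excitation gate and
    detection color*.  ``delta`` is always derived from ``gamma_pie`` and
    ``alpha``, never stored independently.
    """

    background_dd_hz: float = 0.0
    background_da_hz: float = 0.0
    background_aa_hz: float = 0.0
    leakage: float = 0.0
    alpha: float = 0.042
    gamma: float = 1.0
    gamma_pie: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.alpha < 1):
            raise ValueError("alpha must lie in [0, 1)")
        if self.gamma <= 0 or self.gamma_pie <= 0:
            raise ValueError("gamma and gamma_pie must be positive")
        if self.leakage < 0:
            raise ValueError("leakage must be >= 0")

    @property
    def delta(self) -> float:
        """Stoichiometry direct-excitation factor: gamma_PIE alpha/(1-alpha)."""
        return self.gamma_pie * self.alpha / (1.0 - self.alpha)

    @property
    def delta_prime(self) -> float:
        """Count-correction direct-excitation factor: alpha/(1-alpha)."""
        return self.alpha / (1.0 - self.alpha)


# ---------------------------------------------------------------------------
# stage 1: aggregate removal
# ---------------------------------------------------------------------------

def remove_aggregates(
    stream: PhotonStream, bin_s: float = 2.0, k_sd: float = 6.0
) -> tuple[PhotonStream, dict]:
    """Drop all photons in time bins whose count exceeds mean + k SD.

    Bin statistics are computed once on the input (single pass); removing a
    bin does not trigger re-evaluation of the threshold.  Streams shorter
    than two bins are returned unchanged.
    """
    if stream.n_photons == 0:
        return stream, {"n_bins": 0, "bins_removed": 0, "photons_removed": 0}
    t = stream.times_s
    n_bins = int(np.floor(t[-1] / bin_s)) + 1
    if n_bins < 2:
        return stream, {"n_bins": n_bins, "bins_removed": 0, "photons_removed": 0}
    idx = np.minimum((t / bin_s).astype(np.int64), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    threshold = counts.mean() + k_sd * counts.std(ddof=0)
    bad_bins = np.nonzero(counts > threshold)[0]
    keep = ~np.isin(idx, bad_bins)
    cleaned = stream.select(keep)
    info = {
        "n_bins": n_bins,
        "threshold": float(threshold),
        "bins_removed": int(bad_bins.size),
        "photons_removed": int(stream.n_photons - cleaned.n_photons),
    }
    return cleaned, info


# ---------------------------------------------------------------------------
# stage 2: delta-T burst search
# ---------------------------------------------------------------------------

def call_bursts(
    stream: PhotonStream,
    dt_us: float = 100.0,
    min_photons: int = 30,
    max_photons: int = 1000,
) -> np.ndarray:
    """Delta-T burst search over all photons.

    Returns an (n_bursts, 2) integer array of [first, last] photon indices
    (inclusive).  A burst is a maximal run whose consecutive inter-photon
    gaps are all <= dT; runs outside [min_photons, max_photons] photons are
    discarded.  Bursts are non-overlapping and time-ordered by construction.
    """
    n = stream.n_photons
    if n == 0:
        return np.empty((0, 2), dtype=np.int64)
    gaps = np.diff(stream.times_s)
    breaks = np.nonzero(gaps > dt_us * 1e-6)[0]
    starts = np.concatenate(([0], breaks + 1))
    stops = np.concatenate((breaks, [n - 1]))
    sizes = stops - starts + 1
    ok = (sizes >= min_photons) & (sizes <= max_photons)
    return np.stack([starts[ok], stops[ok]], axis=1)


# ---------------------------------------------------------------------------
# stage 3+4: counting and corrections
# ---------------------------------------------------------------------------

def _reduceat_sums(values: np.ndarray, starts: np.ndarray, stops: np.ndarray):
    """Sum ``values`` over [start, stop] index ranges via a cumulative sum."""
    csum = np.concatenate(([0.0], np.cumsum(values, dtype=np.float64)))
    return csum[stops + 1] - csum[starts]


def correct_counts(n_dd, n_da, n_aa, duration_s, corrections: CorrectionSet):
    """Apply the correction chain to raw per-burst counts.

    Order: (1) background, rate x duration per class; (2) leakage,
    n_DA -= l n_DD; (3) direct excitation, n_DA -= alpha/(1-alpha) n_AA;
    (4) detection efficiency, n'_D = gamma n_DD.  Negative intermediate
    counts are floored at zero and flagged.

    Returns ``(n_d_corr, n_a_corr, n_aa_corr, flagged)``.
    """
    n_dd = np.asarray(n_dd, dtype=float)
    n_da = np.asarray(n_da, dtype=float)
    n_aa = np.asarray(n_aa, dtype=float)
    duration_s = np.asarray(duration_s, dtype=float)
    c = corrections
    dd = n_dd - c.background_dd_hz * duration_s
    da = n_da - c.background_da_hz * duration_s
    aa = n_aa - c.background_aa_hz * duration_s
    flagged = (dd < 0) | (da < 0) | (aa < 0)
    dd, da, aa = np.maximum(dd, 0.0), np.maximum(da, 0.0), np.maximum(aa, 0.0)
    da = da - c.leakage * dd
    da = da - c.delta_prime * aa
    flagged |= da < 0
    da = np.maximum(da, 0.0)
    return c.gamma * dd, da, aa, flagged


def efficiency(n_d_corr, n_a_corr):
    """Corrected transfer efficiency E = n'_A / (n'_A + n'_D).

    Zero-denominator entries return NaN (callers flag and exclude them).
    """
    n_d = np.asarray(n_d_corr, dtype=float)
    n_a = np.asarray(n_a_corr, dtype=float)
    denom = n_a + n_d
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(denom > 0, n_a / denom, np.nan)
    return float(e) if e.ndim == 0 else e


def stoichiometry(
    n_dd, n_da, n_aa,
    gamma_pie: float = 1.0,
    alpha: float = 0.042,
    delta_on_naa: bool = True,
):
    """PIE stoichiometry.

    S = (n_DA + n_DD - delta n_AA) / (n_DA + n_DD + gamma_PIE n_AA - delta x)
    with delta = gamma_PIE alpha / (1 - alpha).  The delta term in the
    denominator multiplies n_AA by default (``delta_on_naa=True``, the
    symmetric reading); set False to multiply n_DA instead.
    """
    n_dd = np.asarray(n_dd, dtype=float)
    n_da = np.asarray(n_da, dtype=float)
    n_aa = np.asarray(n_aa, dtype=float)
    delta = gamma_pie * alpha / (1.0 - alpha)
    num = n_da + n_dd - delta * n_aa
    denom = n_da + n_dd + gamma_pie * n_aa - delta * (n_aa if delta_on_naa else n_da)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(denom != 0, num / denom, np.nan)
    return float(s) if s.ndim == 0 else s


def asymmetry_sigma(duration, n_d, n_a):
    """Null SD of the arrival-time difference: T/(2 sqrt(3)) sqrt(1/N_D + 1/N_A).

    For N photons uniform over a burst of length T, the mean arrival time has
    variance T^2/(12 N); the difference of two independent such means has SD
    equal to this expression.  Units follow ``duration``.
    """
    duration = np.asarray(duration, dtype=float)
    n_d = np.asarray(n_d, dtype=float)
    n_a = np.asarray(n_a, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        sig = duration / (2.0 * np.sqrt(3.0)) * np.sqrt(1.0 / n_d + 1.0 / n_a)
    return float(sig) if sig.ndim == 0 else sig


def burst_anisotropy(i_par, i_perp, g_factor: float = 1.0):
    """Steady-state anisotropy r = (I_par - g I_perp) / (I_par + 2 g I_perp)."""
    i_par = np.asarray(i_par, dtype=float)
    i_perp = np.asarray(i_perp, dtype=float)
    denom = i_par + 2.0 * g_factor * i_perp
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, (i_par - g_factor * i_perp) / denom, np.nan)
    return float(r) if r.ndim == 0 else r


def build_burst_table(
    stream: PhotonStream,
    bursts: np.ndarray,
    corrections: CorrectionSet,
    g_factor: float = 1.0,
    asymmetry_threshold: float = 1.5,
    delta_on_naa: bool = True,
) -> pd.DataFrame:
    """Count, correct and characterize every called burst (vectorized).

    One row per burst with raw and corrected counts, duration, E, S, both
    asymmetry statistics with pass flags, donor anisotropy, and the mean
    donor microtime used by the lifetime analysis.
    """
    cols = [
        "i_first", "i_last", "t_start_s", "duration_us", "n_photons",
        "n_dd", "n_da", "n_aa", "i_par", "i_perp",
        "n_d_corr", "n_a_corr", "n_aa_corr", "E", "S",
        "asym_dex", "asym_pie", "asym_dex_pass", "asym_pie_pass",
        "asym_vacuous", "r_anisotropy", "mean_t_dd_ns",
        "corr_flagged", "e_valid",
    ]
    if bursts.shape[0] == 0:
        return pd.DataFrame(columns=cols)
    starts, stops = bursts[:, 0], bursts[:, 1]
    t = stream.times_s
    cls = stream.photon_classes()
    nanot_ns = stream.nanotimes_ns
    det = stream.detectors
    cmap = stream.channel_map

    is_dd = (cls == PHOTON_CLASSES["DD"]).astype(np.float64)
    is_da = (cls == PHOTON_CLASSES["DA"]).astype(np.float64)
    is_aa = (cls == PHOTON_CLASSES["AA"]).astype(np.float64)
    is_par = is_dd * (det == cmap.donor_parallel)
    is_perp = is_dd * (det == cmap.donor_perpendicular)

    n_dd = _reduceat_sums(is_dd, starts, stops)
    n_da = _reduceat_sums(is_da, starts, stops)
    n_aa = _reduceat_sums(is_aa, starts, stops)
    i_par = _reduceat_sums(is_par, starts, stops)
    i_perp = _reduceat_sums(is_perp, starts, stops)
    sum_t_dd = _reduceat_sums(t * is_dd, starts, stops)
    sum_t_da = _reduceat_sums(t * is_da, starts, stops)
    sum_t_aa = _reduceat_sums(t * is_aa, starts, stops)
    sum_nt_dd = _reduceat_sums(nanot_ns * is_dd, starts, stops)

    t_start = t[starts]
    duration_s = t[stops] - t[starts]
    n_phot = stops - starts + 1

    with np.errstate(divide="ignore", invalid="ignore"):
        mean_t_dd = np.where(n_dd > 0, sum_t_dd / n_dd - t_start, np.nan)
        mean_t_da = np.where(n_da > 0, sum_t_da / n_da - t_start, np.nan)
        mean_t_aa = np.where(n_aa > 0, sum_t_aa / n_aa - t_start, np.nan)
        mean_nt_dd = np.where(n_dd > 0, sum_nt_dd / n_dd, np.nan)

    n_d_corr, n_a_corr, n_aa_corr, flagged = correct_counts(
        n_dd, n_da, n_aa, duration_s, corrections
    )
    e = efficiency(n_d_corr, n_a_corr)
    s = stoichiometry(
        n_dd - corrections.background_dd_hz * duration_s,
        n_da - corrections.background_da_hz * duration_s,
        n_aa - corrections.background_aa_hz * duration_s,
        gamma_pie=corrections.gamma_pie,
        alpha=corrections.alpha,
        delta_on_naa=delta_on_naa,
    )

    # asymmetry: donor-excitation A vs D arrival, and Aex-A vs Dex-D arrival
    sig_dex = asymmetry_sigma(duration_s, n_dd, n_da)
    sig_pie = asymmetry_sigma(duration_s, n_dd, n_aa)
    with np.errstate(invalid="ignore", divide="ignore"):
        asym_dex = np.abs(mean_t_da - mean_t_dd) / sig_dex
        asym_pie = np.abs(mean_t_aa - mean_t_dd) / sig_pie
    vac_dex = (n_dd == 0) | (n_da == 0)
    vac_pie = (n_dd == 0) | (n_aa == 0)
    # vacuous bursts pass (no statistic computable) but are flagged
    pass_dex = np.where(vac_dex, True, asym_dex <= asymmetry_threshold)
    pass_pie = np.where(vac_pie, True, asym_pie <= asymmetry_threshold)

    return pd.DataFrame({
        "i_first": starts,
        "i_last": stops,
        "t_start_s": t_start,
        "duration_us": duration_s * 1e6,
        "n_photons": n_phot,
        "n_dd": n_dd,
        "n_da": n_da,
        "n_aa": n_aa,
        "i_par": i_par,
        "i_perp": i_perp,
        "n_d_corr": n_d_corr,
        "n_a_corr": n_a_corr,
        "n_aa_corr": n_aa_corr,
        "E": e,
        "S": s,
        "asym_dex": asym_dex,
        "asym_pie": asym_pie,
        "asym_dex_pass": pass_dex.astype(bool),
        "asym_pie_pass": pass_pie.astype(bool),
        "asym_vacuous": (vac_dex | vac_pie),
        "r_anisotropy": burst_anisotropy(i_par, i_perp, g_factor),
        "mean_t_dd_ns": mean_nt_dd,
        "corr_flagged": flagged,
        "e_valid": np.isfinite(e),
    })


def select_fret_population(
    table: pd.DataFrame, s_window: tuple[float, float] = (0.3, 0.7)
) -> np.ndarray:
    """Boolean mask: stoichiometric FRET pairs passing both asymmetry tests."""
    lo, hi = s_window
    mask = (
        (table["S"] >= lo) & (table["S"] <= hi)
        & table["asym_dex_pass"] & table["asym_pie_pass"]
        & table["e_valid"]
    ).to_numpy()
    return mask


# ---------------------------------------------------------------------------
# stage 7: Gaussian population fitting
# ---------------------------------------------------------------------------

@dataclass
class PopulationFit:
    """Gaussian mixture fitted to per-burst transfer efficiencies."""

    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    mean_errors_2sd: np.ndarray    # 2 SD of fit error on each component mean
    n_values: int
    converged: bool
    donor_only_component: int | None = None   # index of the pinned component
    log_likelihood: float = float("nan")

    @property
    def fret_mean(self) -> float:
        """Mean of the (non-pinned) FRET component."""
        if self.donor_only_component is None:
            return float(self.means[np.argmax(self.means)])
        idx = [i for i in range(len(self.means)) if i != self.donor_only_component]
        return float(self.means[idx[0]])

    def to_dict(self) -> dict:
        return {
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "weights": self.weights.tolist(),
            "mean_errors_2sd": self.mean_errors_2sd.tolist(),
            "n_values": self.n_values,
            "converged": self.converged,
            "donor_only_component": self.donor_only_component,
        }


def _mixture_nll(params, x, n_comp, pin):
    if n_comp == 1:
        mu, log_sd = params
        return -np.sum(stats.norm.logpdf(x, mu, np.exp(log_sd)))
    mu0, mu1, log_s0, log_s1, w_logit = params
    w0 = 1.0 / (1.0 + np.exp(-w_logit))
    p = (
        w0 * stats.norm.pdf(x, mu0, np.exp(log_s0))
        + (1.0 - w0) * stats.norm.pdf(x, mu1, np.exp(log_s1))
    )
    return -np.sum(np.log(np.maximum(p, 1e-300)))


def _numerical_hessian(f, x0, eps=1e-4):
    n = len(x0)
    h = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = eps
            ej = np.zeros(n); ej[j] = eps
            fpp = f(x0 + ei + ej)
            fpm = f(x0 + ei - ej)
            fmp = f(x0 - ei + ej)
            fmm = f(x0 - ei - ej)
            h[i, j] = h[j, i] = (fpp - fpm - fmp + fmm) / (4 * eps * eps)
    return h


def fit_populations(
    e_values: np.ndarray,
    n_components: int = 1,
    pin_donor_only: bool = False,
    sd_floor: float = 0.025,
    min_values: int = 100,
    rng: np.random.Generator | None = None,
) -> PopulationFit:
    """Maximum-likelihood Gaussian mixture on unbinned per-burst E values.

    With ``pin_donor_only`` (requires two components) the first component's
    mean is constrained to [-0.05, 0.05], absorbing the residual donor-only
    population near zero efficiency.  Component SDs are floored at
    ``sd_floor`` (the histogram bin width) so degenerate samples cannot
    collapse the likelihood.  Reported mean errors are 2 SD from the inverse
    observed information at the optimum.
    """
    x = np.asarray(e_values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < min_values:
        raise ValueError(
            f"only {x.size} efficiency values; need >= {min_values} for a "
            "stable population fit"
        )
    if n_components not in (1, 2):
        raise ValueError("n_components must be 1 or 2")
    if pin_donor_only and n_components != 2:
        raise ValueError("pin_donor_only requires n_components=2")
    rng = rng or np.random.default_rng(0)
    log_floor = np.log(sd_floor)

    if n_components == 1:
        sd0 = max(float(x.std(ddof=1)), sd_floor)
        res = optimize.minimize(
            _mixture_nll, x0=[float(x.mean()), np.log(sd0)],
            args=(x, 1, False), method="L-BFGS-B",
            bounds=[(-0.5, 1.5), (log_floor, np.log(0.5))],
        )
        mu, log_sd = res.x
        hess = _numerical_hessian(lambda p: _mixture_nll(p, x, 1, False), res.x)
        try:
            cov = np.linalg.inv(hess)
            err = 2.0 * np.sqrt(max(cov[0, 0], 0.0))
        except np.linalg.LinAlgError:
            err = 2.0 * float(x.std(ddof=1)) / np.sqrt(x.size)
        return PopulationFit(
            means=np.array([mu]), sds=np.array([np.exp(log_sd)]),
            weights=np.array([1.0]), mean_errors_2sd=np.array([err]),
            n_values=x.size, converged=bool(res.success),
            log_likelihood=-float(res.fun),
        )

    # two components
    high = x[x > 0.15]
    mu1_init = float(np.median(high)) if high.size >= 10 else float(np.median(x))
    mu0_init = 0.0
    w0_init = float(np.clip(np.mean(x <= 0.15), 0.05, 0.95))
    mu0_bounds = (-0.05, 0.05) if pin_donor_only else (-0.5, 1.5)
    best = None
    for jitter in (0.0, 0.05, -0.05):
        res = optimize.minimize(
            _mixture_nll,
            x0=[mu0_init, np.clip(mu1_init + jitter, 0.0, 1.2),
                np.log(0.05), np.log(0.08),
                np.log(w0_init / (1 - w0_init))],
            args=(x, 2, pin_donor_only), method="L-BFGS-B",
            bounds=[mu0_bounds, (-0.5, 1.5), (log_floor, np.log(0.5)),
                    (log_floor, np.log(0.5)), (-6.0, 6.0)],
        )
        if best is None or res.fun < best.fun:
            best = res
    res = best
    mu0, mu1, log_s0, log_s1, w_logit = res.x
    w0 = 1.0 / (1.0 + np.exp(-w_logit))
    hess = _numerical_hessian(
        lambda p: _mixture_nll(p, x, 2, pin_donor_only), res.x
    )
    errs = np.full(2, np.nan)
    try:
        cov = np.linalg.inv(hess)
        errs = 2.0 * np.sqrt(np.maximum(np.diag(cov)[:2], 0.0))
    except np.linalg.LinAlgError:
        pass
    if not bool(res.success):
        raise RuntimeError(f"population fit did not converge: {res.message}")
    return PopulationFit(
        means=np.array([mu0, mu1]),
        sds=np.exp([log_s0, log_s1]),
        weights=np.array([w0, 1.0 - w0]),
        mean_errors_2sd=errs,
        n_values=x.size,
        converged=True,
        donor_only_component=0 if pin_donor_only else None,
        log_likelihood=-float(res.fun),
    )


# ---------------------------------------------------------------------------
# convenience: full pipeline
# ---------------------------------------------------------------------------

def analyze_stream(
    stream: PhotonStream, config: AnalysisConfig | None = None
) -> tuple[pd.DataFrame, dict]:
    """Run aggregate removal, burst search and burst characterization.

    Returns the burst table and an info dict (aggregate-removal statistics,
    burst counts).  Deterministic given stream + config.
    """
    config = config or AnalysisConfig()
    cleaned, agg_info = remove_aggregates(
        stream, config.aggregate_bin_s, config.aggregate_k_sd
    )
    bursts = call_bursts(
        cleaned, config.burst_dt_us, config.min_photons, config.max_photons
    )
    table = build_burst_table(
        cleaned, bursts, config.corrections(),
        g_factor=config.g_factor,
        asymmetry_threshold=config.asymmetry_threshold,
        delta_on_naa=config.stoich_delta_on_naa,
    )
    info = {"aggregate_removal": agg_info, "n_bursts": int(len(table))}
    return table, info
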