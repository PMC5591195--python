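"""Kinetic analyses of decoded single-molecule traces.

Covers the standard two-state toolbox: signal-to-noise metrics,
intensity autocorrelation with a telegraph-model fit (photoblinking),
threshold-based dwell-time extraction with exponential lifetime estimation
(binding/unbinding), FRET efficiency with background and leakage
correction, and Gaussian-emission hidden-Markov state inference with
transition-rate estimation (conformational dynamics).

Conventions
-----------
For a bright/dark telegraph process with rates ``k_on`` (dark->bright) and
``k_off`` (bright->dark), the mean-subtracted intensity autocorrelation
normalized by the squared mean intensity is

    G(t) = (k_off / k_on) * exp(-(k_on + k_off) * t)

so both rates are identifiable from one curve: the amplitude gives the
rate ratio and the decay their sum.  The off-time is 1/k_on and the
on-time 1/k_off.

Decoded dwell durations are integer multiples of the substep, so the
exponential lifetime MLE is implemented on the run-length (geometric)
scale for binned data; for exponential dwells under per-bin threshold
detection the run-length tail is exactly geometric with ratio
exp(-substep/tau) from two substeps on, which makes the left-truncated
estimator unbiased even with partially occupied edge bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .errors import InvalidArgumentError, InsufficientDataError, FitFailureError
from .decode import SpotTrace


# --------------------------------------------------------------------------
# SNR
# --------------------------------------------------------------------------

@dataclass
class SnrResult:
    """Background- and signal-referenced signal-to-noise ratios.

    ``snr_b = (I_S - I_B)/sigma_B`` and ``snr_s = (I_S - I_B)/sigma_S``
    where I_S/sigma_S are the mean/SD over ON samples and I_B/sigma_B over
    OFF samples.
    """

    snr_b: float
    snr_s: float
    i_s: float
    i_b: float
    sigma_s: float
    sigma_b: float


def compute_snr(trace: SpotTrace | np.ndarray, on_mask: np.ndarray) -> SnrResult:
    """SNR metrics from a trace and a per-sample ON/OFF labelling."""
    values = trace.values if isinstance(trace, SpotTrace) else np.asarray(trace, float)
    on_mask = np.asarray(on_mask, bool)
    if on_mask.shape != values.shape:
        raise InvalidArgumentError("on_mask must match the trace length")
    if on_mask.sum() < 2 or (~on_mask).sum() < 2:
        raise InsufficientDataError("need at least 2 ON and 2 OFF samples")
    i_s, sigma_s = float(values[on_mask].mean()), float(values[on_mask].std(ddof=1))
    i_b, sigma_b = float(values[~on_mask].mean()), float(values[~on_mask].std(ddof=1))
    return SnrResult(snr_b=(i_s - i_b) / sigma_b, snr_s=(i_s - i_b) / sigma_s,
                     i_s=i_s, i_b=i_b, sigma_s=sigma_s, sigma_b=sigma_b)


# --------------------------------------------------------------------------
# autocorrelation
# --------------------------------------------------------------------------

def autocorrelation(trace: np.ndarray, max_lag: int,
                    normalization: str = "variance") -> np.ndarray:
    """Mean-subtracted autocorrelation of a trace at lags 0..max_lag.

    ``normalization="variance"`` divides by the lag-0 autocovariance so the
    result starts at 1; ``normalization="mean"`` divides by the squared
    trace mean, the scale on which the telegraph model amplitude equals
    k_off/k_on.  Computed by FFT; all n - k products at lag k are averaged
    with denominator n (the standard biased estimator).
    """
    x = np.asarray(trace, dtype=float)
    if x.ndim != 1 or x.size <= 2 * max_lag:
        raise InvalidArgumentError("trace length must exceed 2 * max_lag")
    x = x - x.mean()
    var = float(np.mean(x * x))
    if var == 0:
        raise InsufficientDataError("zero-variance trace has no autocorrelation")
    n = x.size
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[: max_lag + 1] / n
    if normalization == "variance":
        return acov / var
    if normalization == "mean":
        mean = float(np.asarray(trace, float).mean())
        if mean == 0:
            raise InsufficientDataError("zero-mean trace cannot be mean-normalized")
        return acov / mean ** 2
    raise InvalidArgumentError(f"unknown normalization {normalization!r}")


@dataclass
class AcfFit:
    """Two-state telegraph fit of a blinking autocorrelation curve."""

    k_on: float               # dark->bright rate, s^-1
    k_off: float              # bright->dark rate, s^-1
    amplitude: float          # fitted k_off/k_on (after binning correction)
    lags_ms: np.ndarray
    acf_values: np.ndarray
    covariance: np.ndarray = field(default_factory=lambda: np.full((2, 2), np.nan))

    @property
    def off_time_ms(self) -> float:
        return 1000.0 / self.k_on

    @property
    def on_time_ms(self) -> float:
        return 1000.0 / self.k_off

    @property
    def decay_rate_s(self) -> float:
        return self.k_on + self.k_off


def _binning_amplitude_factor(decay_s: float, substep_ms: float) -> float:
    """Amplitude factor (sinh(x/2)/(x/2))^2 from boxcar averaging over a substep."""
    x = decay_s * substep_ms / 1000.0
    if x == 0:
        return 1.0
    return float((np.sinh(x / 2.0) / (x / 2.0)) ** 2)


def fit_blinking_acf(acf: np.ndarray, lags_ms: np.ndarray,
                     substep_ms: float | None = None) -> AcfFit:
    """Fit (k_off/k_on) exp(-(k_on + k_off) t) to a blinking ACF.

    ``acf`` must be normalized by the squared mean (see
    :func:`autocorrelation`); the lag-0 point, if present, is excluded from
    the fit because shot noise contributes only there.  With ``substep_ms``
    given, the fitted amplitude is corrected for boxcar averaging over one
    substep before converting (amplitude, decay) into the two rates.
    """
    acf = np.asarray(acf, float)
    lags_ms = np.asarray(lags_ms, float)
    if acf.shape != lags_ms.shape:
        raise InvalidArgumentError("acf and lags_ms must have the same shape")
    pos = lags_ms > 0
    if pos.sum() < 5:
        raise InvalidArgumentError("need at least 5 positive-lag points")
    t = lags_ms[pos] / 1000.0  # seconds
    y = acf[pos]

    def model(t, amp, decay):
        return amp * np.exp(-decay * t)

    a0 = max(float(y[0]), 1e-3)
    d0 = 1.0 / max(float(t[-1]) / 3.0, 1e-6)
    try:
        popt, pcov = curve_fit(model, t, y, p0=[a0, d0],
                               bounds=([1e-12, 1e-9], [np.inf, np.inf]), maxfev=10000)
    except (RuntimeError, ValueError) as exc:
        raise FitFailureError(f"ACF fit did not converge: {exc}") from exc
    amp, decay = float(popt[0]), float(popt[1])
    if substep_ms is not None:
        amp /= _binning_amplitude_factor(decay, substep_ms)
    k_on = decay / (1.0 + amp)
    k_off = decay - k_on
    return AcfFit(k_on=k_on, k_off=k_off, amplitude=amp,
                  lags_ms=lags_ms, acf_values=acf, covariance=pcov)


# --------------------------------------------------------------------------
# threshold dwell analysis
# --------------------------------------------------------------------------

@dataclass
class DwellRecord:
    """One ON or OFF interval of a decoded trace."""

    state: str                 # "ON" | "OFF"
    start_ms: float
    duration_ms: float
    molecule_id: int = 0
    censored: bool = False     # touches the start or end of the trace


def detect_dwells_threshold(trace: SpotTrace, threshold_sigma: float = 3.0,
                            molecule_id: int = 0) -> list[DwellRecord]:
    """Threshold a trace at I_B + threshold_sigma * sigma_B into dwells.

    A sample is ON when it exceeds the threshold; runs of equal state become
    DwellRecords of duration = run length x substep.  Runs touching either
    trace boundary are flagged censored (their true duration is unknown).
    Note ``trace.values`` are background-subtracted, so the effective
    threshold on them is ``threshold_sigma * sigma_B``.
    """
    if not np.isfinite(trace.sigma_b) or trace.sigma_b <= 0:
        raise InvalidArgumentError("trace.sigma_b must be positive")
    on = trace.values > threshold_sigma * trace.sigma_b
    edges = np.flatnonzero(np.diff(on.astype(np.int8))) + 1
    bounds = np.concatenate(([0], edges, [on.size]))
    records = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        records.append(DwellRecord(
            state="ON" if on[a] else "OFF",
            start_ms=a * trace.substep_ms,
            duration_ms=(b - a) * trace.substep_ms,
            molecule_id=molecule_id,
            censored=(a == 0 or b == on.size)))
    return records


@dataclass
class DwellFit:
    """Exponential lifetime estimate from a set of dwells."""

    tau_ms: float
    se_ms: float
    n_dwells: int
    state: str
    truncated_at_ms: float


def _geometric_tau(k: np.ndarray, bin_ms: float, k_min: int) -> float:
    """MLE of the exponential mean from run lengths (in bins) >= k_min.

    For a geometric tail P(k) ~ rho^k, E[k | k >= k_min] = k_min +
    rho/(1-rho), so rho = (m - k_min)/(m - k_min + 1) with m the sample
    mean, and tau = -bin / ln(rho).
    """
    m = float(k.mean())
    rho = (m - k_min) / (m - k_min + 1.0)
    if not 0.0 < rho < 1.0:
        raise InsufficientDataError("degenerate run-length distribution")
    return -bin_ms / np.log(rho)


def fit_dwell_histogram(dwells: list[DwellRecord], state: str,
                        min_dwells: int = 50, bin_ms: float | None = None,
                        interval_ms: float | None = None,
                        n_bootstrap: int = 200,
                        seed: int = 0) -> DwellFit:
    """Maximum-likelihood exponential mean of uncensored dwells of one state.

    Censored dwells are excluded.  When ``bin_ms`` is given (the substep
    duration of threshold-decoded traces) the estimator operates on run
    lengths and is left-truncated at 2 bins, which removes the edge-bin
    bias of threshold detection; otherwise the plain continuous MLE (the
    sample mean) is used.  The standard error comes from a bootstrap over
    dwells.

    ``interval_ms`` is the real time one bin advance represents and defaults
    to ``bin_ms``; for decoded swept traces pass the config's
    ``sample_interval_ms`` ((exposure + lag)/N), since the inter-frame dead
    time stretches runs that cross a frame boundary.
    """
    d = np.array([r.duration_ms for r in dwells
                  if r.state == state and not r.censored], dtype=float)
    if d.size < min_dwells:
        raise InsufficientDataError(
            f"only {d.size} uncensored {state} dwells; need >= {min_dwells}")
    rng = np.random.default_rng(seed)

    if bin_ms is not None:
        dt = bin_ms if interval_ms is None else interval_ms
        k_all = np.round(d / bin_ms).astype(int)
        k_min = 2
        k = k_all[k_all >= k_min]
        if k.size < min_dwells:
            raise InsufficientDataError(
                f"only {k.size} dwells of >= {k_min} substeps; need >= {min_dwells}")
        tau = _geometric_tau(k, dt, k_min)
        boot = []
        for _ in range(n_bootstrap):
            try:
                boot.append(_geometric_tau(rng.choice(k, size=k.size), dt, k_min))
            except InsufficientDataError:
                continue
        se = float(np.std(boot, ddof=1)) if len(boot) > 1 else float("nan")
        return DwellFit(tau_ms=float(tau), se_ms=se, n_dwells=int(k.size),
                        state=state, truncated_at_ms=k_min * bin_ms)

    tau = float(d.mean())
    boot = [float(rng.choice(d, size=d.size).mean()) for _ in range(n_bootstrap)]
    se = float(np.std(boot, ddof=1))
    return DwellFit(tau_ms=tau, se_ms=se, n_dwells=int(d.size), state=state,
                    truncated_at_ms=0.0)


# --------------------------------------------------------------------------
# FRET
# --------------------------------------------------------------------------

def fret_efficiency(i_d: np.ndarray, i_a: np.ndarray, leakage: float = 0.0,
                    background_d: float = 0.0, background_a: float = 0.0
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Proximity-ratio FRET efficiency with background and leakage correction.

    E = I_A' / (I_D' + I_A') with I_D' = i_d - background_d and
    I_A' = i_a - background_a - leakage * I_D'.  E is clamped to [0, 1];
    samples with non-positive total intensity are flagged invalid and
    should be excluded downstream.  Returns (efficiency, valid_mask).
    """
    i_d = np.asarray(i_d, float)
    i_a = np.asarray(i_a, float)
    if i_d.shape != i_a.shape:
        raise InvalidArgumentError("donor and acceptor arrays must have equal length")
    d = i_d - background_d
    a = i_a - background_a - leakage * d
    total = d + a
    valid = total > 0
    eff = np.full(i_d.shape, np.nan)
    eff[valid] = np.clip(a[valid] / total[valid], 0.0, 1.0)
    return eff, valid


def block_average(values: np.ndarray, block: int) -> np.ndarray:
    """Average consecutive blocks of ``block`` samples (trailing remainder dropped).

    Used to emulate conventional frame-rate data from substep-resolution
    traces (e.g. 4 x 5 ms -> 20 ms).
    """
    if block < 1:
        raise InvalidArgumentError("block must be >= 1")
    v = np.asarray(values, float)
    n = (v.size // block) * block
    return v[:n].reshape(-1, block).mean(axis=1)


def fret_histogram(efficiencies: np.ndarray, n_bins: int = 30,
                   range_: tuple[float, float] = (0.0, 1.0)
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Normalized FRET-efficiency histogram (density, bin_edges)."""
    e = np.asarray(efficiencies, float)
    e = e[np.isfinite(e)]
    if e.size < 100:
        raise InsufficientDataError(f"need >= 100 samples, got {e.size}")
    density, edges = np.histogram(e, bins=n_bins, range=range_, density=True)
    return density, edges


def histogram_is_bimodal(density: np.ndarray, valley_fraction: float = 0.6) -> bool:
    """Two-mode test: a valley below ``valley_fraction`` of the smaller peak.

    Finds the two highest local maxima; returns True when the minimum
    density between them is below ``valley_fraction`` times the smaller of
    the two peaks.
    """
    d = np.asarray(density, float)
    peaks = [i for i in range(1, d.size - 1)
             if d[i] >= d[i - 1] and d[i] >= d[i + 1] and d[i] > 0]
    if d[0] > d[1]:
        peaks.insert(0, 0)
    if d[-1] > d[-2]:
        peaks.append(d.size - 1)
    if len(peaks) < 2:
        return False
    peaks.sort(key=lambda i: d[i], reverse=True)
    i, j = sorted(peaks[:2])
    if j - i < 2:
        return False
    valley = d[i + 1: j].min()
    return valley < valley_fraction * min(d[i], d[j])


# --------------------------------------------------------------------------
# two-state HMM
# --------------------------------------------------------------------------

@dataclass
class HmmResult:
    """Two-state (or one-state) Gaussian HMM fit of a FRET trace."""

    state_path: np.ndarray     # 0 = low-E state, 1 = high-E state
    n_states: int
    means: np.ndarray
    k_12: float                # low -> high rate, s^-1 (nan for 1 state)
    k_21: float                # high -> low rate, s^-1
    k_12_transmat: float       # same rates from the transition matrix
    k_21_transmat: float
    bic: dict

    @property
    def combined_rate_s(self) -> float:
        return self.k_12 + self.k_21


def _path_dwell_rates(path: np.ndarray, substep_ms: float) -> tuple[float, float]:
    """Exit rates (s^-1) of states 0 and 1 from mean uncensored dwell lengths."""
    edges = np.flatnonzero(np.diff(path)) + 1
    bounds = np.concatenate(([0], edges, [path.size]))
    dwell = {0: [], 1: []}
    for i, (a, b) in enumerate(zip(bounds[:-1], bounds[1:])):
        if a == 0 or b == path.size:  # censored
            continue
        dwell[int(path[a])].append(b - a)
    rates = []
    for s in (0, 1):
        if dwell[s]:
            rates.append(1000.0 / (float(np.mean(dwell[s])) * substep_ms))
        else:
            rates.append(float("nan"))
    return rates[0], rates[1]


def fit_two_state_hmm(efficiency: np.ndarray, substep_ms: float,
                      seed: int = 0, n_iter: int = 200) -> HmmResult:
    """Select 1 vs 2 Gaussian-emission HMM states by BIC and estimate rates.

    Fits maximum-likelihood HMMs (Baum-Welch) with 1 and 2 states to the
    per-substep efficiency trace, picks the model with the lower BIC, and
    returns the Viterbi path with states ordered by emission mean (state 0
    = low E).  Rates come from mean uncensored Viterbi dwell lengths
    (``k_12``/``k_21``) and, alternatively, from the transition matrix as
    -ln(1 - p_switch)/substep.  A zero-variance trace yields a single-state
    result.
    """
    from hmmlearn.hmm import GaussianHMM

    e = np.asarray(efficiency, float)
    e = e[np.isfinite(e)]
    if e.size < 50:
        raise InsufficientDataError(f"trace too short for HMM ({e.size} samples)")
    X = e.reshape(-1, 1)
    if float(e.std()) == 0.0:
        return HmmResult(state_path=np.zeros(e.size, dtype=int), n_states=1,
                         means=np.array([e.mean()]), k_12=float("nan"),
                         k_21=float("nan"), k_12_transmat=float("nan"),
                         k_21_transmat=float("nan"), bic={})

    bic = {}
    models = {}
    for k in (1, 2):
        best = None
        for trial in range(3 if k == 2 else 1):
            m = GaussianHMM(n_components=k, covariance_type="diag",
                            n_iter=n_iter, random_state=seed + trial,
                            min_covar=1e-6)
            try:
                m.fit(X)
                ll = float(m.score(X))
            except (ValueError, np.linalg.LinAlgError):
                continue
            if best is None or ll > best[0]:
                best = (ll, m)
        if best is None:
            continue
        ll, m = best
        n_params = (k - 1) + k * (k - 1) + 2 * k  # startprob + transmat + means + vars
        bic[k] = -2.0 * ll + n_params * np.log(e.size)
        models[k] = m
    if not models:
        raise FitFailureError("HMM fits failed for all state counts")
    k_sel = min(bic, key=bic.get)
    m = models[k_sel]

    if k_sel == 1:
        return HmmResult(state_path=np.zeros(e.size, dtype=int), n_states=1,
                         means=m.means_.ravel(), k_12=float("nan"),
                         k_21=float("nan"), k_12_transmat=float("nan"),
                         k_21_transmat=float("nan"), bic=bic)

    path = m.predict(X)
    order = np.argsort(m.means_.ravel())
    relabel = np.empty(2, dtype=int)
    relabel[order] = np.arange(2)
    path = relabel[path]
    means = m.means_.ravel()[order]
    trans = m.transmat_[np.ix_(order, order)]
    dt_s = substep_ms / 1000.0
    with np.errstate(divide="ignore"):
        k12_tm = float(-np.log(max(1.0 - trans[0, 1], 1e-300)) / dt_s)
        k21_tm = float(-np.log(max(1.0 - trans[1, 0], 1e-300)) / dt_s)
    k12, k21 = _path_dwell_rates(path, substep_ms)
    return HmmResult(state_path=path, n_states=2, means=means,
                     k_12=k12, k_21=k21, k_12_transmat=k12_tm,
                     k_21_transmat=k21_tm, bic=bic)


def pooled_transition_rates(paths: list[np.ndarray], substep_ms: float,
                            method: str = "propagator") -> tuple[float, float]:
    """Pool Viterbi paths from many molecules into one rate pair (s^-1).

    Events (not per-molecule rates) are pooled, which is more stable at low
    per-trace event counts.  ``method="propagator"`` estimates the per-bin
    switch probabilities p_12 = N_12/N_1, p_21 = N_21/N_2 from the pooled
    transition counts and inverts the exact two-state propagator of the
    sampled chain: p_12 + p_21 = 1 - exp(-(k_12 + k_21) dt), with the rate
    ratio given by p_12/p_21 — this corrects the first-order bias of
    1/mean(dwell) at bin widths comparable to the dwell times.
    ``method="dwell"`` concatenates uncensored dwells and uses 1/mean(dwell).
    For decoded swept traces pass the config's ``sample_interval_ms``.
    """
    dt_s = substep_ms / 1000.0
    if method == "propagator":
        n12 = n21 = n1 = n2 = 0
        for path in paths:
            a = np.asarray(path[:-1], int)
            b = np.asarray(path[1:], int)
            n12 += int(((a == 0) & (b == 1)).sum())
            n21 += int(((a == 1) & (b == 0)).sum())
            n1 += int((a == 0).sum())
            n2 += int((a == 1).sum())
        if n1 == 0 or n2 == 0 or (n12 == 0 and n21 == 0):
            raise InsufficientDataError("no transitions in the pooled paths")
        p12, p21 = n12 / n1, n21 / n2
        s = p12 + p21
        if s >= 1.0:
            raise InsufficientDataError("switching faster than the sampling resolves")
        kd = -np.log(1.0 - s) / dt_s
        return float(kd * p12 / s), float(kd * p21 / s)
    if method != "dwell":
        raise InvalidArgumentError(f"unknown method {method!r}")
    dwell = {0: [], 1: []}
    for path in paths:
        path = np.asarray(path, int)
        edges = np.flatnonzero(np.diff(path)) + 1
        bounds = np.concatenate(([0], edges, [path.size]))
        for a, b in zip(bounds[:-1], bounds[1:]):
            if a == 0 or b == path.size:
                continue
            dwell[int(path[a])].append(b - a)
    out = []
    for s in (0, 1):
        if not dwell[s]:
            raise InsufficientDataError(f"no uncensored dwells in state {s}")
        out.append(1.0 / (float(np.mean(dwell[s])) * dt_s))
    return out[0], out[1]
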