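"""Averaging, difference waves, data-driven windows, and inferential statistics.

Per performer, epochs of the error and hit categories are averaged; their
samplewise difference (error minus hit) isolates error-specific activity.
The analysis channel is FCz, where the Ne/ERN is maximal.  Because no prior
window exists for a ballistic throwing task, the analysis windows are defined
from the grand average of the difference wave: the first window captures the
sharp deflection around its minimum in the 100-350 ms post-release range, the
second the broad deflection between the first window and the moment of KR.
Mean window amplitudes are tested against zero with one-sample t-tests and
correlated with hit percentage across performers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from .preprocess import EpochSet

__all__ = [
    "ERPWaveform",
    "Window",
    "WindowStats",
    "average_epochs",
    "difference_wave",
    "grand_average",
    "detect_windows",
    "mean_amplitude",
    "deflection_magnitude",
    "one_sample_t",
    "pearson_correlation",
    "window_stats",
]

ANALYSIS_CHANNEL = "FCz"


@dataclass
class ERPWaveform:
    """Channelwise trial-average (or difference of averages) on an epoch grid."""

    sync: str
    category: str  # 'hit' | 'error' | 'difference'
    ch_names: list[str]
    times: np.ndarray  # (n_times,) s relative to sync
    amplitudes: np.ndarray  # (n_channels, n_times) microvolt
    n_trials: int

    def channel(self, name: str = ANALYSIS_CHANNEL) -> np.ndarray:
        return self.amplitudes[self.ch_names.index(name)]


@dataclass(frozen=True)
class Window:
    """A detected analysis time window."""

    start: float
    end: float
    peak_time: float | None = None
    peak_amplitude: float | None = None
    defined: bool = True


@dataclass(frozen=True)
class WindowStats:
    """Windowed mean amplitudes with the tests computed on them."""

    window: Window
    amplitudes: np.ndarray  # per-participant mean amplitude, microvolt
    t: float
    df: int
    p: float
    r: float | None = None
    p_r: float | None = None


def average_epochs(es: EpochSet, category: str = "") -> ERPWaveform:
    """Samplewise arithmetic mean across an epoch set's trials."""
    if es.n_epochs < 1:
        raise ValueError("need at least one epoch to average")
    return ERPWaveform(es.sync, category, list(es.ch_names), es.times.copy(),
                       es.epochs.mean(axis=0), es.n_epochs)


def _check_grids(a: ERPWaveform, b: ERPWaveform):
    if (a.times.shape != b.times.shape
            or not np.allclose(a.times, b.times, atol=1e-12)
            or a.ch_names != b.ch_names):
        raise ValueError("waveform grids do not match")


def difference_wave(error_erp: ERPWaveform, hit_erp: ERPWaveform) -> ERPWaveform:
    """Error-minus-hit samplewise difference."""
    _check_grids(error_erp, hit_erp)
    return ERPWaveform(error_erp.sync, "difference", list(error_erp.ch_names),
                       error_erp.times.copy(),
                       error_erp.amplitudes - hit_erp.amplitudes,
                       min(error_erp.n_trials, hit_erp.n_trials))


def grand_average(waves: list[ERPWaveform]) -> ERPWaveform:
    """Unweighted mean over performers."""
    if not waves:
        raise ValueError("no waveforms to average")
    for w in waves[1:]:
        _check_grids(waves[0], w)
    amp = np.mean([w.amplitudes for w in waves], axis=0)
    return ERPWaveform(waves[0].sync, waves[0].category,
                       list(waves[0].ch_names), waves[0].times.copy(), amp,
                       len(waves))


def _fractional_window(trace: np.ndarray, times: np.ndarray,
                       lo: float, hi: float, frac: float) -> Window:
    sel = np.nonzero((times >= lo) & (times <= hi))[0]
    if sel.size == 0:
        return Window(lo, hi, defined=False)
    # a deflection peak is a local extremum: prefer the deepest interior
    # local minimum over a range-edge point where the trace merely keeps
    # falling toward a neighbouring component
    interior = sel[(sel > 0) & (sel < len(trace) - 1)]
    if interior.size:
        is_loc = ((trace[interior] <= trace[interior - 1])
                  & (trace[interior] <= trace[interior + 1]))
        local = interior[is_loc]
    else:
        local = np.empty(0, int)
    if local.size:
        i = int(local[np.argmin(trace[local])])
    else:
        i = int(sel[np.argmin(trace[sel])])
    if trace[i] >= 0:
        return Window(lo, hi, defined=False)
    # the run stays within the search range, so the first window cannot
    # swallow the second deflection when the two merge (feedback locking)
    thresh = frac * trace[i]  # negative
    below = trace <= thresh
    a = i
    while a > sel[0] and below[a - 1]:
        a -= 1
    b = i
    while b < sel[-1] and below[b + 1]:
        b += 1
    return Window(float(times[a]), float(times[b]), float(times[i]),
                  float(trace[i]), True)


def detect_windows(grand_diff: ERPWaveform, kr_bounds: tuple[float, float],
                   frac: float = 0.5,
                   search1: tuple[float, float] | None = None,
                   channel: str = ANALYSIS_CHANNEL,
                   manual: tuple[Window, Window] | None = None
                   ) -> tuple[Window, Window]:
    """Data-driven definition of the two analysis windows at FCz.

    Window 1: the maximal contiguous run around the grand-difference minimum
    in the first-deflection search range where the amplitude stays below
    ``frac`` times that minimum.  Window 2: the same rule around the minimum
    between the end of window 1 and the earliest KR latency (release sync) or
    the KR moment itself (feedback sync, time 0).  ``kr_bounds`` is the
    (lowest, highest) typical KR latency across performers.  A manual window
    pair from the run configuration bypasses detection.
    """
    if manual is not None:
        return manual
    trace = grand_diff.channel(channel)
    times = grand_diff.times
    kr_lo, kr_hi = kr_bounds
    if grand_diff.sync == "release":
        s1 = search1 if search1 is not None else (0.10, 0.35)
        w2_hi = kr_lo
    else:
        s1 = search1 if search1 is not None else (0.10 - kr_hi, 0.35 - kr_lo)
        w2_hi = 0.0
    w1 = _fractional_window(trace, times, s1[0], s1[1], frac)
    if not w1.defined:
        return w1, Window(s1[1], w2_hi, defined=False)
    dt = float(np.diff(times).mean())
    lo2 = w1.end + dt
    w2 = _fractional_window(trace, times, lo2, w2_hi, frac)
    if w2.defined and w2.end > w2_hi:
        w2 = Window(w2.start, w2_hi, w2.peak_time, w2.peak_amplitude, True)
    return w1, w2


def mean_amplitude(wave: ERPWaveform, window: Window,
                   channel: str = ANALYSIS_CHANNEL) -> float:
    """Arithmetic mean of the samples with time in [start, end] inclusive."""
    sel = (wave.times >= window.start) & (wave.times <= window.end)
    if not sel.any():
        raise ValueError("window contains no samples")
    return float(wave.channel(channel)[sel].mean())


def deflection_magnitude(wave: ERPWaveform, search: tuple[float, float],
                         flank: float = 0.10,
                         channel: str = ANALYSIS_CHANNEL) -> float:
    """Prominence of a negative deflection: depth of the minimum in the
    search range below the mean level of the flanking segments.

    Measures what the eye measures on a baseline-corrected waveform — how far
    the dip falls below its surroundings — and is invariant to constant
    offsets, which makes it the right scale for comparing a deflection across
    synchronization schemes.  Returns 0 for a non-negative prominence.
    """
    t = wave.times
    x = wave.channel(channel)
    sel = (t >= search[0]) & (t <= search[1])
    if not sel.any():
        raise ValueError("search range outside the epoch grid")
    trough = x[sel].min()
    flanks = ((t >= search[0] - flank) & (t < search[0])) | \
             ((t > search[1]) & (t <= search[1] + flank))
    level = x[flanks].mean() if flanks.any() else 0.0
    return float(max(level - trough, 0.0))


def epoch_noise_psd(es: EpochSet, channel: str = ANALYSIS_CHANNEL) -> np.ndarray:
    """Per-epoch noise power spectrum of one channel, from the trial-to-trial
    residuals about the epoch average (the event-locked signal cancels)."""
    x = es.epochs[:, es.ch_index(channel), :]
    resid = x - x.mean(axis=0, keepdims=True)
    # residuals of n epochs about their mean carry (n-1)/n of the noise power
    scale = x.shape[0] / max(x.shape[0] - 1, 1)
    return scale * np.mean(np.abs(np.fft.rfft(resid, axis=1)) ** 2, axis=0)


def fit_component_amplitudes(wave: ERPWaveform, t_krs,
                             noise_psd: np.ndarray | None = None,
                             n_trials: int | None = None,
                             channel: str = ANALYSIS_CHANNEL
                             ) -> tuple[float, float]:
    """Recover the injected pulse and boxcar magnitudes by template regression.

    Fits the waveform with the two component templates (the 250 ms Gaussian
    pulse and the mean of the per-trial KR-bounded boxcars) plus an intercept.
    With ``noise_psd`` (per-epoch, e.g. from :func:`epoch_noise_psd`) the fit
    is generalized least squares in the frequency domain, down-weighting the
    coloured background; otherwise least squares on first-differenced data,
    which whitens the dominant low-frequency noise.  Both variants are
    invariant to constant offsets such as the whole-segment baseline.
    Returns the two magnitudes with the sign convention of the injection
    (positive = a negative-going deflection of that size).
    """
    from .synth_cohort import gauss_pulse, smooth_boxcar

    t = wave.times
    g = gauss_pulse(t)
    b = np.mean([smooth_boxcar(t, offset=float(k))
                 for k in np.atleast_1d(t_krs)], axis=0)
    y = wave.channel(channel)
    if noise_psd is None:
        X = np.column_stack([np.diff(g), np.diff(b)])
        beta, *_ = np.linalg.lstsq(X, np.diff(y), rcond=None)
        return float(-beta[0]), float(-beta[1])
    X = np.vstack([np.fft.rfft(g), np.fft.rfft(b)])
    Y = np.fft.rfft(y - y.mean())
    w = np.where(noise_psd > 1e-12 * noise_psd.max(),
                 1.0 / np.maximum(noise_psd, 1e-30), 0.0)
    w[0] = 0.0  # DC carries no information after baseline correction
    A = np.real(X @ (w[None, :] * np.conj(X)).T)
    rhs = np.real(X @ (w * np.conj(Y)))
    beta = np.linalg.solve(A, rhs)
    return float(-beta[0]), float(-beta[1])


def one_sample_t(values) -> tuple[float, int, float]:
    """One-sample t-test of the mean against zero (two-tailed).

    t = mean / (sd / sqrt(n)) with df = n - 1; more negative window
    amplitudes (larger error signals) give more negative t.
    """
    x = np.asarray(values, float)
    n = x.size
    if n < 2:
        raise ValueError("need at least two values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero sample standard deviation: t undefined")
    t = x.mean() / (sd / np.sqrt(n))
    df = n - 1
    p = 2.0 * sstats.t.sf(abs(t), df)
    return float(t), int(df), float(p)


def pearson_correlation(x, y) -> tuple[float, float]:
    """Product-moment correlation with the two-tailed t-based p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need matched samples of size >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input")
    r, p = sstats.pearsonr(x, y)
    return float(r), float(p)


def window_stats(amplitudes, window: Window,
                 hit_percentages=None) -> WindowStats:
    """Bundle per-performer window amplitudes with the t-test (and, when hit
    percentages are given, the performance-amplitude correlation)."""
    amplitudes = np.asarray(amplitudes, float)
    t, df, p = one_sample_t(amplitudes)
    r = p_r = None
    if hit_percentages is not None:
        r, p_r = pearson_correlation(hit_percentages, amplitudes)
    return WindowStats(window, amplitudes, t, df, p, r, p_r)
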