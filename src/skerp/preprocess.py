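"""Continuous-signal conditioning and epoch extraction.

The conditioning chain mirrors standard ERP practice for this kind of
recording: a zero-phase Butterworth band-pass (0.2-30 Hz), re-referencing
from the online left-mastoid reference to averaged mastoids, ocular-artifact
removal from the continuous signal (Infomax ICA, with a regression fallback),
segmentation into fixed-length event-locked epochs, whole-segment baseline
correction, and automatic amplitude/gradient artifact rejection in place of
manual visual inspection.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .eeg_io import (EOG_CHANNELS, MASTOID_CHANNEL, SCALP_CHANNELS,
                     EEGRecording)

__all__ = [
    "EpochSet",
    "bandpass_filter",
    "rereference_avg_mastoids",
    "remove_ocular",
    "infomax_ica",
    "extract_epochs",
    "baseline_correct",
    "reject_artifacts",
    "RELEASE_WINDOW",
    "FEEDBACK_WINDOW",
]

log = logging.getLogger(__name__)

RELEASE_WINDOW = (-0.6, 1.0)
FEEDBACK_WINDOW = (-1.0, 0.8)


@dataclass
class EpochSet:
    """Fixed-length event-locked segments for one synchronization event."""

    sync: str  # 'release' | 'feedback'
    window: tuple[float, float]  # (start, end) s relative to the sync event
    times: np.ndarray  # (n_times,) s
    epochs: np.ndarray  # (n_trials, n_channels, n_times) microvolt
    trial_ids: np.ndarray  # (n_trials,)
    ch_names: list[str]
    sfreq: float
    rejection_log: list[dict] = field(default_factory=list)

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    def ch_index(self, name: str) -> int:
        return self.ch_names.index(name)

    def select(self, trial_ids) -> "EpochSet":
        """Subset by trial id, preserving order of the stored epochs."""
        wanted = set(int(t) for t in trial_ids)
        mask = np.array([int(t) in wanted for t in self.trial_ids])
        return EpochSet(self.sync, self.window, self.times,
                        self.epochs[mask], self.trial_ids[mask],
                        list(self.ch_names), self.sfreq,
                        list(self.rejection_log))


def bandpass_filter(rec: EEGRecording, low: float = 0.2, high: float = 30.0,
                    order: int = 2, channels=None) -> EEGRecording:
    """Zero-phase Butterworth band-pass of the continuous recording.

    The filter is designed at ``order`` and applied forward then backward
    (no net phase shift; effective order doubled), with reflected padding at
    the record edges.  By default only scalp and mastoid channels are
    filtered; EOG channels pass through untouched.
    """
    nyq = rec.sfreq / 2.0
    if not 0 < low < high < nyq:
        raise ValueError(f"band ({low}, {high}) outside (0, {nyq}) Hz")
    sos = signal.butter(order, [low, high], btype="bandpass",
                        fs=rec.sfreq, output="sos")
    out = rec.copy()
    if channels is None:
        channels = [c for c in rec.ch_names if c not in EOG_CHANNELS]
    idx = [rec.ch_index(c) for c in channels]
    pad = 3 * (2 * order + 1) * 10
    pad = min(pad, rec.n_samples - 1)
    out.data[idx] = signal.sosfiltfilt(sos, rec.data[idx], axis=-1,
                                       padtype="even", padlen=pad)
    return out


def rereference_avg_mastoids(rec: EEGRecording) -> EEGRecording:
    """Switch from the online left-mastoid reference to averaged mastoids.

    With the left mastoid M1 as recording reference, the recorded right
    mastoid channel equals M2 - M1, so subtracting half of it from every
    scalp channel re-expresses the data against (M1 + M2)/2.  The mastoid
    channel itself becomes its half; EOG channels are untouched.
    """
    if rec.reference != "left_mastoid":
        raise ValueError(f"expected left_mastoid reference, got {rec.reference}")
    if MASTOID_CHANNEL not in rec.ch_names:
        raise ValueError("right mastoid channel missing")
    out = rec.copy()
    m2 = rec.get(MASTOID_CHANNEL)
    for name in rec.ch_names:
        if name in EOG_CHANNELS:
            continue
        i = out.ch_index(name)
        if name == MASTOID_CHANNEL:
            out.data[i] = m2 / 2.0
        else:
            out.data[i] = rec.data[i] - m2 / 2.0
    out.reference = "averaged_mastoids"
    return out


def _bipolar_eog(rec: EEGRecording) -> np.ndarray:
    """(2, n) horizontal and vertical bipolar EOG derivations."""
    h = rec.get("HEOGL") - rec.get("HEOGR")
    v = rec.get("VEOGU") - rec.get("VEOGD")
    return np.vstack([h, v])


def infomax_ica(data: np.ndarray, seed: int = 0, max_iter: int = 512,
                tol: float = 1e-6, l_rate: float | None = None,
                block: int = 1024):
    """Natural-gradient Infomax ICA with a logistic nonlinearity.

    ``data`` is (n_channels, n_samples), assumed zero-mean per channel after
    internal centring.  The data are whitened by PCA; the square unmixing
    matrix is then learned by block-wise natural-gradient ascent of the
    information-maximization objective, with the learning rate annealed
    whenever successive updates change direction sharply.  Convergence is
    declared when the per-pass weight change drops below ``tol``; hitting
    ``max_iter`` without convergence returns ``converged=False``.

    Returns ``(sources, unmixing, mixing, converged)`` with
    ``sources = unmixing @ data`` and ``mixing = pinv(unmixing)``.
    """
    x = np.asarray(data, float)
    n_ch, n_samp = x.shape
    mean = x.mean(axis=1, keepdims=True)
    x = x - mean
    cov = x @ x.T / n_samp
    evals, evecs = np.linalg.eigh(cov)
    evals = np.maximum(evals, 1e-18)
    sphere = evecs @ np.diag(evals ** -0.5) @ evecs.T
    xw = sphere @ x

    rng = np.random.default_rng(seed)
    W = np.eye(n_ch) + 1e-3 * rng.standard_normal((n_ch, n_ch))
    if l_rate is None:
        l_rate = 0.01 / np.log(max(n_ch, 2) ** 2)
    I = np.eye(n_ch)
    prev_dW = None
    converged = False
    for it in range(max_iter):
        W_old = W.copy()
        perm = rng.permutation(n_samp)
        for start in range(0, n_samp - block + 1, block):
            sel = perm[start:start + block]
            u = W @ xw[:, sel]
            y = 1.0 / (1.0 + np.exp(-u))
            grad = (block * I + (1.0 - 2.0 * y) @ u.T) @ W
            W = W + (l_rate / block) * grad
            if not np.all(np.isfinite(W)):
                raise FloatingPointError("Infomax weights diverged")
        dW = W - W_old
        # squared weight change and >60 deg annealing, the standard
        # natural-gradient bookkeeping for this algorithm
        change = float(np.sum(dW * dW))
        if prev_dW is not None:
            cosang = (np.sum(dW * prev_dW)
                      / max(np.linalg.norm(dW) * np.linalg.norm(prev_dW),
                            1e-30))
            if cosang < 0.5:
                l_rate *= 0.9
        if it >= 32:
            # steady decay so the stochastic-update noise floor keeps
            # shrinking even when the update direction stays consistent
            l_rate *= 0.99
        prev_dW = dW
        if change < tol:
            converged = True
            break
    unmixing = W @ sphere
    mixing = np.linalg.pinv(unmixing)
    return unmixing @ (np.asarray(data, float) - mean), unmixing, mixing, converged


def _remove_by_regression(rec: EEGRecording, targets: list[str]) -> EEGRecording:
    eog = _bipolar_eog(rec)
    if np.allclose(eog.var(axis=1), 0):
        return rec.copy()
    out = rec.copy()
    design = np.vstack([eog, np.ones(rec.n_samples)]).T
    idx = [rec.ch_index(c) for c in targets]
    y = rec.data[idx].T
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    out.data[idx] = (y - design[:, :2] @ coef[:2]).T
    return out


def remove_ocular(rec: EEGRecording, method: str = "infomax",
                  seed: int = 0, corr_threshold: float = 0.8,
                  max_fit_samples: int = 50_000) -> EEGRecording:
    """Remove ocular artifacts from the continuous recording.

    ``regression``: least-squares propagation coefficients of every scalp
    (and mastoid) channel onto the bipolar HEOG/VEOG derivations are
    estimated and the fitted contribution subtracted.

    ``infomax``: Infomax ICA is fitted on all channels (decimated to at most
    ``max_fit_samples`` time points); components whose time courses correlate
    with either bipolar EOG derivation at ``|r| > corr_threshold`` are zeroed
    and the data re-mixed.  EOG channels themselves are passed through
    unchanged.  Non-convergence falls back to regression with a warning.
    """
    present_eog = [c for c in EOG_CHANNELS if c in rec.ch_names]
    if len(present_eog) < 2:
        raise ValueError("need at least two EOG channels")
    targets = [c for c in rec.ch_names if c not in EOG_CHANNELS]
    eog = _bipolar_eog(rec)
    if np.allclose(eog.var(axis=1), 0):
        return rec.copy()
    if method == "regression":
        return _remove_by_regression(rec, targets)
    if method != "infomax":
        raise ValueError(f"unknown method {method!r}")

    n_ch = len(rec.ch_names)
    if rec.n_samples < 20 * n_ch ** 2:
        raise ValueError("record too short for ICA (need >= 20 * channels^2 "
                         "samples)")
    step = max(1, rec.n_samples // max_fit_samples)
    fit = rec.data[:, ::step]
    try:
        _, unmixing, mixing, converged = infomax_ica(fit, seed=seed)
    except FloatingPointError:
        converged = False
    if not converged:
        warnings.warn("Infomax ICA did not converge; falling back to "
                      "regression-based ocular removal")
        log.warning("ICA non-convergence for ocular removal; regression used")
        return _remove_by_regression(rec, targets)

    mean = rec.data.mean(axis=1, keepdims=True)
    sources = unmixing @ (rec.data - mean)
    keep = np.ones(n_ch, bool)
    for k in range(n_ch):
        for e in range(2):
            r = np.corrcoef(sources[k], eog[e])[0, 1]
            if abs(r) > corr_threshold:
                keep[k] = False
    out = rec.copy()
    cleaned = mixing[:, keep] @ sources[keep] + mean
    for name in targets:
        i = rec.ch_index(name)
        out.data[i] = cleaned[i]
    return out


def extract_epochs(rec: EEGRecording, sync: str = "release",
                   window: tuple[float, float] | None = None) -> EpochSet:
    """One fixed-length epoch per event of the sync label.

    Windows default to (-0.6, +1.0) s around release and (-1.0, +0.8) s
    around feedback.  Events whose window would exceed the record bounds are
    dropped and logged.
    """
    if window is None:
        window = RELEASE_WINDOW if sync == "release" else FEEDBACK_WINDOW
    if window[0] >= window[1]:
        raise ValueError("degenerate window")
    events = rec.events_of(sync)
    if not events:
        raise ValueError(f"no events with label {sync!r}")
    fs = rec.sfreq
    n_t = int(round((window[1] - window[0]) * fs))
    off = int(round(window[0] * fs))
    times = (off + np.arange(n_t)) / fs
    kept, ids, dropped = [], [], []
    for trial, sample in events:
        i0 = sample + off
        if i0 < 0 or i0 + n_t > rec.n_samples:
            dropped.append({"trial": int(trial), "reason": "window_out_of_bounds"})
            continue
        kept.append(rec.data[:, i0:i0 + n_t])
        ids.append(trial)
    if dropped:
        log.info("dropped %d %s epochs at record bounds", len(dropped), sync)
    return EpochSet(sync, window, times,
                    np.array(kept) if kept else np.empty((0, len(rec.ch_names), n_t)),
                    np.array(ids, int), list(rec.ch_names), fs, dropped)


def baseline_correct(es: EpochSet) -> EpochSet:
    """Whole-segment baseline: subtract each epoch/channel's own full-window
    mean (not a pre-stimulus interval mean)."""
    if es.n_epochs == 0:
        raise ValueError("empty epoch set")
    out = EpochSet(es.sync, es.window, es.times,
                   es.epochs - es.epochs.mean(axis=2, keepdims=True),
                   es.trial_ids.copy(), list(es.ch_names), es.sfreq,
                   list(es.rejection_log))
    return out


def reject_artifacts(es: EpochSet, amp_limit: float = 100.0,
                     grad_limit: float = 50.0) -> EpochSet:
    """Automatic stand-in for visual artifact inspection.

    Drops epochs whose scalp channels exceed ``amp_limit`` (microvolt,
    absolute) anywhere or jump by more than ``grad_limit`` microvolts between
    consecutive samples; rejected trial ids and the triggering criterion go
    to the rejection log.
    """
    if not (amp_limit > 0 and grad_limit > 0):
        raise ValueError("limits must be > 0")
    scalp = [i for i, c in enumerate(es.ch_names) if c in SCALP_CHANNELS]
    x = es.epochs[:, scalp, :]
    amp_bad = np.abs(x).max(axis=(1, 2)) > amp_limit
    grad_bad = np.abs(np.diff(x, axis=2)).max(axis=(1, 2)) > grad_limit
    keep = ~(amp_bad | grad_bad)
    logrows = list(es.rejection_log)
    for k in np.nonzero(~keep)[0]:
        logrows.append({"trial": int(es.trial_ids[k]),
                        "reason": "amplitude" if amp_bad[k] else "gradient"})
    return EpochSet(es.sync, es.window, es.times, es.epochs[keep],
                    es.trial_ids[keep], list(es.ch_names), es.sfreq, logrows)
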