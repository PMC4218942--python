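"""Band-pass filtering and windowed artifact rejection.

Continuous data are band-pass filtered (default 1–100 Hz, zero-phase
linear-phase FIR), then screened in 500-ms windows starting at stimulus
onsets with two criteria: an absolute-amplitude threshold (±150 µV) and
a data-improbability test.  The improbability statistic estimates, per
channel, the amplitude density over all window samples (histogram,
Freedman–Diaconis bins, floored at 1e-12), scores each window by its
mean negative log-density, and z-scores those across windows — windows
whose single-channel z exceeds 5 or whose all-channel pooled z exceeds
2 are improbable.  Flagged windows are cleared from the retained-sample
mask and their events are excluded from later epoching.

Whether a window must fail *any* criterion or *more than one* is a
configurable mode (default "any"); both behaviours ship because common
practice and a literal reading of the rejection rule disagree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .data_io import Recording, ValidationError

__all__ = [
    "RejectionReport",
    "WindowFlags",
    "bandpass",
    "segment_windows",
    "amplitude_flags",
    "improbability_flags",
    "combine_and_apply",
    "reject_artifacts",
]


@dataclass
class WindowFlags:
    amplitude: np.ndarray
    improbability_single: np.ndarray
    improbability_all: np.ndarray

    def stack(self) -> np.ndarray:
        return np.vstack([self.amplitude, self.improbability_single, self.improbability_all])


@dataclass
class RejectionReport:
    window_ms: float
    window_onsets: np.ndarray
    flags: WindowFlags
    rejected: np.ndarray  # combined per-window decision
    mode: str
    retained_trials: dict[str, int] = field(default_factory=dict)
    total_trials: dict[str, int] = field(default_factory=dict)

    @property
    def n_rejected(self) -> int:
        return int(self.rejected.sum())

    def as_dict(self) -> dict:
        return {
            "window_ms": self.window_ms,
            "n_windows": int(self.rejected.size),
            "n_rejected": self.n_rejected,
            "mode": self.mode,
            "n_flagged_amplitude": int(self.flags.amplitude.sum()),
            "n_flagged_improbability_single": int(self.flags.improbability_single.sum()),
            "n_flagged_improbability_all": int(self.flags.improbability_all.sum()),
            "retained_trials": self.retained_trials,
            "total_trials": self.total_trials,
        }


def bandpass(
    rec: Recording, lo_hz: float = 1.0, hi_hz: float = 100.0
) -> Recording:
    """Zero-phase FIR band-pass; passband flat to ±0.5 dB, DC ≥ 40 dB down.

    A linear-phase (odd-length, symmetric) Hamming-window FIR is applied
    by FFT convolution with reflect padding; symmetry makes the single
    pass exactly zero-phase.
    """
    nyq = rec.fs / 2.0
    if not (0.0 < lo_hz < hi_hz):
        raise ValidationError("need 0 < lo_hz < hi_hz")
    if hi_hz >= nyq:
        raise ValidationError("hi_hz must be below the Nyquist frequency")
    # transition width: tight enough that 0.2 Hz is well into the stopband
    # when lo_hz = 1 (Hamming transition ~3.3/N normalized)
    trans = min(0.8 * lo_hz, nyq - hi_hz)
    numtaps = int(np.ceil(3.3 * rec.fs / trans)) // 2 * 2 + 1
    taps = sps.firwin(numtaps, [lo_hz, hi_hz], pass_zero=False, fs=rec.fs)
    half = numtaps // 2
    padded = np.pad(rec.data, ((0, 0), (half, half)), mode="reflect")
    out = sps.fftconvolve(padded, taps[None, :], mode="valid", axes=1)
    new = rec.copy()
    new.data = out
    return new


def segment_windows(rec: Recording, window_ms: float = 500.0) -> np.ndarray:
    """Per-event analysis windows: [onset, onset + window) samples.

    Returns the onset sample of each full window; events whose window
    would run past the end of the recording are dropped.
    """
    if rec.events is None or len(rec.events) == 0:
        raise ValidationError("recording has no events to window")
    wlen = int(round(window_ms / 1000.0 * rec.fs))
    onsets = rec.events.onsets
    return onsets[onsets + wlen <= rec.n_samples]


def _window_view(data: np.ndarray, onsets: np.ndarray, wlen: int) -> np.ndarray:
    """(n_windows, n_channels, wlen) gather of window samples."""
    idx = onsets[:, None] + np.arange(wlen)[None, :]
    return data[:, idx].transpose(1, 0, 2)


def amplitude_flags(
    rec: Recording, window_onsets: np.ndarray, window_ms: float = 500.0,
    thresh_uv: float = 150.0,
) -> np.ndarray:
    """Flag windows where any channel sample exceeds ±thresh_uv."""
    if thresh_uv <= 0:
        raise ValidationError("amplitude threshold must be positive")
    wlen = int(round(window_ms / 1000.0 * rec.fs))
    win = _window_view(rec.data, window_onsets, wlen)
    return (np.abs(win) > thresh_uv).any(axis=(1, 2))


def improbability_flags(
    rec: Recording,
    window_onsets: np.ndarray,
    window_ms: float = 500.0,
    sd_single: float = 5.0,
    sd_all: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Data-improbability flags (single-channel and all-channel).

    Returns ``(flag_single, flag_all)`` per window.  The z of a
    zero-variance statistic is defined as 0, so identical windows are
    never flagged.
    """
    n_win = window_onsets.size
    if n_win < 20:
        raise ValidationError("improbability test needs >= 20 windows")
    wlen = int(round(window_ms / 1000.0 * rec.fs))
    win = _window_view(rec.data, window_onsets, wlen)  # (W, C, L)
    n_ch = win.shape[1]

    surprise = np.zeros((n_win, n_ch))  # mean neg log density per window+channel
    keep_ch = np.ones(n_ch, dtype=bool)
    for c in range(n_ch):
        x = win[:, c, :].ravel()
        lo, hi = x.min(), x.max()
        if hi == lo:
            keep_ch[c] = False
            warnings.warn(f"channel {rec.channel_names[c]} is constant; excluded")
            continue
        iqr = np.subtract(*np.percentile(x, [75, 25]))
        if iqr > 0:
            bin_w = 2.0 * iqr / x.size ** (1.0 / 3.0)  # Freedman–Diaconis
            n_bins = max(8, min(512, int(np.ceil((hi - lo) / bin_w))))
        else:
            n_bins = 64
        hist, edges = np.histogram(x, bins=n_bins, range=(lo, hi), density=True)
        dens = np.maximum(hist, 1e-12)
        which = np.clip(np.searchsorted(edges, win[:, c, :], side="right") - 1, 0, n_bins - 1)
        surprise[:, c] = -np.log(dens[which]).mean(axis=1)

    def _z(v: np.ndarray) -> np.ndarray:
        sd = v.std()
        return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)

    z_single = np.zeros((n_win, n_ch))
    z_single[:, keep_ch] = np.apply_along_axis(_z, 0, surprise[:, keep_ch]) if keep_ch.any() else 0.0
    flag_single = (z_single > sd_single).any(axis=1)
    pooled = surprise[:, keep_ch].sum(axis=1) if keep_ch.any() else np.zeros(n_win)
    flag_all = _z(pooled) > sd_all
    return flag_single, flag_all


def combine_and_apply(
    rec: Recording,
    flags: WindowFlags,
    window_onsets: np.ndarray,
    window_ms: float = 500.0,
    mode: str = "any",
) -> tuple[Recording, RejectionReport]:
    """Combine criteria, clear rejected windows from the retained mask.

    mode="any": reject windows failing any criterion (default, common
    practice); mode="at_least_two": reject only windows failing two or
    more criteria (literal reading of the rejection rule).
    """
    if mode not in ("any", "at_least_two"):
        raise ValidationError("mode must be 'any' or 'at_least_two'")
    n_fail = flags.stack().sum(axis=0)
    rejected = n_fail >= (1 if mode == "any" else 2)

    wlen = int(round(window_ms / 1000.0 * rec.fs))
    new = rec.copy()
    for onset in window_onsets[rejected]:
        new.retained_mask[onset : onset + wlen] = False

    report = RejectionReport(
        window_ms=window_ms,
        window_onsets=window_onsets,
        flags=flags,
        rejected=rejected,
        mode=mode,
    )
    if rec.events is not None:
        onset_rejected = dict(zip(window_onsets.tolist(), rejected.tolist()))
        for code in np.unique(rec.events.codes):
            sel = rec.events.select(code)
            report.total_trials[str(code)] = int(sel.size)
            kept = sum(
                1
                for o in sel
                if not onset_rejected.get(int(o), True)  # truncated windows count as lost
            )
            report.retained_trials[str(code)] = kept
    return new, report


def reject_artifacts(
    rec: Recording,
    window_ms: float = 500.0,
    thresh_uv: float = 150.0,
    sd_single: float = 5.0,
    sd_all: float = 2.0,
    mode: str = "any",
) -> tuple[Recording, RejectionReport]:
    """Full two-stage rejection: amplitude + improbability, then apply."""
    onsets = segment_windows(rec, window_ms)
    amp = amplitude_flags(rec, onsets, window_ms, thresh_uv)
    imp_s, imp_a = improbability_flags(rec, onsets, window_ms, sd_single, sd_all)
    flags = WindowFlags(amp, imp_s, imp_a)
    return combine_and_apply(rec, flags, onsets, window_ms, mode)
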