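"""Epoching, condition ERPs, deviance responses, pvaf and peak scoring.

Epochs span −100..500 ms around stimulus onset.  Averages are computed
per condition over retained trials only, and the mean of the −100..0 ms
baseline is subtracted AFTER averaging — and, for IC activations, after
the decomposition (baselining before ICA would corrupt the linear
model).  The auditory deviance response is the pointwise
Deviant − Standard difference.

Cluster contributions are expressed in channel space by back-projecting
each member IC (map × source ERP) after polarity alignment, summarised
as an RMS-across-channels trace signed at the channel of maximal
absolute cluster-map projection (RMS itself is unsigned; the signing
convention is a documented choice).  pvaf(component) =
100·(1 − var(total − component)/var(total)) over channels × window.

Peak scoring scans fixed windows — MMN 140–240 ms (negative), P3a
220–340 ms (positive), RON 310–460 ms (negative) — for the extremum of
the nominal polarity (earliest sample on ties), then reports the mean
amplitude over latency ±10 ms, flagging extrema that sit on a window
edge.  A free-polarity mode exists because medial-source projections
can invert.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import DEVIANT, STANDARD, EventSequence, Montage, ValidationError

__all__ = [
    "ERPSet",
    "Peak",
    "PeakSet",
    "PEAK_WINDOWS",
    "PEAK_POLARITY",
    "epoch_average",
    "condition_erps",
    "deviance_response",
    "backproject",
    "signed_rms_trace",
    "pvaf",
    "score_peaks",
    "fz_reference_measures",
    "peak_table_row",
]

PEAK_WINDOWS: dict[str, tuple[float, float]] = {
    "MMN": (140.0, 240.0),
    "P3a": (220.0, 340.0),
    "RON": (310.0, 460.0),
}
PEAK_POLARITY: dict[str, int] = {"MMN": -1, "P3a": +1, "RON": -1}


@dataclass
class ERPSet:
    """Per-condition mean waveforms on a common −100..500 ms time base."""

    times_ms: np.ndarray
    waves: dict[str, np.ndarray]  # condition -> (n_signals, n_times)
    trial_counts: dict[str, int]

    def __post_init__(self) -> None:
        for cond, w in self.waves.items():
            if w.shape[-1] != self.times_ms.size:
                raise ValidationError(f"waveform/time-base mismatch for {cond!r}")
            if self.trial_counts.get(cond, 0) < 1:
                raise ValidationError(f"condition {cond!r} has no trials")


@dataclass
class Peak:
    label: str
    latency_ms: float
    amplitude: float  # mean over latency ±10 ms
    edge: bool


@dataclass
class PeakSet:
    peaks: dict[str, Peak] = field(default_factory=dict)

    def __getitem__(self, label: str) -> Peak:
        return self.peaks[label]


def _epoch_indices(
    events: np.ndarray,
    fs: float,
    n_samples: int,
    retained_mask: np.ndarray | None,
    pre_ms: float,
    post_ms: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample offsets of the epoch window and the usable event onsets."""
    i0 = -int(round(pre_ms / 1000.0 * fs))
    i1 = int(round(post_ms / 1000.0 * fs))
    offs = np.arange(i0, i1)
    ok = []
    for onset in events:
        a, b = onset + i0, onset + i1
        if a < 0 or b > n_samples:
            continue
        if retained_mask is not None and not retained_mask[a:b].all():
            continue
        ok.append(onset)
    return offs, np.asarray(ok, dtype=np.int64)


def epoch_average(
    data: np.ndarray,
    fs: float,
    event_onsets: np.ndarray,
    retained_mask: np.ndarray | None = None,
    pre_ms: float = 100.0,
    post_ms: float = 500.0,
    label: str = "",
) -> tuple[np.ndarray, np.ndarray, int]:
    """Average epochs of 1-D or 2-D continuous data; baseline after averaging.

    Returns ``(times_ms, erp, n_trials)``.  Raises when no trial of the
    condition survives rejection, naming the offending condition.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    offs, usable = _epoch_indices(
        event_onsets, fs, data.shape[1], retained_mask, pre_ms, post_ms
    )
    if usable.size == 0:
        raise ValidationError(f"no retained trials for condition {label or '?'}")
    idx = usable[:, None] + offs[None, :]
    erp = data[:, idx].mean(axis=1)  # (n_signals, n_times)
    times = offs / fs * 1000.0
    baseline = erp[:, times < 0].mean(axis=1, keepdims=True)
    return times, erp - baseline, int(usable.size)


def condition_erps(
    data: np.ndarray,
    fs: float,
    events: EventSequence,
    retained_mask: np.ndarray | None = None,
    pre_ms: float = 100.0,
    post_ms: float = 500.0,
) -> ERPSet:
    """Standard and deviant ERPs of continuous data on one time base."""
    waves = {}
    counts = {}
    times = None
    for cond in (STANDARD, DEVIANT):
        t, erp, n = epoch_average(
            data, fs, events.select(cond), retained_mask, pre_ms, post_ms, label=cond
        )
        times, waves[cond], counts[cond] = t, erp, n
    assert times is not None
    return ERPSet(times_ms=times, waves=waves, trial_counts=counts)


def deviance_response(erps: ERPSet) -> np.ndarray:
    """Pointwise Deviant − Standard difference waveform(s)."""
    if STANDARD not in erps.waves or DEVIANT not in erps.waves:
        raise ValidationError("both condition ERPs are required")
    dev, std = erps.waves[DEVIANT], erps.waves[STANDARD]
    if dev.shape != std.shape:
        raise ValidationError("condition ERPs have mismatched shapes")
    return dev - std


def backproject(
    member_maps: np.ndarray,  # (n_channels, n_members), unit-norm columns
    member_erps: np.ndarray,  # (n_members, n_times), source-resolved
) -> np.ndarray:
    """Channel-space waveforms of a cluster: Σ members map ⊗ ERP.

    Member ICs are polarity-aligned first: any member whose map
    correlates negatively with the cluster-mean map has its (map, ERP)
    pair flipped — a no-op on the sum, but it makes the mean map and the
    summary trace well defined.
    """
    member_maps = np.atleast_2d(np.asarray(member_maps, dtype=float))
    member_erps = np.atleast_2d(np.asarray(member_erps, dtype=float))
    if member_maps.ndim == 2 and member_maps.shape[1] != member_erps.shape[0]:
        raise ValidationError("one ERP per member map required")
    if member_maps.size == 0:
        return np.zeros((0, member_erps.shape[1]))
    maps = member_maps.copy()
    erps = member_erps.copy()
    ref = maps.mean(axis=1)
    if np.linalg.norm(ref) > 0:
        for j in range(maps.shape[1]):
            if maps[:, j] @ ref < 0:
                maps[:, j] *= -1
                erps[j] *= -1
    return maps @ erps


def signed_rms_trace(channel_waves: np.ndarray, cluster_map: np.ndarray | None = None) -> np.ndarray:
    """RMS across channels, signed at the maximal-|projection| channel."""
    channel_waves = np.atleast_2d(channel_waves)
    rms = np.sqrt((channel_waves**2).mean(axis=0))
    if cluster_map is None:
        cluster_map = np.abs(channel_waves).mean(axis=1)
    ch = int(np.argmax(np.abs(cluster_map)))
    return rms * np.sign(channel_waves[ch])


def pvaf(
    component: np.ndarray,
    total: np.ndarray,
    times_ms: np.ndarray | None = None,
    window_ms: tuple[float, float] = (0.0, 500.0),
) -> float:
    """Percent variance of ``total`` accounted for by ``component``.

    Variance pools over all channels and window samples; may be negative
    for components anti-correlated with the total.
    """
    component = np.atleast_2d(component)
    total = np.atleast_2d(total)
    if component.shape != total.shape:
        raise ValidationError("component/total shape mismatch")
    if times_ms is not None:
        sel = (times_ms >= window_ms[0]) & (times_ms <= window_ms[1])
        component = component[:, sel]
        total = total[:, sel]
    v_tot = total.var()
    if v_tot == 0:
        raise ValidationError("total waveform has zero variance")
    return float(100.0 * (1.0 - (total - component).var() / v_tot))


def score_peaks(
    times_ms: np.ndarray,
    wave: np.ndarray,
    windows: dict[str, tuple[float, float]] | None = None,
    polarity: dict[str, int] | str = "nominal",
    mean_halfwidth_ms: float = 10.0,
) -> PeakSet:
    """Score MMN/P3a/RON peaks on one waveform.

    ``polarity="nominal"`` constrains the extremum search to each peak's
    nominal sign; ``polarity="free"`` takes the largest magnitude either
    way.  Latency is the extremum sample (earliest on ties); amplitude
    is the mean over latency ±10 ms; ``edge`` flags extrema at window
    boundaries.
    """
    wave = np.asarray(wave, dtype=float).ravel()
    if wave.size != times_ms.size:
        raise ValidationError("waveform/time-base mismatch")
    windows = PEAK_WINDOWS if windows is None else windows
    if times_ms[0] > min(w[0] for w in windows.values()) or times_ms[-1] < max(
        w[1] for w in windows.values()
    ):
        raise ValidationError("waveform does not cover the peak windows")
    out = PeakSet()
    for label, (lo, hi) in windows.items():
        sel = np.flatnonzero((times_ms >= lo) & (times_ms <= hi))
        seg = wave[sel]
        if polarity == "free":
            j = int(np.argmax(np.abs(seg)))
        else:
            pol = PEAK_POLARITY[label] if polarity == "nominal" else polarity[label]
            j = int(np.argmin(seg)) if pol < 0 else int(np.argmax(seg))
        lat = float(times_ms[sel[j]])
        msel = (times_ms >= lat - mean_halfwidth_ms) & (times_ms <= lat + mean_halfwidth_ms)
        amp = float(wave[msel].mean())
        out.peaks[label] = Peak(
            label=label,
            latency_ms=lat,
            amplitude=amp,
            edge=bool(j == 0 or j == seg.size - 1),
        )
    return out


def fz_reference_measures(
    scalp_erps: ERPSet,
    montage: Montage,
    channel: str = "Fz",
    polarity: dict[str, int] | str = "nominal",
) -> PeakSet:
    """Peak measures of the deviance waveform at the Fz comparator channel."""
    i = montage.index(channel)  # raises if absent
    diff = deviance_response(scalp_erps)
    return score_peaks(scalp_erps.times_ms, diff[i], polarity=polarity)


def peak_table_row(
    subject_id: str,
    group: str,
    source: str,
    peaks: PeakSet,
) -> list[dict]:
    """Tidy rows for the PeakTable TSV: one row per scored peak."""
    return [
        {
            "subject": subject_id,
            "group": group,
            "source": source,
            "peak": p.label,
            "latency_ms": p.latency_ms,
            "amplitude_uv": p.amplitude,
            "edge_flag": int(p.edge),
        }
        for p in peaks.peaks.values()
    ]
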