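"""Synthetic oddball-EEG cohorts with known ground truth.

Emulates a passive duration-oddball session: 1-kHz tones at a 500-ms
onset asynchrony, standards (p = 0.90, 50 ms) and deviants (p = 0.10,
100 ms) with at least 6 standards between deviants, recorded at 500 Hz.
Cortical sources are point dipoles inside the 3-shell spherical head
model shared with :mod:`devsource.localize`; each source emits 1/f
background activity, a small tone-locked response common to both
conditions, and — on deviant trials only — a triphasic MMN/P3a/RON
sequence of Gaussian-windowed bumps whose amplitudes differ by group.
Ocular, myogenic and line-noise artifact sources plus white sensor noise
complete the mixture, so the rejection and IC-screening stages have real
work to do.

Clinical scores are drawn per subject; selected scores can be coupled to
the subject's realized peak amplitudes at a configurable population r²,
which is what the end-to-end correlation audit recovers.

The six-source roster and all waveform parameters are implementer
defaults on a template head, not measured quantities; see docs/methods.md.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import (
    DEVIANT,
    STANDARD,
    EventSequence,
    Montage,
    Recording,
    ValidationError,
    load_montage,
    write_recording,
    write_score_table,
)
from .localize import HeadModel, dipole_gain

__all__ = [
    "DeviancePeak",
    "SourceSpec",
    "Coupling",
    "CohortConfig",
    "GroundTruth",
    "generate_event_sequence",
    "generate_subject",
    "generate_cohort",
    "default_sources",
    "default_score_defs",
    "subject_rng",
]

PEAK_LABELS = ("MMN", "P3a", "RON")


@dataclass
class DeviancePeak:
    label: str
    latency_ms: float
    width_ms: float  # Gaussian SD
    amplitude: dict[str, float]  # group -> signed amplitude, source units

    def __post_init__(self) -> None:
        if self.width_ms <= 0:
            raise ValidationError("peak width must be positive")


@dataclass
class SourceSpec:
    name: str
    location: np.ndarray  # mm, template space
    orientation: np.ndarray  # unit vector
    background_rms: float = 1.0e5  # source units (~10 uV RMS at the scalp)
    one_over_f_exponent: float = 1.0
    oscillations: list[tuple[float, float]] = field(default_factory=list)  # (Hz, rms)
    deviance_peaks: list[DeviancePeak] = field(default_factory=list)
    standard_response: list[DeviancePeak] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.location = np.asarray(self.location, dtype=float)
        self.orientation = np.asarray(self.orientation, dtype=float)
        n = np.linalg.norm(self.orientation)
        if n == 0:
            raise ValidationError("orientation must be non-zero")
        self.orientation = self.orientation / n


@dataclass
class Coupling:
    score: str
    source: str
    peak: str
    target_r2: float
    group: str = "SZ"
    sign: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_r2 < 1.0:
            raise ValidationError("target r² must lie in [0, 1)")


def default_sources(sz_scale: dict[str, float] | None = None) -> list[SourceSpec]:
    """Six-source roster with template coordinates (implementer defaults).

    MMN latencies are staggered across sources; SZ amplitudes are the NCS
    amplitudes scaled per source (default: near-equal in the superior
    temporal source, clearly reduced in the midline sources).
    """
    scale = {
        "R Superior Temporal": 0.95,
        "R Inferior Frontal": 0.70,
        "Ventral Mid-Cingulate": 0.55,
        "Anterior Cingulate": 0.60,
        "Medial Orbitofrontal": 0.60,
        "Dorsal Mid-Cingulate": 0.50,
    }
    if sz_scale:
        scale.update(sz_scale)
    rows = [
        # name, location, orientation, MMN lat, P3a lat, RON lat, amp scale of roster
        ("R Superior Temporal", (52, -22, 8), (0.6, 0.3, 0.74), 158, 262, 352, 1.0),
        ("R Inferior Frontal", (44, 26, 10), (0.55, 0.55, 0.63), 172, 272, 366, 0.8),
        ("Ventral Mid-Cingulate", (3, 2, 34), (0.1, 0.25, 0.96), 186, 282, 380, 0.9),
        ("Anterior Cingulate", (3, 32, 16), (0.1, 0.5, 0.86), 198, 292, 392, 0.8),
        ("Medial Orbitofrontal", (3, 42, -10), (0.0, 0.8, 0.6), 210, 302, 406, 0.7),
        ("Dorsal Mid-Cingulate", (3, 8, 46), (0.1, 0.1, 0.99), 222, 312, 420, 0.8),
    ]
    out = []
    for name, loc, ori, l_mmn, l_p3a, l_ron, a in rows:
        s = scale[name]
        peaks = [
            DeviancePeak("MMN", l_mmn, 25.0, {"NCS": -2.2e4 * a, "SZ": -2.2e4 * a * s}),
            DeviancePeak("P3a", l_p3a, 25.0, {"NCS": 2.6e4 * a, "SZ": 2.6e4 * a * s}),
            DeviancePeak("RON", l_ron, 25.0, {"NCS": -1.8e4 * a, "SZ": -1.8e4 * a * s}),
        ]
        std = [DeviancePeak("N1", 100.0, 18.0, {"NCS": -8.0e3 * a, "SZ": -8.0e3 * a})]
        out.append(
            SourceSpec(
                name=name,
                location=np.array(loc, dtype=float),
                orientation=np.array(ori, dtype=float),
                background_rms=1.0e5,
                one_over_f_exponent=1.0,
                deviance_peaks=peaks,
                standard_response=std,
            )
        )
    return out


def default_score_defs() -> dict[str, tuple[float, float]]:
    """Ten clinical/cognitive score distributions (mean, SD), scale units."""
    return {
        "SANS": (14.0, 5.0),
        "SAPS": (9.0, 4.5),
        "GAF": (41.0, 5.0),
        "SOF": (47.0, 6.0),
        "UPSA": (81.0, 11.0),
        "WRAT": (95.0, 12.0),
        "CVLT_immediate": (40.0, 10.0),
        "CVLT_delayed": (9.0, 3.0),
        "WCST": (18.0, 9.0),
        "LNS": (13.0, 4.0),
    }


@dataclass
class CohortConfig:
    n_subjects: dict[str, int] = field(default_factory=lambda: {"NCS": 10, "SZ": 10})
    fs: float = 500.0
    session_min: float = 20.0
    soa_ms: float = 500.0
    p_deviant: float = 0.10
    min_standards_between: int = 6
    montage: str = "standard-68"
    head_model: HeadModel = field(default_factory=HeadModel)
    sources: list[SourceSpec] = field(default_factory=default_sources)
    # artifacts
    blink_rate_per_min: float = 3.0
    blink_amplitude: float = 190.0  # scalp µV at the dominant frontal channel
    emg_bursts_per_min: float = 2.5
    emg_amplitude: float = 55.0  # scalp µV per burst SD at the dominant temporal channel
    line_noise_hz: float = 60.0
    line_noise_uv: float = 4.0
    sensor_noise_uv: float = 3.0
    # weak fixed-random-map generators emulating the many small cortical
    # and non-cortical processes that make real EEG's residual subspace
    # spatially structured but non-dipolar
    n_noise_sources: int = 48
    noise_source_uv: float = 0.8  # per-channel RMS of each noise generator
    # inter-subject jitter
    location_jitter_mm: float = 5.0
    amplitude_jitter_frac: float = 0.30
    latency_jitter_ms: float = 10.0
    # score model
    score_defs: dict[str, tuple[float, float]] = field(default_factory=default_score_defs)
    couplings: list[Coupling] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_deviant < 1.0:
            raise ValidationError("p_deviant must lie in [0, 1)")
        if self.min_standards_between < 0:
            raise ValidationError("min_standards_between must be >= 0")

    @property
    def n_tones(self) -> int:
        return int(round(self.session_min * 60_000.0 / self.soa_ms))

    def load_montage(self) -> Montage:
        return load_montage(self.montage, scalp_radius=self.head_model.scalp_radius)


@dataclass
class SubjectTruth:
    subject_id: str
    group: str
    source_names: list[str]
    locations: np.ndarray  # (n_sources, 3) realized
    orientations: np.ndarray
    peaks: dict[str, dict[str, dict[str, float]]]  # source -> peak -> {latency, amplitude}
    mixing: np.ndarray | None  # channels × (sources + artifacts)
    mixing_names: list[str]
    artifact_times: dict[str, list[float]]
    timecourses: np.ndarray | None = None  # (sources + artifacts) × samples


@dataclass
class GroundTruth:
    subjects: dict[str, SubjectTruth]
    scores: pd.DataFrame
    couplings: list[Coupling]

    def peak_amplitude(self, subject_id: str, source: str, peak: str) -> float:
        return self.subjects[subject_id].peaks[source][peak]["amplitude"]


def subject_rng(seed: int, subject_index: int) -> np.random.Generator:
    """Deterministic per-subject stream derived from (cohort seed, index)."""
    return np.random.default_rng(np.random.SeedSequence((int(seed), int(subject_index))))


# ---------------------------------------------------------------------------
# event sequences
# ---------------------------------------------------------------------------


def generate_event_sequence(
    n_tones: int,
    p_deviant: float = 0.10,
    min_standards_between: int = 6,
    seed: int | np.random.Generator = 0,
    fs: float = 500.0,
    soa_ms: float = 500.0,
) -> EventSequence:
    """Pseudorandom standard/deviant sequence honouring the run constraint.

    A deviant is only eligible once ``min_standards_between`` standards
    have elapsed since the previous deviant; eligible tones become
    deviants with probability ``p/(1 - min·p)`` so that the empirical
    deviant fraction converges to ``p_deviant``.
    """
    if n_tones < 1:
        raise ValidationError("n_tones must be >= 1")
    m = min_standards_between
    if p_deviant > 1.0 / (1.0 + m):
        raise ValidationError(
            f"p_deviant={p_deviant} infeasible with >= {m} standards between deviants"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if p_deviant == 0:
        codes = np.array([STANDARD] * n_tones, dtype=object)
    else:
        p_adj = p_deviant / (1.0 - m * p_deviant)
        codes = np.empty(n_tones, dtype=object)
        since = m  # allow an early deviant
        for i in range(n_tones):
            if since >= m and rng.random() < p_adj:
                codes[i] = DEVIANT
                since = 0
            else:
                codes[i] = STANDARD
                since += 1
    step = soa_ms / 1000.0 * fs
    onsets = np.round(np.arange(n_tones) * step).astype(np.int64)
    return EventSequence(onsets, codes)


# ---------------------------------------------------------------------------
# waveform building blocks
# ---------------------------------------------------------------------------


def _one_over_f_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS noise with a ~1/f^exponent power spectrum."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0)
    shaping = np.ones_like(f)
    nz = f > 0
    shaping[nz] = f[nz] ** (-exponent / 2.0)
    shaping[0] = 0.0  # no DC
    x = np.fft.irfft(spec * shaping, n)
    return x / np.std(x)


def _gaussian_bump(fs: float, latency_ms: float, width_ms: float) -> tuple[np.ndarray, int]:
    """Sampled Gaussian bump (unit peak) and its onset offset in samples."""
    half = 4.0 * width_ms
    t0 = latency_ms - half
    t1 = latency_ms + half
    i0 = int(np.floor(t0 / 1000.0 * fs))
    i1 = int(np.ceil(t1 / 1000.0 * fs))
    t = np.arange(i0, i1 + 1) / fs * 1000.0
    return np.exp(-0.5 * ((t - latency_ms) / width_ms) ** 2), i0


def _add_at(x: np.ndarray, onset: int, kernel: np.ndarray, offset: int, gain: float) -> None:
    a = onset + offset
    b = a + kernel.size
    ka, kb = 0, kernel.size
    if a < 0:
        ka = -a
        a = 0
    if b > x.size:
        kb = kernel.size - (b - x.size)
        b = x.size
    if a < b:
        x[a:b] += gain * kernel[ka:kb]


def _unshielded_map(position: np.ndarray, moment: np.ndarray, montage: Montage) -> np.ndarray:
    """Dipole map without the skull shells (used for non-brain sources).

    Ocular and myogenic generators sit outside the brain shell where the
    3-shell expansion does not apply; a bare dipole-field falloff gives
    them the steep, non-brain-dipolar topographies that the dipolarity
    screen is meant to reject.
    """
    d = montage.positions - np.asarray(position, float)[None, :]
    r = np.linalg.norm(d, axis=1)
    raw = (d @ np.asarray(moment, float)) / r**3
    # unit peak gain: artifact amplitudes are specified in scalp µV at the
    # dominant channel, independent of montage density
    return raw / np.abs(raw).max()


# ---------------------------------------------------------------------------
# subjects and cohorts
# ---------------------------------------------------------------------------


def _realize_sources(
    config: CohortConfig, group: str, rng: np.random.Generator
) -> tuple[list[SourceSpec], np.ndarray, dict]:
    """Apply per-subject jitter; return specs, locations and realized peaks."""
    locs = []
    peaks: dict[str, dict[str, dict[str, float]]] = {}
    brain_r = config.head_model.brain_radius
    for spec in config.sources:
        if np.linalg.norm(spec.location) >= brain_r:
            raise ValidationError(
                f"source {spec.name!r} lies outside the brain shell"
            )
        loc = spec.location + rng.normal(0.0, config.location_jitter_mm, size=3)
        ecc = np.linalg.norm(loc)
        if ecc >= 0.95 * brain_r:  # keep jittered sources inside the brain shell
            loc = loc * (0.95 * brain_r / ecc)
        locs.append(loc)
        pk: dict[str, dict[str, float]] = {}
        for p in spec.deviance_peaks:
            base = p.amplitude[group]
            amp = base * (1.0 + rng.normal(0.0, config.amplitude_jitter_frac))
            lat = p.latency_ms + rng.normal(0.0, config.latency_jitter_ms)
            pk[p.label] = {"latency_ms": float(lat), "amplitude": float(amp)}
        peaks[spec.name] = pk
    return config.sources, np.array(locs), peaks


def generate_subject(
    config: CohortConfig,
    subject_id: str,
    group: str,
    seed: int | np.random.Generator,
    montage: Montage | None = None,
    keep_timecourses: bool = False,
) -> tuple[Recording, SubjectTruth]:
    """Synthesize one subject's continuous recording plus its ground truth."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if montage is None:
        montage = config.load_montage()
    fs = config.fs
    n_samples = int(round(config.session_min * 60.0 * fs))
    events = generate_event_sequence(
        config.n_tones,
        config.p_deviant,
        config.min_standards_between,
        rng,
        fs=fs,
        soa_ms=config.soa_ms,
    )
    if len(events) and events.onsets[-1] >= n_samples:
        raise ValidationError("session too short for the requested tone count")

    specs, locs, peaks = _realize_sources(config, group, rng)
    for loc in locs:
        if np.linalg.norm(loc) >= config.head_model.brain_radius:
            raise ValidationError("source outside the brain shell")

    n_src = len(specs)
    mix_cols: list[np.ndarray] = []
    tcs = np.zeros((n_src, n_samples))
    dev_onsets = events.select(DEVIANT)
    all_onsets = events.onsets
    for i, spec in enumerate(specs):
        gain = dipole_gain(locs[i], config.head_model, montage) @ spec.orientation
        mix_cols.append(gain)
        tc = np.zeros(n_samples)
        if spec.background_rms > 0:
            tc += spec.background_rms * _one_over_f_noise(
                n_samples, spec.one_over_f_exponent, rng
            )
        for hz, rms in spec.oscillations:
            phase = rng.uniform(0, 2 * np.pi)
            tc += rms * np.sqrt(2.0) * np.sin(
                2 * np.pi * hz * np.arange(n_samples) / fs + phase
            )
        for p in spec.standard_response:
            kern, off = _gaussian_bump(fs, p.latency_ms, p.width_ms)
            amp = p.amplitude[group]
            for onset in all_onsets:
                _add_at(tc, int(onset), kern, off, amp)
        for p in spec.deviance_peaks:
            realized = peaks[spec.name][p.label]
            kern, off = _gaussian_bump(fs, realized["latency_ms"], p.width_ms)
            for onset in dev_onsets:
                _add_at(tc, int(onset), kern, off, realized["amplitude"])
        tcs[i] = tc

    # artifact sources
    art_names: list[str] = []
    art_cols: list[np.ndarray] = []
    art_tcs: list[np.ndarray] = []
    art_times: dict[str, list[float]] = {}

    if config.blink_rate_per_min > 0 and config.blink_amplitude > 0:
        blink_map = _unshielded_map((0.0, 81.0, -28.0), (0.0, 0.3, 1.0), montage)
        n_blinks = rng.poisson(config.blink_rate_per_min * config.session_min)
        times = np.sort(rng.uniform(0, n_samples - int(0.6 * fs), size=n_blinks))
        tc = np.zeros(n_samples)
        d = int(0.3 * fs)  # 300-ms primary lobe
        up = np.sin(np.pi * np.arange(d) / d) ** 2
        down = -0.25 * np.sin(np.pi * np.arange(d) / d) ** 2
        kern = np.concatenate([up, down])
        for t0 in times:
            _add_at(tc, int(t0), kern, 0, 1.0)
        art_names.append("blink")
        art_cols.append(blink_map * config.blink_amplitude)
        art_tcs.append(tc)
        art_times["blink"] = (times / fs).tolist()

    if config.emg_bursts_per_min > 0 and config.emg_amplitude > 0:
        from scipy import signal as sps

        for side, pos in (("emg_left", (-86.0, -12.0, -6.0)), ("emg_right", (86.0, -12.0, -6.0))):
            emg_map = _unshielded_map(pos, np.asarray(pos) / np.linalg.norm(pos), montage)
            n_bursts = rng.poisson(config.emg_bursts_per_min * config.session_min / 2.0)
            times = np.sort(rng.uniform(0, n_samples - int(0.5 * fs), size=n_bursts))
            tc = np.zeros(n_samples)
            d = int(0.35 * fs)
            sos = sps.butter(4, [20.0, min(100.0, 0.45 * fs)], btype="bandpass", fs=fs, output="sos")
            for t0 in times:
                burst = sps.sosfilt(sos, rng.standard_normal(d))
                burst *= np.hanning(d) / (np.std(burst) + 1e-12)
                _add_at(tc, int(t0), burst, 0, 1.0)
            art_names.append(side)
            art_cols.append(emg_map * config.emg_amplitude)
            art_tcs.append(tc)
            art_times[side] = (times / fs).tolist()

    if config.n_noise_sources > 0 and config.noise_source_uv > 0:
        nmaps = rng.standard_normal((len(montage), config.n_noise_sources))
        nmaps /= np.linalg.norm(nmaps, axis=0, keepdims=True)
        for j in range(config.n_noise_sources):
            art_names.append(f"noise{j:02d}")
            art_cols.append(nmaps[:, j] * config.noise_source_uv * np.sqrt(len(montage)))
            art_tcs.append(_one_over_f_noise(n_samples, 1.0, rng))

    if config.line_noise_uv > 0:
        # near-common map with a mild front-to-back gradient
        grad = 1.0 + 0.2 * (montage.positions[:, 1] / config.head_model.scalp_radius)
        phase = rng.uniform(0, 2 * np.pi)
        tc = np.sin(2 * np.pi * config.line_noise_hz * np.arange(n_samples) / fs + phase)
        art_names.append("line")
        art_cols.append(grad * config.line_noise_uv)
        art_tcs.append(tc)

    mixing = np.column_stack(mix_cols + art_cols) if (mix_cols or art_cols) else np.zeros((len(montage), 0))
    stacked = np.vstack([tcs] + [t[None, :] for t in art_tcs]) if art_tcs else tcs
    data = mixing @ stacked
    if config.sensor_noise_uv > 0:
        data = data + rng.normal(0.0, config.sensor_noise_uv, size=data.shape)

    rec = Recording(
        data=data,
        fs=fs,
        channel_names=list(montage.channel_names),
        events=events,
    )
    truth = SubjectTruth(
        subject_id=subject_id,
        group=group,
        source_names=[s.name for s in specs],
        locations=locs,
        orientations=np.array([s.orientation for s in specs]),
        peaks=peaks,
        mixing=mixing,
        mixing_names=[s.name for s in specs] + art_names,
        artifact_times=art_times,
        timecourses=stacked if keep_timecourses else None,
    )
    return rec, truth


def _theoretical_peak_sd(config: CohortConfig, source: str, peak: str, group: str) -> tuple[float, float]:
    """Population mean and SD of the realized peak amplitude."""
    for spec in config.sources:
        if spec.name == source:
            for p in spec.deviance_peaks:
                if p.label == peak:
                    base = p.amplitude[group]
                    return base, abs(base) * config.amplitude_jitter_frac
    raise ValidationError(f"coupling references unknown source/peak {source}/{peak}")


def _make_scores(
    config: CohortConfig,
    truths: dict[str, SubjectTruth],
    rng: np.random.Generator,
) -> pd.DataFrame:
    rows = []
    order = list(truths.values())
    coupled = {(c.score, c.group): c for c in config.couplings}
    for c in config.couplings:
        if c.score not in config.score_defs:
            raise ValidationError(f"coupling references unknown score {c.score!r}")
        _theoretical_peak_sd(config, c.source, c.peak, c.group)  # validates
    for st in order:
        row: dict[str, object] = {"subject_id": st.subject_id, "group": st.group}
        for name, (mean, sd) in config.score_defs.items():
            c = coupled.get((name, st.group))
            if c is not None and c.target_r2 > 0:
                base, amp_sd = _theoretical_peak_sd(config, c.source, c.peak, c.group)
                x = st.peaks[c.source][c.peak]["amplitude"]
                beta = c.sign * sd * np.sqrt(c.target_r2) / amp_sd
                noise = rng.normal(0.0, sd * np.sqrt(1.0 - c.target_r2))
                row[name] = mean + beta * (x - base) + noise
            else:
                row[name] = mean + rng.normal(0.0, sd)
        rows.append(row)
    return pd.DataFrame(rows)


def generate_cohort(
    config: CohortConfig,
    signals: bool = True,
    keep_timecourses: bool = False,
) -> tuple[dict[str, Recording], pd.DataFrame, GroundTruth]:
    """Generate a full cohort: recordings (optional), scores, ground truth.

    With ``signals=False`` only the latent per-subject source parameters
    and the coupled clinical scores are realized — the study conditions
    without the waveforms — which keeps large Monte-Carlo audits of the
    score↔peak couplings tractable.
    """
    montage = config.load_montage() if signals else None
    recordings: dict[str, Recording] = {}
    truths: dict[str, SubjectTruth] = {}
    idx = 0
    score_rng = np.random.default_rng(np.random.SeedSequence((int(config.seed), 10_000_019)))
    for group in sorted(config.n_subjects):
        for k in range(config.n_subjects[group]):
            sid = f"{group}{k + 1:03d}"
            rng = subject_rng(config.seed, idx)
            if signals:
                rec, truth = generate_subject(
                    config, sid, group, rng, montage=montage, keep_timecourses=keep_timecourses
                )
                recordings[sid] = rec
            else:
                _, locs, peaks = _realize_sources(config, group, rng)
                truth = SubjectTruth(
                    subject_id=sid,
                    group=group,
                    source_names=[s.name for s in config.sources],
                    locations=locs,
                    orientations=np.array([s.orientation for s in config.sources]),
                    peaks=peaks,
                    mixing=None,
                    mixing_names=[],
                    artifact_times={},
                )
            truths[sid] = truth
            idx += 1
    scores = _make_scores(config, truths, score_rng)
    gt = GroundTruth(subjects=truths, scores=scores, couplings=list(config.couplings))
    return recordings, scores, gt


def ground_truth_ic_records(
    config: CohortConfig,
    truth: GroundTruth,
    montage: Montage | None = None,
    fit_dipoles: bool = True,
    map_noise: float = 0.05,
    seed: int = 0,
):
    """Build per-subject IC records directly from cohort ground truth.

    For every subject and planted source this synthesizes the IC-level
    clustering measures — forward-projected scalp map (plus optional map
    noise), fitted (or planted) equivalent dipole, 3–50 Hz log spectrum
    and condition ERPs — without running the decomposition chain.  This
    is the scale-friendly substrate for clustering-recovery and audit
    studies on large cohorts.
    """
    from .cluster import ICRecord
    from .localize import DipoleFit, fit_dipole

    if montage is None:
        montage = config.load_montage()
    fs = config.fs
    times = np.arange(0, int(round(0.5 * fs)) + 1) / fs * 1000.0  # 0..500 ms
    freqs = np.arange(3.0, 50.0 + 1e-9, 1.0)
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 424243)))
    records = []
    for st in truth.subjects.values():
        for i, name in enumerate(st.source_names):
            gain = dipole_gain(st.locations[i], config.head_model, montage) @ st.orientations[i]
            g = np.linalg.norm(gain)
            scalp_map = gain / g
            if map_noise > 0:
                scalp_map = scalp_map + rng.normal(0.0, map_noise, size=scalp_map.size)
                scalp_map = scalp_map / np.linalg.norm(scalp_map)
            if fit_dipoles:
                dip = fit_dipole(
                    scalp_map, config.head_model, montage,
                    n_starts=4, seed=rng,
                )
            else:
                dip = DipoleFit(
                    position=st.locations[i],
                    moment=st.orientations[i],
                    rv=0.0,
                    inside_brain=True,
                )
            spec = next(s for s in config.sources if s.name == name)
            log_spec = 10.0 * np.log10(spec.background_rms**2 / freqs) + rng.normal(
                0.0, 1.0, size=freqs.size
            )
            peak_gain = np.abs(gain).max()
            erp_std = np.zeros_like(times)
            for p in spec.standard_response:
                erp_std += (
                    p.amplitude[st.group]
                    * peak_gain
                    * np.exp(-0.5 * ((times - p.latency_ms) / p.width_ms) ** 2)
                )
            erp_dev = erp_std.copy()
            for p in spec.deviance_peaks:
                realized = st.peaks[name][p.label]
                erp_dev += (
                    realized["amplitude"]
                    * peak_gain
                    * np.exp(
                        -0.5 * ((times - realized["latency_ms"]) / p.width_ms) ** 2
                    )
                )
            records.append(
                ICRecord(
                    subject_id=st.subject_id,
                    group=st.group,
                    ic_index=i,
                    scalp_map=scalp_map,
                    dipole=dip,
                    log_spectrum=log_spec,
                    erp_standard=erp_std,
                    erp_deviant=erp_dev,
                    source_name=name,
                )
            )
    return records


def planted_peak_table(truth: GroundTruth) -> pd.DataFrame:
    """Tidy peak table built from ground-truth realized peaks.

    Latency and amplitude are the planted per-subject values; the table
    has the same shape the measurement pipeline produces, so the
    correlation audit can run on cohorts where only the latent layer was
    generated.
    """
    rows = []
    for st in truth.subjects.values():
        for name, peaks in st.peaks.items():
            for label, v in peaks.items():
                rows.append(
                    {
                        "subject": st.subject_id,
                        "group": st.group,
                        "source": name,
                        "peak": label,
                        "latency_ms": v["latency_ms"],
                        "amplitude_uv": v["amplitude"],
                        "edge_flag": 0,
                    }
                )
    return pd.DataFrame(rows)


def write_cohort(
    config: CohortConfig,
    out_dir: str | Path,
    signals: bool = True,
) -> Path:
    """Materialize a cohort on disk: EDF+ + events TSV + scores TSV + truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    recordings, scores, gt = generate_cohort(config, signals=signals)
    for sid, rec in recordings.items():
        write_recording(rec, out / f"{sid}.edf", out / f"{sid}_events.tsv")
    write_score_table(scores, out / "scores.tsv")
    truth_json = {
        sid: {
            "group": st.group,
            "sources": st.source_names,
            "locations": st.locations.tolist(),
            "peaks": st.peaks,
            "artifact_times": st.artifact_times,
        }
        for sid, st in gt.subjects.items()
    }
    (out / "ground_truth.json").write_text(json.dumps(truth_json, indent=1))
    return out
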