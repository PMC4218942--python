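"""Shared data model and on-disk formats.

Raw EEG travels as EDF (16-bit, configurable physical range, default
±1000 µV) with stimulus events in a sidecar TSV (``onset_sample<TAB>code``)
so that integer sample onsets survive round trips losslessly.  Electrode
positions live either in a built-in 68-channel 10-5 template montage or in
whitespace-delimited ``name x y z`` ("sfp"-style) files.  Clinical and
cognitive score tables are TSV with one row per subject.

Conventions used throughout the package:

* sample indexing is 0-based; epoch intervals are half-open in samples;
* times in ms are relative to stimulus onset;
* potentials are in µV; positions in mm, right-anterior-superior, origin
  at the head-model centre;
* the nose reference is a property of the recording, no re-referencing is
  performed by default.
"""

from __future__ import annotations

import datetime
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EventSequence",
    "Recording",
    "Montage",
    "ValidationError",
    "FormatError",
    "STANDARD",
    "DEVIANT",
    "CHANNELS_68",
    "read_recording",
    "write_recording",
    "read_events",
    "write_events",
    "load_montage",
    "read_score_table",
    "write_score_table",
]

STANDARD = "standard"
DEVIANT = "deviant"


class ValidationError(ValueError):
    """Raised when an in-memory object violates its invariants."""


class FormatError(ValueError):
    """Raised when an on-disk artifact cannot be interpreted."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class EventSequence:
    """Stimulus events: sample onsets plus standard/deviant codes."""

    onsets: np.ndarray
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=np.int64)
        self.codes = np.asarray(self.codes, dtype=object)
        if self.onsets.ndim != 1 or self.codes.shape != self.onsets.shape:
            raise ValidationError("onsets and codes must be 1-D and equal length")
        if self.onsets.size and np.any(np.diff(self.onsets) <= 0):
            raise ValidationError("event onsets must be strictly increasing")
        bad = set(self.codes) - {STANDARD, DEVIANT}
        if bad:
            raise ValidationError(f"unknown event codes: {sorted(bad)}")

    def __len__(self) -> int:
        return self.onsets.size

    def select(self, code: str) -> np.ndarray:
        """Onsets of all events with the given code."""
        return self.onsets[self.codes == code]


@dataclass
class Recording:
    """Continuous multi-channel EEG: channels × samples, in µV."""

    data: np.ndarray
    fs: float
    channel_names: list[str]
    reference: str = "nose"
    events: EventSequence | None = None
    retained_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValidationError("data must be channels × samples")
        if self.fs <= 0:
            raise ValidationError("sampling rate must be positive")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValidationError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} data rows"
            )
        if self.retained_mask is None:
            self.retained_mask = np.ones(self.data.shape[1], dtype=bool)
        else:
            self.retained_mask = np.asarray(self.retained_mask, dtype=bool)
            if self.retained_mask.shape != (self.data.shape[1],):
                raise ValidationError("retained_mask length must equal n_samples")
        if self.events is not None and len(self.events):
            if self.events.onsets[0] < 0 or self.events.onsets[-1] >= self.n_samples:
                raise ValidationError("event onsets must fall inside [0, n_samples)")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def copy(self) -> "Recording":
        return replace(
            self,
            data=self.data.copy(),
            retained_mask=self.retained_mask.copy(),
        )


@dataclass
class Montage:
    """Electrode positions (mm) on the template head, RAS, origin at centre."""

    channel_names: list[str]
    positions: np.ndarray  # (n_channels, 3)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64)
        if self.positions.shape != (len(self.channel_names), 3):
            raise ValidationError("one 3-D position required per channel")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValidationError("duplicate channel labels in montage")

    def __len__(self) -> int:
        return len(self.channel_names)

    def index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise ValidationError(f"channel {name!r} not in montage") from None

    def subset(self, names: list[str]) -> "Montage":
        idx = [self.index(n) for n in names]
        return Montage(list(names), self.positions[idx])


# 68-channel roster on the extended 10-5 system (the montage size analysed
# throughout; the template positions come from the MNE colin27 10-5 layout).
CHANNELS_68 = (
    "Fp1 Fpz Fp2 AF7 AF3 AFz AF4 AF8 F7 F5 F3 F1 Fz F2 F4 F6 F8 "
    "FT7 FC5 FC3 FC1 FCz FC2 FC4 FC6 FT8 T7 C5 C3 C1 Cz C2 C4 C6 T8 "
    "TP7 CP5 CP3 CP1 CPz CP2 CP4 CP6 TP8 P7 P5 P3 P1 Pz P2 P4 P6 P8 "
    "PO7 PO5 PO3 POz PO4 PO6 PO8 O1 Oz O2 FT9 FT10 TP9 TP10 Iz"
).split()

# symmetric reduced rosters with full head coverage, for test profiles
_CHANNEL_SUBSETS: dict[int, list[str]] = {
    16: "Fp1 Fp2 F7 F3 Fz F4 F8 T7 C3 Cz C4 T8 P3 Pz P4 Oz".split(),
    24: (
        "Fp1 Fp2 F7 F3 Fz F4 F8 FT7 FC3 FCz FC4 FT8 "
        "T7 C3 Cz C4 T8 P7 P3 Pz P4 P8 O1 O2"
    ).split(),
    32: (
        "Fp1 Fpz Fp2 AF7 AF8 F7 F3 Fz F4 F8 FT7 FC3 FCz FC4 FT8 "
        "T7 C3 Cz C4 T8 TP7 CP3 CPz CP4 TP8 P7 P3 Pz P4 P8 O1 O2"
    ).split(),
    68: CHANNELS_68,
}


def load_montage(source: str | Path, scalp_radius: float = 92.0) -> Montage:
    """Load electrode positions and register them to the spherical head model.

    ``source`` is either a built-in montage name (``"standard-68"``;
    ``"standard-N"`` gives a symmetric N-channel subset for N in
    {16, 24, 32}, otherwise the roster's first N channels) or a path to
    a ``name x y z`` positions file.
    Positions are centred on a least-squares sphere fit, rotated about the
    x axis so Cz sits at the apex (when Cz is present), and projected onto
    the scalp radius of the head model.
    """
    name = str(source)
    if name.startswith("standard-"):
        try:
            n = int(name.split("-", 1)[1])
        except ValueError:
            raise ValidationError(f"unknown builtin montage {name!r}") from None
        if not 4 <= n <= 68:
            raise ValidationError("builtin montages cover 4..68 channels")
        labels = _CHANNEL_SUBSETS.get(n, CHANNELS_68[:n])
        raw = _template_positions(labels)
    else:
        path = Path(source)
        if not path.exists():
            raise FormatError(f"montage source {name!r} is neither builtin nor a file")
        labels, raw = _read_sfp(path)
    return _register_to_sphere(labels, raw, scalp_radius)


def _template_positions(labels: list[str]) -> np.ndarray:
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        montage = mne.channels.make_standard_montage("standard_1005")
    pos = montage.get_positions()["ch_pos"]
    missing = [l for l in labels if l not in pos]
    if missing:
        raise ValidationError(f"unknown channel labels: {missing}")
    return np.array([pos[l] for l in labels]) * 1000.0  # m -> mm


def _read_sfp(path: Path) -> tuple[list[str], np.ndarray]:
    labels: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        parts = line.split()
        if not parts or parts[0].startswith("#"):
            continue
        if len(parts) != 4:
            raise FormatError(f"{path}:{lineno}: expected 'name x y z'")
        labels.append(parts[0])
        try:
            rows.append([float(v) for v in parts[1:]])
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-numeric coordinate") from None
    if len(set(labels)) != len(labels):
        raise ValidationError(f"duplicate labels in {path}")
    if not labels:
        raise FormatError(f"{path}: empty montage file")
    return labels, np.asarray(rows, dtype=float)


def _register_to_sphere(
    labels: list[str], raw: np.ndarray, scalp_radius: float
) -> Montage:
    # least-squares sphere fit: |x - c|^2 = r^2 is linear in (c, r^2 - |c|^2)
    if len(labels) >= 4:
        A = np.hstack([2 * raw, np.ones((len(raw), 1))])
        b = (raw**2).sum(axis=1)
        sol, *_ = np.linalg.lstsq(A, b, rcond=None)
        centre = sol[:3]
    else:
        centre = raw.mean(axis=0)
    pos = raw - centre
    if "Cz" in labels:
        cz = pos[labels.index("Cz")]
        # rotate about x so Cz's (y, z) aligns with the apex; preserves the
        # left/right mirror symmetry of the roster
        theta = np.arctan2(cz[1], cz[2])
        c, s = np.cos(theta), np.sin(theta)
        rot = np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])
        pos = pos @ rot.T
    norms = np.linalg.norm(pos, axis=1)
    if np.any(norms == 0):
        raise ValidationError("electrode coincides with the head-model centre")
    pos = pos / norms[:, None] * scalp_radius
    return Montage(labels, pos)


# ---------------------------------------------------------------------------
# events and score tables
# ---------------------------------------------------------------------------


def write_events(events: EventSequence, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame({"onset_sample": events.onsets, "code": events.codes})
    df.to_csv(path, sep="\t", index=False)
    return path


def read_events(path: str | Path) -> EventSequence:
    df = pd.read_csv(path, sep="\t")
    for col in ("onset_sample", "code"):
        if col not in df.columns:
            raise FormatError(f"events file {path} lacks column {col!r}")
    return EventSequence(df["onset_sample"].to_numpy(), df["code"].to_numpy())


def write_score_table(scores: pd.DataFrame, path: str | Path) -> Path:
    if "subject_id" not in scores.columns or "group" not in scores.columns:
        raise ValidationError("score table needs subject_id and group columns")
    if scores["subject_id"].duplicated().any():
        raise ValidationError("subject_id must be unique")
    path = Path(path)
    scores.to_csv(path, sep="\t", index=False)
    return path


def read_score_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "subject_id" not in df.columns or "group" not in df.columns:
        raise FormatError(f"score table {path} lacks subject_id/group")
    if df["group"].isna().any():
        raise ValidationError("group must be non-empty for every subject")
    if df["subject_id"].duplicated().any():
        raise ValidationError("subject_id must be unique")
    return df


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

_EDF_DIG_MIN, _EDF_DIG_MAX = -32767, 32767


def write_recording(
    rec: Recording,
    edf_path: str | Path,
    events_path: str | Path | None = None,
    phys_range: float = 1000.0,
) -> tuple[Path, Path | None]:
    """Write a Recording as EDF+ (continuous) plus a sidecar events TSV.

    Samples are quantised to 16 bits over ±``phys_range`` µV.  Records are
    one second long; the final record is zero-padded, so recordings whose
    length is a whole number of seconds round-trip exactly.
    """
    if not np.all(np.isfinite(rec.data)):
        raise ValidationError("recording contains non-finite samples")
    if np.max(np.abs(rec.data), initial=0.0) > phys_range:
        raise ValidationError(
            f"samples exceed the physical range ±{phys_range} µV; "
            "increase phys_range"
        )
    edf_path = Path(edf_path)
    fs = rec.fs
    spr = int(round(fs))  # samples per 1-s record
    if abs(spr - fs) > 1e-9:
        raise ValidationError("EDF writer requires an integer sampling rate")
    n_rec = int(np.ceil(rec.n_samples / spr)) if rec.n_samples else 0
    n_sig = rec.n_channels + 1  # + one EDF Annotations signal

    scale = (2.0 * phys_range) / (_EDF_DIG_MAX - _EDF_DIG_MIN)
    digital = np.round(rec.data / scale).astype("<i2")
    pad = n_rec * spr - rec.n_samples
    if pad:
        digital = np.pad(digital, ((0, 0), (0, pad)))

    # annotation payload per record: one timestamp TAL; fixed byte budget
    ann_len = 20  # bytes -> 10 2-byte "samples"
    anns = []
    for r in range(n_rec):
        tal = f"+{r * spr / fs:g}\x14\x14\x00".encode("ascii")
        anns.append(tal.ljust(ann_len, b"\x00"))

    now = datetime.datetime(2000, 1, 1)
    hdr = b""
    hdr += b"0".ljust(8)
    hdr += b"X X X X".ljust(80)  # local patient id (anonymous)
    hdr += b"Startdate 01-JAN-2000 X devsource X".ljust(80)
    hdr += now.strftime("%d.%m.%y").encode().ljust(8)
    hdr += now.strftime("%H.%M.%S").encode().ljust(8)
    hdr += str(256 * (n_sig + 1)).encode().ljust(8)
    hdr += b"EDF+C".ljust(44)
    hdr += str(n_rec).encode().ljust(8)
    hdr += b"1".ljust(8)  # record duration, s
    hdr += str(n_sig).encode().ljust(4)  # ns field is 4 ascii chars

    labels = [n[:16] for n in rec.channel_names] + ["EDF Annotations"]
    fields: list[tuple[str, list[str]]] = [
        ("label", [l.ljust(16) for l in labels]),
        ("transducer", [" " * 80] * n_sig),
        ("dimension", ["uV".ljust(8)] * rec.n_channels + [" " * 8]),
        ("phys_min", [f"{-phys_range:g}".ljust(8)] * rec.n_channels + ["-1".ljust(8)]),
        ("phys_max", [f"{phys_range:g}".ljust(8)] * rec.n_channels + ["1".ljust(8)]),
        ("dig_min", [str(_EDF_DIG_MIN).ljust(8)] * rec.n_channels + ["-32768".ljust(8)]),
        ("dig_max", [str(_EDF_DIG_MAX).ljust(8)] * rec.n_channels + ["32767".ljust(8)]),
        ("prefilter", [" " * 80] * n_sig),
        ("n_samples", [str(spr).ljust(8)] * rec.n_channels + [str(ann_len // 2).ljust(8)]),
        ("reserved", [" " * 32] * n_sig),
    ]
    for _, vals in fields:
        hdr += "".join(vals).encode("ascii")

    with open(edf_path, "wb") as fh:
        fh.write(hdr)
        for r in range(n_rec):
            fh.write(digital[:, r * spr : (r + 1) * spr].tobytes())
            fh.write(anns[r])

    ev_path = None
    if events_path is not None:
        ev_path = write_events(
            rec.events if rec.events is not None else EventSequence([], []),
            events_path,
        )
    return edf_path, ev_path


def read_recording(
    edf_path: str | Path,
    events_path: str | Path | None = None,
    montage: Montage | None = None,
) -> Recording:
    """Read an EDF(+) file (via MNE) and its sidecar events TSV."""
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(str(edf_path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # V -> µV
    names = list(raw.ch_names)
    if montage is not None:
        if set(montage.channel_names) != set(names):
            raise FormatError(
                "EDF channel set does not match the supplied montage"
            )
        order = [names.index(n) for n in montage.channel_names]
        data = data[order]
        names = list(montage.channel_names)
    events = read_events(events_path) if events_path is not None else None
    return Recording(
        data=data,
        fs=float(raw.info["sfreq"]),
        channel_names=names,
        events=events,
    )
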