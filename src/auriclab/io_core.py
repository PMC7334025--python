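"""Domain types, file I/O and configuration for auricular-EMG attention analyses.

The package works on multichannel surface-EMG/EOG recordings made while
listeners attend lateralized sounds (exogenous novel-sound sessions and
endogenous dichotic-listening runs).  Continuous signals travel as
:class:`Recording` objects (µV, time x channel), stimulus/condition metadata
as :class:`EventTable` (BIDS-events-like TSV: onset/duration in seconds,
0-referenced to recording start), and every tunable of the analysis chain
lives in :class:`AnalysisConfig`.

On disk, recordings are either plain text TSV (exact at the written decimal
precision) or 16-bit EDF.  EDF files are written by a small built-in writer
and read back through MNE's EDF reader, so write/read round trips are checked
against an independent implementation of the format.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, fields, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("auriclab")

VALID_AZIMUTHS = (-120, -30, 30, 120)


def configure_logging(verbose: bool = False) -> None:
    """Route package logging to stderr; DEBUG level when *verbose*."""
    handler = logging.StreamHandler()
    handler.setFormatter(logging.Formatter("%(name)s %(levelname)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.DEBUG if verbose else logging.INFO)


# ---------------------------------------------------------------------------
# errors
# ---------------------------------------------------------------------------

class AuriclabError(Exception):
    """Base class for all package errors."""


class FormatError(AuriclabError):
    """File does not parse under the named dialect."""


class DataError(AuriclabError):
    """Parsed data violates a Recording invariant (e.g. non-finite samples)."""


class LabeledChannelError(AuriclabError):
    """Channel label does not map onto the known muscle vocabulary."""


class ValidationError(AuriclabError):
    """Event table or condition table violates a design invariant."""


class ConfigError(AuriclabError):
    """Analysis/simulation configuration is not realizable."""


class DesignError(AuriclabError):
    """Incomplete or unbalanced experimental design."""


# ---------------------------------------------------------------------------
# channels
# ---------------------------------------------------------------------------

class Muscle(str, Enum):
    PAM = "PAM"            # postauricular
    AAM = "AAM"            # anterior auricular
    SAM = "SAM"            # superior auricular
    TAM = "TAM"            # transverse auricular
    SCM = "SCM"            # sternocleidomastoid (neck control)
    FRONTALIS = "FRONTALIS"
    ZYGOMATICUS = "ZYGOMATICUS"
    EOG_H = "EOG_H"        # horizontal electrooculogram


class Side(str, Enum):
    LEFT = "left"
    RIGHT = "right"
    MIDLINE = "midline"


class Role(str, Enum):
    AURICULAR_EMG = "auricular_emg"
    NECK_EMG = "neck_emg"
    FACIAL_EMG = "facial_emg"
    EOG = "eog"


AURICULAR_MUSCLES = (Muscle.PAM, Muscle.AAM, Muscle.SAM, Muscle.TAM)

_ROLE_OF = {
    Muscle.PAM: Role.AURICULAR_EMG,
    Muscle.AAM: Role.AURICULAR_EMG,
    Muscle.SAM: Role.AURICULAR_EMG,
    Muscle.TAM: Role.AURICULAR_EMG,
    Muscle.SCM: Role.NECK_EMG,
    Muscle.FRONTALIS: Role.FACIAL_EMG,
    Muscle.ZYGOMATICUS: Role.FACIAL_EMG,
    Muscle.EOG_H: Role.EOG,
}

_SIDE_SUFFIX = {"L": Side.LEFT, "R": Side.RIGHT, "M": Side.MIDLINE}
_SUFFIX_OF = {Side.LEFT: "L", Side.RIGHT: "R", Side.MIDLINE: "M"}


@dataclass(frozen=True)
class ChannelInfo:
    """Identity and provenance of one recorded channel."""

    muscle: Muscle
    side: Side
    processing: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.role is Role.AURICULAR_EMG and self.side is Side.MIDLINE:
            raise LabeledChannelError(
                f"auricular muscle {self.muscle.value} must be left or right"
            )

    @property
    def role(self) -> Role:
        return _ROLE_OF[self.muscle]

    @property
    def label(self) -> str:
        if self.side is Side.MIDLINE:
            return self.muscle.value
        return f"{self.muscle.value}_{_SUFFIX_OF[self.side]}"

    def with_processing(self, *steps: str) -> "ChannelInfo":
        return replace(self, processing=self.processing + steps)


def parse_channel_label(label: str) -> ChannelInfo:
    """Map a ``MUSCLE_SIDE`` label (e.g. ``PAM_L``, ``EOG_H``) to ChannelInfo."""
    label = label.strip()
    head, sep, tail = label.rpartition("_")
    if sep and tail in _SIDE_SUFFIX and head in Muscle.__members__:
        return ChannelInfo(Muscle[head], _SIDE_SUFFIX[tail])
    if label in Muscle.__members__:
        muscle = Muscle[label]
        if _ROLE_OF[muscle] is Role.AURICULAR_EMG:
            raise LabeledChannelError(
                f"auricular channel label {label!r} lacks a side suffix"
            )
        return ChannelInfo(muscle, Side.MIDLINE)
    raise LabeledChannelError(f"unknown channel label {label!r}")


# ---------------------------------------------------------------------------
# Recording
# ---------------------------------------------------------------------------

@dataclass
class Recording:
    """Continuous multichannel recording, voltages in µV, shape (samples, channels)."""

    data: np.ndarray
    fs: float
    channels: list[ChannelInfo]
    subject_id: str = ""
    session: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise DataError("recording data must be 2-D (samples x channels)")
        if self.fs <= 0:
            raise DataError(f"sampling rate must be positive, got {self.fs}")
        if self.data.shape[1] != len(self.channels):
            raise DataError(
                f"{self.data.shape[1]} data columns but {len(self.channels)} channels"
            )
        labels = [c.label for c in self.channels]
        if len(set(labels)) != len(labels):
            raise DataError(f"duplicate channel labels in {labels}")
        if not np.all(np.isfinite(self.data)):
            raise DataError("recording contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.channels]

    def channel(self, label: str) -> np.ndarray:
        """1-D signal of the channel with the given label."""
        try:
            idx = self.labels.index(label)
        except ValueError:
            raise LabeledChannelError(f"no channel {label!r} in {self.labels}") from None
        return self.data[:, idx]

    def pick(self, role: Role | None = None, muscle: Muscle | None = None) -> "Recording":
        """Sub-recording restricted to channels of one role and/or muscle."""
        keep = [
            i
            for i, c in enumerate(self.channels)
            if (role is None or c.role is role) and (muscle is None or c.muscle is muscle)
        ]
        return Recording(
            self.data[:, keep],
            self.fs,
            [self.channels[i] for i in keep],
            self.subject_id,
            self.session,
        )


# ---------------------------------------------------------------------------
# EventTable
# ---------------------------------------------------------------------------

EVENT_COLUMNS = [
    "onset",
    "duration",
    "speaker_azimuth",
    "stimulus_type",
    "attended_azimuth",
    "experiment",
]


@dataclass
class EventTable:
    """Stimulus/condition annotations; onsets in seconds from recording start.

    Exogenous rows carry a ``stimulus_type`` (one of the nine novel sounds)
    and no ``attended_azimuth``; endogenous rows carry an ``attended_azimuth``
    (the speaker the listener was told to follow) and no ``stimulus_type``.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.copy()
        missing = [c for c in EVENT_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"event table missing columns {missing}")
        df = df[EVENT_COLUMNS].reset_index(drop=True)
        if len(df):
            onsets = df["onset"].to_numpy(float)
            if np.any(~np.isfinite(onsets)) or np.any(np.diff(onsets) <= 0):
                raise ValidationError("event onsets must be finite and strictly increasing")
            if np.any(df["duration"].to_numpy(float) <= 0):
                raise ValidationError("event durations must be > 0")
            for col in ("speaker_azimuth", "attended_azimuth"):
                vals = df[col].dropna()
                bad = set(vals) - set(VALID_AZIMUTHS)
                if bad:
                    raise ValidationError(
                        f"{col} outside {VALID_AZIMUTHS}: {sorted(bad)}"
                    )
            exo = df["experiment"] == "exogenous"
            endo = df["experiment"] == "endogenous"
            if not (exo | endo).all():
                raise ValidationError("experiment must be 'exogenous' or 'endogenous'")
            if exo.any():
                sub = df[exo]
                if sub["stimulus_type"].isna().any() or sub["attended_azimuth"].notna().any():
                    raise ValidationError(
                        "exogenous events need stimulus_type and no attended_azimuth"
                    )
            if endo.any():
                sub = df[endo]
                if sub["attended_azimuth"].isna().any() or sub["stimulus_type"].notna().any():
                    raise ValidationError(
                        "endogenous events need attended_azimuth and no stimulus_type"
                    )
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        return (row for _, row in self.df.iterrows())

    @staticmethod
    def from_rows(rows: Iterable[dict]) -> "EventTable":
        df = pd.DataFrame(list(rows))
        for col in EVENT_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
        return EventTable(df)


def read_events(path: str | Path) -> EventTable:
    """Read a tab-separated event table (``n/a`` marks missing values)."""
    df = pd.read_csv(path, sep="\t", na_values=["n/a"], keep_default_na=True)
    if df.empty and not set(EVENT_COLUMNS) <= set(df.columns):
        df = pd.DataFrame(columns=EVENT_COLUMNS)
    return EventTable(df)


def write_events(events: EventTable, path: str | Path) -> None:
    events.df.to_csv(path, sep="\t", index=False, na_rep="n/a")


# ---------------------------------------------------------------------------
# AnalysisConfig
# ---------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    """All tunables of the analysis chain.

    Defaults reproduce the published processing: 9600 Hz acquisition,
    10–1000 Hz FIR(2000) for auricular EMG plus a 50 Hz notch (IIR, 2nd
    order), 60–1000 Hz FIR(2000) for the sternocleidomastoid, 0.01–20 Hz
    IIR(2) for the horizontal EOG, decimation to 2400 Hz, a 150-sample
    (62.5 ms) sliding RMS window with 1-sample step, epochs from 3 s before
    onset to 3 s after stimulus offset, a 100–1500 ms measurement window and
    a 50–300 ms phasic window, 1-s energy segments with a 2 SD artifact
    criterion, 10-s time-resolved segments, and an 8-level db5 octave
    filter bank.
    """

    raw_fs: float = 9600.0
    emg_band: tuple[float, float] = (10.0, 1000.0)
    emg_fir_order: int = 2000
    scm_band: tuple[float, float] = (60.0, 1000.0)
    scm_fir_order: int = 2000
    eog_band: tuple[float, float] = (0.01, 20.0)
    eog_iir_order: int = 2
    notch_hz: float = 50.0
    notch_order: int = 2
    notch_q: float = 30.0
    decim_factor: int = 4
    rms_window: int = 150
    rms_step: int = 1
    rms_align: str = "causal"  # or "center"
    epoch_pre: float = 3.0
    epoch_post: float = 3.0
    measure_window_ms: tuple[float, float] = (100.0, 1500.0)
    phasic_window_ms: tuple[float, float] = (50.0, 300.0)
    energy_segment_s: float = 1.0
    artifact_k: float = 2.0
    timecourse_segment_s: float = 10.0
    subband_levels: int = 8
    wavelet_name: str = "db5"
    norm_mode: str = "signed"  # or "abs": use |value| for the normalization max
    run_norm: str = "max_condition"  # or "max_segment"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for band in (self.emg_band, self.scm_band, self.eog_band):
            lo, hi = band
            if not (0 < lo < hi):
                raise ConfigError(f"bad band edges {band}")
        if self.decim_factor < 1 or int(self.decim_factor) != self.decim_factor:
            raise ConfigError(f"decimation factor must be a positive integer")
        if self.rms_window < 1 or self.rms_step < 1:
            raise ConfigError("rms window and step must be >= 1")
        if self.rms_align not in ("causal", "center"):
            raise ConfigError(f"unknown rms alignment {self.rms_align!r}")

    @property
    def processed_fs(self) -> float:
        return self.raw_fs / self.decim_factor

    @property
    def rms_window_ms(self) -> float:
        return 1000.0 * self.rms_window / self.processed_fs

    @classmethod
    def scaled_to(cls, raw_fs: float, decim_factor: int = 2, **overrides) -> "AnalysisConfig":
        """Config with filter orders, band edges and RMS window rescaled to *raw_fs*.

        Used for reduced-scale simulation studies: transition widths relative
        to the sampling rate, and the RMS window duration (62.5 ms), are kept
        fixed while the absolute sample counts shrink.
        """
        ratio = raw_fs / 9600.0
        fs_proc = raw_fs / decim_factor
        hi = min(1000.0, 0.44 * fs_proc)
        scm_lo = min(60.0, 0.3 * hi)
        defaults = dict(
            raw_fs=raw_fs,
            emg_band=(10.0, hi),
            emg_fir_order=max(64, 2 * round(1000 * ratio)),
            scm_band=(scm_lo, hi),
            scm_fir_order=max(64, 2 * round(1000 * ratio)),
            decim_factor=decim_factor,
            rms_window=max(4, round(0.0625 * fs_proc)),
        )
        defaults.update(overrides)
        return cls(**defaults)

    def to_yaml(self, path: str | Path | None = None) -> str:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}
        text = yaml.safe_dump(d, sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "AnalysisConfig":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = yaml.safe_load(text) or {}
        tuple_fields = {
            f.name for f in fields(cls) if "tuple" in str(f.type)
        }
        for k in list(d):
            if k in tuple_fields and isinstance(d[k], list):
                d[k] = tuple(d[k])
        return cls(**d)


# ---------------------------------------------------------------------------
# recording I/O — TSV dialect
# ---------------------------------------------------------------------------

_TSV_MAGIC = "# auriclab-recording v1"
TSV_DECIMALS = 6


def _write_recording_tsv(rec: Recording, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(_TSV_MAGIC + "\n")
        fh.write(f"# subject_id = {rec.subject_id}\n")
        fh.write(f"# session = {rec.session}\n")
        fh.write(f"# fs = {rec.fs!r}\n")
        fh.write("\t".join(rec.labels) + "\n")
        np.savetxt(fh, rec.data, fmt=f"%.{TSV_DECIMALS}f", delimiter="\t")


def _read_recording_tsv(path: Path) -> Recording:
    meta: dict[str, str] = {}
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if first != _TSV_MAGIC:
            raise FormatError(f"{path}: not an auriclab recording TSV")
        pos = fh.tell()
        while True:
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            key, _, val = line[1:].partition("=")
            meta[key.strip()] = val.strip()
            pos = fh.tell()
        header = fh.readline().rstrip("\n").split("\t")
        try:
            data = np.loadtxt(fh, delimiter="\t", ndmin=2)
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    if data.size == 0:
        data = data.reshape(0, len(header))
    channels = [parse_channel_label(lbl) for lbl in header]
    try:
        fs = float(meta["fs"])
    except (KeyError, ValueError) as exc:
        raise FormatError(f"{path}: missing or bad fs header") from exc
    return Recording(data, fs, channels, meta.get("subject_id", ""), meta.get("session", ""))


# ---------------------------------------------------------------------------
# recording I/O — EDF dialect
# ---------------------------------------------------------------------------

def _edf_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        # shorten numerics rather than truncate arbitrarily
        if isinstance(value, float):
            s = f"{value:.{max(0, width - 8)}e}"
        s = s[:width]
    return s.ljust(width).encode("ascii")


def _write_recording_edf(rec: Recording, path: Path) -> None:
    """Write a plain continuous 16-bit EDF file (physical dimension uV).

    Data records are 1 s long; the final record is zero-padded when the
    recording is not a whole number of seconds (a warning is logged).
    """
    fs = rec.fs
    if fs != int(fs):
        raise FormatError("EDF writer requires an integer sampling rate")
    spr = int(fs)  # samples per 1-s record, per channel
    nchan = len(rec.channels)
    n = rec.n_samples
    n_rec = math.ceil(n / spr) if n else 0
    pad = n_rec * spr - n
    if pad:
        logger.warning("EDF write: padding final record with %d zero samples", pad)
    data = np.vstack([rec.data, np.zeros((pad, nchan))]) if pad else rec.data

    pmin = data.min(axis=0)
    pmax = data.max(axis=0)
    flat = pmax - pmin <= 0
    pmin = np.where(flat, pmin - 1.0, pmin)
    pmax = np.where(flat, pmax + 1.0, pmax)
    dmin, dmax = -32768, 32767
    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.round((data - pmin) * scale + dmin).astype("<i2")

    header = io.BytesIO()
    header.write(_edf_field("0", 8))
    header.write(_edf_field(f"X X X {rec.subject_id or 'X'}", 80))
    header.write(_edf_field(f"Startdate 01-JAN-2000 X X {rec.session or 'X'}", 80))
    header.write(_edf_field("01.01.00", 8))
    header.write(_edf_field("00.00.00", 8))
    header.write(_edf_field(256 * (1 + nchan), 8))
    header.write(_edf_field("", 44))
    header.write(_edf_field(n_rec, 8))
    header.write(_edf_field(1, 8))
    header.write(_edf_field(nchan, 4))

    def sig_fields(values: Sequence, width: int) -> bytes:
        return b"".join(_edf_field(v, width) for v in values)

    labels = rec.labels
    header.write(sig_fields(labels, 16))
    header.write(sig_fields(["" for _ in labels], 80))           # transducer
    header.write(sig_fields(["uV" for _ in labels], 8))          # physical dim
    header.write(sig_fields([f"{v:.6g}" for v in pmin], 8))
    header.write(sig_fields([f"{v:.6g}" for v in pmax], 8))
    header.write(sig_fields([dmin for _ in labels], 8))
    header.write(sig_fields([dmax for _ in labels], 8))
    header.write(sig_fields(["" for _ in labels], 80))           # prefilter
    header.write(sig_fields([spr for _ in labels], 8))
    header.write(sig_fields(["" for _ in labels], 32))           # reserved

    with open(path, "wb") as fh:
        fh.write(header.getvalue())
        for r in range(n_rec):
            block = digital[r * spr : (r + 1) * spr]  # (spr, nchan)
            fh.write(block.T.tobytes())


def _read_recording_edf(path: Path) -> Recording:
    import mne

    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # mne raises assorted types on malformed files
        raise FormatError(f"{path}: {exc}") from exc
    fs = float(raw.info["sfreq"])
    data = raw.get_data().T * 1e6  # MNE returns volts
    channels = [parse_channel_label(name) for name in raw.ch_names]
    if not np.all(np.isfinite(data)):
        raise DataError(f"{path}: non-finite samples after EDF ingest")
    # recover the subject/session tokens this package's writer stores in the
    # local patient/recording identification fields
    with open(path, "rb") as fh:
        header = fh.read(248)
    patient = header[8:88].decode("ascii", "replace").split()
    recording = header[88:168].decode("ascii", "replace").split()
    subject = patient[3] if len(patient) >= 4 and patient[3] != "X" else ""
    session = recording[4] if len(recording) >= 5 and recording[4] != "X" else ""
    return Recording(data, fs, channels, subject, session)


# ---------------------------------------------------------------------------
# public recording I/O
# ---------------------------------------------------------------------------

def write_recording(rec: Recording, path: str | Path, dialect: str = "tsv") -> None:
    """Write *rec* to *path* as ``tsv`` (text) or ``edf`` (16-bit binary)."""
    path = Path(path)
    if dialect == "tsv":
        _write_recording_tsv(rec, path)
    elif dialect == "edf":
        _write_recording_edf(rec, path)
    else:
        raise FormatError(f"unknown recording dialect {dialect!r}")


def read_recording(path: str | Path, dialect: str = "tsv") -> Recording:
    """Read a recording; channel labels must map onto the muscle vocabulary."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv":
        return _read_recording_tsv(path)
    if dialect == "edf":
        return _read_recording_edf(path)
    raise FormatError(f"unknown recording dialect {dialect!r}")
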