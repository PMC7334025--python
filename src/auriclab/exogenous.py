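"""Event-related analysis of the novel-sound (exogenous attention) experiment.

The filtered, downsampled auricular EMG is reduced to a sliding-window RMS
envelope (150 samples / 62.5 ms at 2400 Hz, step 1), segmented into epochs
from 3 s before stimulus onset to 3 s after stimulus offset, baseline
corrected against the pre-stimulus mean, normalized per muscle and stimulus
type by the largest voltage across the four repetitions of that stimulus,
and pooled into ipsi-/contralateral x front/back condition waveforms (18
trials per cell under the full 9-stimulus x 4-speaker design).  Mean
amplitudes over 100–1500 ms (and a 50–300 ms phasic window) feed the mixed
repeated-measures ANOVA in :mod:`auriclab.stats`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_core import (
    AnalysisConfig,
    ChannelInfo,
    DataError,
    DesignError,
    EventTable,
    Muscle,
    Recording,
    Role,
    Side,
    logger,
)

__all__ = [
    "Envelope",
    "Epoch",
    "EpochSet",
    "ConditionAverages",
    "rms_envelope",
    "segment_epochs",
    "baseline_correct",
    "normalize_by_stimulus_type",
    "pool_laterality",
    "mean_amplitude",
    "estimate_onset_latency",
    "exogenous_epochs",
    "subject_condition_measures",
]


# ---------------------------------------------------------------------------
# RMS envelope
# ---------------------------------------------------------------------------

@dataclass
class Envelope:
    """Sliding-window RMS amplitude of one channel (non-negative, µV)."""

    values: np.ndarray
    fs: float
    channel: ChannelInfo | None = None


def rms_envelope(
    x: np.ndarray,
    window: int,
    step: int = 1,
    fs: float = 1.0,
    align: str = "causal",
    channel: ChannelInfo | None = None,
) -> Envelope:
    """Sliding root-mean-square with the given window/step (samples).

    ``align='causal'`` places the window trailing each output sample
    (value at n summarizes samples ``(n-window, n]``), so a burst cannot
    raise the envelope before its own onset; ``'center'`` centers the
    window on the output sample.  Windows are clipped at the signal edges
    (the mean runs over the available samples only).
    """
    x = np.asarray(x, dtype=np.float64)
    n = x.size
    if window < 1 or step < 1:
        raise DataError("window and step must be >= 1")
    if n < window:
        raise DataError(f"signal length {n} shorter than window {window}")
    css = np.concatenate([[0.0], np.cumsum(x * x)])
    pos = np.arange(0, n, step)
    if align == "causal":
        hi = pos + 1
        lo = np.maximum(hi - window, 0)
    elif align == "center":
        left = window // 2
        lo = np.maximum(pos - left, 0)
        hi = np.minimum(pos - left + window, n)
    else:
        raise DataError(f"unknown rms alignment {align!r}")
    counts = hi - lo
    vals = np.sqrt((css[hi] - css[lo]) / counts)
    return Envelope(vals, fs / step, channel)


# ---------------------------------------------------------------------------
# epochs
# ---------------------------------------------------------------------------

@dataclass
class Epoch:
    """One onset-aligned envelope segment with its condition labels."""

    values: np.ndarray
    fs: float
    onset_index: int          # index of stimulus onset (t = 0) within values
    stim_type: str
    speaker_azimuth: float
    channel: ChannelInfo
    baseline_mean: float = np.nan
    norm_factor: float = np.nan

    @property
    def correspondence(self) -> str:
        ipsi = (self.channel.side is Side.LEFT) == (self.speaker_azimuth < 0)
        return "ipsi" if ipsi else "contra"

    @property
    def anteriority(self) -> str:
        return "front" if abs(self.speaker_azimuth) == 30 else "back"


@dataclass
class EpochSet:
    """Per-trial epochs of one subject (possibly many channels)."""

    epochs: list[Epoch]
    n_dropped: int = 0

    def __len__(self) -> int:
        return len(self.epochs)

    def __iter__(self):
        return iter(self.epochs)


def segment_epochs(env: Envelope, events: EventTable, cfg: AnalysisConfig) -> EpochSet:
    """Cut one channel's envelope into [-epoch_pre, duration + epoch_post) epochs.

    Events whose window falls outside the recording are dropped with a logged
    warning; the drop count is reported on the EpochSet.
    """
    fs = env.fs
    n = env.values.size
    epochs: list[Epoch] = []
    dropped = 0
    for ev in events:
        if ev["experiment"] != "exogenous":
            continue
        start = int(round((ev["onset"] - cfg.epoch_pre) * fs))
        stop = int(round((ev["onset"] + ev["duration"] + cfg.epoch_post) * fs))
        if start < 0 or stop > n:
            dropped += 1
            logger.warning(
                "dropping event at %.3f s: epoch [%d, %d) outside record of %d samples",
                ev["onset"], start, stop, n,
            )
            continue
        onset_index = int(round(ev["onset"] * fs)) - start
        epochs.append(
            Epoch(
                values=env.values[start:stop].copy(),
                fs=fs,
                onset_index=onset_index,
                stim_type=str(ev["stimulus_type"]),
                speaker_azimuth=float(ev["speaker_azimuth"]),
                channel=env.channel,
            )
        )
    return EpochSet(epochs, n_dropped=dropped)


def baseline_correct(epoch: Epoch) -> Epoch:
    """Subtract the mean envelope amplitude of the pre-stimulus interval."""
    if epoch.onset_index < 1:
        raise DataError("epoch has an empty pre-stimulus interval")
    base = float(np.mean(epoch.values[: epoch.onset_index]))
    epoch.values = epoch.values - base
    epoch.baseline_mean = base
    return epoch


def normalize_by_stimulus_type(epochs: EpochSet, mode: str = "signed") -> EpochSet:
    """Scale each (muscle channel, stimulus type) group of four epochs.

    The normalization reference is the largest voltage at any time point
    within the four baseline-corrected epochs of that muscle and stimulus
    type (``mode='abs'`` uses the largest absolute voltage instead); after
    division the maximum normalized value within each group is exactly 1.
    """
    groups: dict[tuple[str, str], list[Epoch]] = {}
    for ep in epochs:
        groups.setdefault((ep.channel.label, ep.stim_type), []).append(ep)
    bad = {k: len(v) for k, v in groups.items() if len(v) != 4}
    if bad:
        raise DesignError(f"groups without exactly 4 epochs: {bad}")
    for key, group in groups.items():
        if mode == "abs":
            ref = max(float(np.max(np.abs(ep.values))) for ep in group)
        else:
            ref = max(float(np.max(ep.values)) for ep in group)
        if not ref > 0:
            raise DesignError(f"non-positive normalization reference for group {key}")
        for ep in group:
            ep.values = ep.values / ref
            ep.norm_factor = ref
    return epochs


# ---------------------------------------------------------------------------
# laterality pooling and condition measures
# ---------------------------------------------------------------------------

@dataclass
class ConditionAverages:
    """Per-muscle ipsi/contra x front/back averaged waveforms and amplitude measures."""

    waveforms: dict[tuple[Muscle, str, str], np.ndarray]
    n_trials: dict[tuple[Muscle, str, str], int]
    fs: float
    onset_index: int
    trial_measures: dict[tuple[Muscle, str, str], np.ndarray] = field(default_factory=dict)

    def cells(self):
        return sorted(self.waveforms, key=lambda k: (k[0].value, k[1], k[2]))


def pool_laterality(epochs: EpochSet, require_full: bool = True) -> ConditionAverages:
    """Average epochs into ipsi/contra x front/back cells per muscle.

    Left/right channels are collapsed: an epoch is ipsilateral when the
    recorded muscle and the speaker lie on the same side.  Cells average
    over trials after truncating to the shortest epoch in the cell (epochs
    share the pre-stimulus span, so onset alignment is preserved).  Under
    the full 9-stimulus x 4-speaker design every cell holds 18 trials.
    """
    cells: dict[tuple[Muscle, str, str], list[Epoch]] = {}
    for ep in epochs:
        if ep.channel.role is not Role.AURICULAR_EMG:
            continue
        cells.setdefault((ep.channel.muscle, ep.correspondence, ep.anteriority), []).append(ep)
    if require_full:
        muscles = {m for m, _, _ in cells}
        missing = [
            (m.value, c, a)
            for m in muscles
            for c in ("ipsi", "contra")
            for a in ("front", "back")
            if (m, c, a) not in cells
        ]
        if missing:
            raise DesignError(f"empty condition cells: {missing}")
    waveforms, counts = {}, {}
    onset_index = None
    fs = None
    for key, eps in cells.items():
        onset_index = eps[0].onset_index
        fs = eps[0].fs
        if any(e.onset_index != onset_index for e in eps):
            raise DesignError("epochs in one cell have different pre-stimulus spans")
        length = min(e.values.size for e in eps)
        stack = np.vstack([e.values[:length] for e in eps])
        waveforms[key] = stack.mean(axis=0)
        counts[key] = len(eps)
    return ConditionAverages(waveforms, counts, fs, onset_index)


def mean_amplitude(
    avg: ConditionAverages, window_ms: tuple[float, float]
) -> dict[tuple[Muscle, str, str], float]:
    """Arithmetic mean of each cell waveform over [start, stop) ms post onset."""
    out = {}
    for key, wf in avg.waveforms.items():
        lo, hi = _window_slice(wf, avg.fs, avg.onset_index, window_ms)
        out[key] = float(np.mean(wf[lo:hi]))
    return out


def _window_slice(wf: np.ndarray, fs: float, onset: int, window_ms) -> tuple[int, int]:
    lo = onset + int(round(window_ms[0] / 1000.0 * fs))
    hi = onset + int(round(window_ms[1] / 1000.0 * fs))
    if lo < 0 or hi > wf.size or hi <= lo:
        raise DataError(
            f"measurement window {window_ms} ms outside waveform of {wf.size} samples"
        )
    return lo, hi


def phasic_trial_measures(
    epochs: EpochSet, window_ms: tuple[float, float]
) -> dict[tuple[Muscle, str, str], np.ndarray]:
    """Per-trial mean amplitudes within the (50–300 ms) phasic window, by cell."""
    out: dict[tuple[Muscle, str, str], list[float]] = {}
    for ep in epochs:
        if ep.channel.role is not Role.AURICULAR_EMG:
            continue
        lo, hi = _window_slice(ep.values, ep.fs, ep.onset_index, window_ms)
        key = (ep.channel.muscle, ep.correspondence, ep.anteriority)
        out.setdefault(key, []).append(float(np.mean(ep.values[lo:hi])))
    return {k: np.asarray(v) for k, v in out.items()}


def estimate_onset_latency(
    waveform: np.ndarray,
    fs: float,
    onset_index: int,
    persist_ms: float = 10.0,
    k: float = 3.0,
) -> float | None:
    """First post-stimulus time (ms) the waveform exceeds baseline mean + k·SD
    and stays above for at least *persist_ms*; ``None`` if it never does.

    Baseline statistics come from the pre-stimulus interval of the same
    (grand-average) waveform.
    """
    if onset_index < int(0.5 * fs):
        raise DataError("need >= 500 ms of pre-stimulus baseline")
    base = waveform[:onset_index]
    mu, sd = float(np.mean(base)), float(np.std(base))
    if sd == 0:
        raise DataError("zero-variance baseline; onset threshold undefined")
    thresh = mu + k * sd
    above = waveform[onset_index:] > thresh
    need = max(1, int(round(persist_ms / 1000.0 * fs)))
    run = 0
    for i, a in enumerate(above):
        run = run + 1 if a else 0
        if run >= need:
            return (i - need + 1) / fs * 1000.0
    return None


# ---------------------------------------------------------------------------
# per-subject pipeline
# ---------------------------------------------------------------------------

def exogenous_epochs(rec: Recording, events: EventTable, cfg: AnalysisConfig) -> EpochSet:
    """Envelope -> epochs -> baseline correction -> normalization, all auricular channels."""
    all_epochs: list[Epoch] = []
    dropped = 0
    for i, ch in enumerate(rec.channels):
        if ch.role is not Role.AURICULAR_EMG:
            continue
        env = rms_envelope(
            rec.data[:, i], cfg.rms_window, cfg.rms_step, rec.fs, cfg.rms_align, ch
        )
        es = segment_epochs(env, events, cfg)
        dropped += es.n_dropped
        for ep in es:
            baseline_correct(ep)
        all_epochs.extend(es.epochs)
    out = EpochSet(all_epochs, n_dropped=dropped)
    return normalize_by_stimulus_type(out, cfg.norm_mode)


def subject_condition_measures(
    rec: Recording, events: EventTable, cfg: AnalysisConfig
) -> pd.DataFrame:
    """Full per-subject exogenous analysis -> tidy cell-measure table.

    Columns: muscle, correspondence, anteriority, mean_amp (100–1500 ms),
    phasic_mean, phasic_sd (50–300 ms, across trials), n_trials.
    """
    epochs = exogenous_epochs(rec, events, cfg)
    avg = pool_laterality(epochs)
    amp = mean_amplitude(avg, cfg.measure_window_ms)
    phasic = phasic_trial_measures(epochs, cfg.phasic_window_ms)
    rows = []
    for key in avg.cells():
        m, corr, ant = key
        ph = phasic.get(key, np.array([]))
        rows.append(
            dict(
                muscle=m.value,
                correspondence=corr,
                anteriority=ant,
                mean_amp=amp[key],
                phasic_mean=float(ph.mean()) if ph.size else np.nan,
                phasic_sd=float(ph.std(ddof=1)) if ph.size > 1 else np.nan,
                n_trials=avg.n_trials[key],
            )
        )
    df = pd.DataFrame(rows)
    df.insert(0, "subject", rec.subject_id)
    return df
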