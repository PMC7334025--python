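"""Synthetic cohorts of auricular-EMG/EOG recordings with known ground truth.

Surface EMG is modeled as amplitude-modulated band-limited Gaussian noise
(the convolution-model view of the interference EMG): each channel carries
an independent 20–500 Hz carrier whose instantaneous amplitude is the
resting noise floor scaled by 1 + modulation.  In exogenous sessions the
modulation is a per-event burst envelope — onset latency 70 ms after
stimulus onset, raised-cosine rise, plateau for the stimulus duration,
raised-cosine decay — whose gain depends on the (muscle, ipsi/contra,
front/back) cell; in endogenous runs it is a sustained tonic level per
condition (optionally declining over the run for the postauricular
muscle).  50 Hz line interference, wideband sensor noise, sporadic
high-energy artifact bursts, and a horizontal EOG built from fixations,
reading-like saccades and 1° resolution noise complete the model.

Default parameters follow the study design this package analyzes: nine
novel-sound stimulus types x four speakers (±30°, ±120°), durations
1.7–10 s, onsets every 15–40 s, four 5-min listening runs, 16 young + 12
old subjects (exogenous) and 10 + 11 (endogenous).  Every simulation is
deterministic given its seed, and each returned GroundTruth records the
injected per-event amplitudes, artifact segments and saccades for
parameter-recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io_core import (
    AnalysisConfig,
    ChannelInfo,
    ConfigError,
    EventTable,
    Muscle,
    Recording,
    Side,
    write_events,
    write_recording,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_exogenous_session",
    "simulate_endogenous_run",
    "simulate_cohort",
    "iter_exogenous_cohort",
    "iter_endogenous_cohort",
    "simulate_gaze",
    "null_sim",
    "reduced_sim",
    "reduced_analysis",
]

STIMULUS_NAMES = (
    "lemur_howling", "dog_barking", "helicopter", "cellphone_vibrating",
    "birds_singing", "baby_crying", "mosquito", "footsteps", "traffic_jam",
)
SPEAKERS = (-120, -30, 30, 120)


@dataclass
class SimulationConfig:
    """All generator parameters (amplitudes in µV, times in s unless noted)."""

    # cohort
    n_young: int = 16
    n_old: int = 12
    n_young_endo: int = 10
    n_old_endo: int = 11
    fs: float = 9600.0
    # exogenous session design
    n_stimulus_types: int = 9
    stimulus_duration_s: tuple[float, float] = (1.7, 10.0)
    isi_s: tuple[float, float] = (15.0, 40.0)  # onset-to-onset
    lead_in_s: float = 5.0
    tail_s: float = 5.0
    # stimulus-locked bursts
    burst_onset_ms: float = 70.0
    burst_rise_ms: float = 20.0
    burst_decay_ms: float = 200.0
    burst_gain: float = 1.0          # modulation depth of a contra/front burst
    trial_cv: float = 0.3            # lognormal trial-amplitude variability
    ipsi_contra_ratio: float = 2.0
    back_front_ratio: float = 1.5
    exo_lateralized: tuple[str, ...] = ("PAM", "AAM", "TAM")  # SAM stays flat
    # endogenous runs
    run_length_s: float = 300.0
    tonic_gain: float = 0.6          # modulation depth of a contra/front run
    tonic_ipsi_contra_ratio: float = 2.0
    tonic_back_front_ratio: float = 1.3
    endo_lateralized: tuple[str, ...] = ("PAM", "AAM", "SAM")  # TAM stays flat
    pam_decline: float = 0.3         # fractional tonic decline of PAM over a run
    run_cv: float = 0.2              # lognormal run-to-run tonic gain variability
    artifact_rate_per_min: float = 1.0
    artifact_duration_s: float = 0.3
    artifact_energy_factor: float = 10.0  # 1-s segment energy vs. clean segments
    # carrier / noise model
    carrier_band: tuple[float, float] = (20.0, 500.0)
    noise_floor_uv: float = 2.0      # resting EMG RMS
    sensor_noise_uv: float = 0.2
    line_amp_uv: float = 1.0
    line_hz: float = 50.0
    # EOG
    eog_gain_uv_per_deg: float = 10.0
    eog_offset_uv: float = 5.0
    saccade_rate_hz: float = 0.25
    saccade_amp_deg: tuple[float, float] = (2.0, 12.0)
    eog_noise_deg: float = 1.0
    # channel layout
    muscles: tuple[str, ...] = ("PAM", "AAM", "SAM", "TAM")
    include_controls: bool = True    # SCM, frontalis, zygomaticus (left) + EOG
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("stimulus_duration_s", "isi_s", "saccade_amp_deg", "carrier_band"):
            lo, hi = getattr(self, name)
            if not (0 < lo < hi):
                raise ConfigError(f"{name} must satisfy 0 < lo < hi, got {(lo, hi)}")
        if self.burst_onset_ms < 0:
            raise ConfigError("burst onset latency must be >= 0")
        for name in ("burst_gain", "tonic_gain", "ipsi_contra_ratio",
                     "back_front_ratio", "tonic_ipsi_contra_ratio",
                     "tonic_back_front_ratio"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.carrier_band[1] >= self.fs / 2:
            raise ConfigError("carrier band exceeds Nyquist")

    def exo_gain(self, muscle: str, correspondence: str, anteriority: str) -> float:
        g = self.burst_gain
        if muscle in self.exo_lateralized:
            if correspondence == "ipsi":
                g *= self.ipsi_contra_ratio
            if anteriority == "back":
                g *= self.back_front_ratio
        return g

    def endo_gain(self, muscle: str, correspondence: str, anteriority: str) -> float:
        g = self.tonic_gain
        if muscle in self.endo_lateralized and correspondence == "ipsi":
            g *= self.tonic_ipsi_contra_ratio
        if anteriority == "back":
            g *= self.tonic_back_front_ratio
        return g


def null_sim(base: SimulationConfig | None = None, **overrides) -> SimulationConfig:
    """A generator with all condition gains equal (no true lateralization)."""
    base = base if base is not None else SimulationConfig()
    return replace(
        base,
        ipsi_contra_ratio=1.0,
        back_front_ratio=1.0,
        tonic_ipsi_contra_ratio=1.0,
        tonic_back_front_ratio=1.0,
        **overrides,
    )


def reduced_sim(**overrides) -> SimulationConfig:
    """Reduced-scale preset for simulation studies (short sessions, 960 Hz,
    one muscle pair, no control channels or line interference)."""
    base = dict(
        fs=960.0,
        n_stimulus_types=1,
        stimulus_duration_s=(1.0, 1.5),
        isi_s=(4.5, 6.5),
        lead_in_s=3.5,
        tail_s=4.0,
        carrier_band=(20.0, 180.0),
        muscles=("PAM",),
        include_controls=False,
        line_amp_uv=0.0,
    )
    base.update(overrides)
    return SimulationConfig(**base)


def reduced_analysis(raw_fs: float = 960.0, decim: int = 2, **overrides) -> AnalysisConfig:
    """Analysis config matched to :func:`reduced_sim` (62.5 ms RMS window kept)."""
    return AnalysisConfig.scaled_to(raw_fs, decim, **overrides)


@dataclass
class GroundTruth:
    """What the generator injected, for parameter-recovery tests."""

    event_amplitudes: pd.DataFrame = field(default_factory=pd.DataFrame)
    artifact_segments: dict = field(default_factory=dict)  # label -> 1-s segment indices
    saccades: list = field(default_factory=list)           # (onset_s, amplitude_deg)
    gains: dict = field(default_factory=dict)
    condition: tuple | None = None


# ---------------------------------------------------------------------------
# signal building blocks
# ---------------------------------------------------------------------------

from functools import lru_cache


@lru_cache(maxsize=32)
def _carrier_sos(band: tuple[float, float], fs: float):
    return sps.butter(4, band, btype="bandpass", fs=fs, output="sos")


def _carrier(rng: np.random.Generator, n: int, fs: float, band) -> np.ndarray:
    """Unit-RMS band-limited Gaussian noise."""
    x = sps.sosfilt(_carrier_sos(tuple(band), fs), rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def _burst_envelope(
    t: np.ndarray, onset: float, duration: float, cfg: SimulationConfig
) -> np.ndarray:
    """Raised-cosine rise to plateau over the stimulus, raised-cosine decay."""
    t0 = onset + cfg.burst_onset_ms / 1000.0
    rise = cfg.burst_rise_ms / 1000.0
    decay = cfg.burst_decay_ms / 1000.0
    t1 = onset + duration  # plateau holds until stimulus offset
    env = np.zeros_like(t)
    m = (t >= t0) & (t < t0 + rise)
    env[m] = 0.5 * (1 - np.cos(np.pi * (t[m] - t0) / rise))
    env[(t >= t0 + rise) & (t < t1)] = 1.0
    m = (t >= t1) & (t < t1 + decay)
    env[m] = 0.5 * (1 + np.cos(np.pi * (t[m] - t1) / decay))
    return env


def simulate_gaze(
    rng: np.random.Generator, n: int, fs: float, cfg: SimulationConfig
) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Reading-like gaze trace (degrees): fixations, saccadic steps, 1° noise."""
    gaze = np.zeros(n)
    pos = 0.0
    t = 0
    saccades: list[tuple[float, float]] = []
    mean_fix = max(1.0 / cfg.saccade_rate_hz, 0.05)
    rise = max(2, int(round(0.03 * fs)))  # ~30 ms saccadic transition
    ramp = 0.5 * (1 - np.cos(np.pi * np.arange(rise) / rise))
    while t < n:
        fix = int(round(rng.exponential(mean_fix) * fs)) + rise
        end = min(n, t + fix)
        gaze[t:end] = pos
        t = end
        if t >= n:
            break
        amp = rng.uniform(*cfg.saccade_amp_deg) * rng.choice([-1.0, 1.0])
        if abs(pos + amp) > 25:  # stay on the ±35° calibrated span
            amp = -amp
        stop = min(n, t + rise)
        gaze[t:stop] = pos + amp * ramp[: stop - t]
        saccades.append((t / fs, amp))
        pos += amp
        t = stop
    gaze = gaze + rng.normal(0.0, cfg.eog_noise_deg, n)
    return gaze, saccades


def _channel_layout(cfg: SimulationConfig) -> list[ChannelInfo]:
    chans = [
        ChannelInfo(Muscle[m], side)
        for m in cfg.muscles
        for side in (Side.LEFT, Side.RIGHT)
    ]
    if cfg.include_controls:
        chans += [
            ChannelInfo(Muscle.SCM, Side.LEFT),
            ChannelInfo(Muscle.FRONTALIS, Side.LEFT),
            ChannelInfo(Muscle.ZYGOMATICUS, Side.LEFT),
            ChannelInfo(Muscle.EOG_H, Side.MIDLINE),
        ]
    return chans


def _emg_channel(
    rng: np.random.Generator, mod: np.ndarray, fs: float, cfg: SimulationConfig
) -> np.ndarray:
    n = mod.size
    x = cfg.noise_floor_uv * (1.0 + mod) * _carrier(rng, n, fs, cfg.carrier_band)
    if cfg.line_amp_uv > 0:
        t = np.arange(n) / fs
        x = x + cfg.line_amp_uv * np.sin(2 * np.pi * cfg.line_hz * t + rng.uniform(0, 2 * np.pi))
    if cfg.sensor_noise_uv > 0:
        x = x + rng.normal(0.0, cfg.sensor_noise_uv, n)
    return x


# ---------------------------------------------------------------------------
# exogenous sessions
# ---------------------------------------------------------------------------

def _exogenous_schedule(rng: np.random.Generator, cfg: SimulationConfig) -> pd.DataFrame:
    stims = [
        (STIMULUS_NAMES[i % len(STIMULUS_NAMES)] + ("" if i < len(STIMULUS_NAMES) else f"_{i}"), sp)
        for i in range(cfg.n_stimulus_types)
        for sp in SPEAKERS
    ]
    order = rng.permutation(len(stims))
    onset = cfg.lead_in_s
    rows = []
    for k in order:
        name, sp = stims[k]
        rows.append(
            dict(
                onset=onset,
                duration=float(rng.uniform(*cfg.stimulus_duration_s)),
                speaker_azimuth=sp,
                stimulus_type=name,
                attended_azimuth=np.nan,
                experiment="exogenous",
            )
        )
        onset += float(rng.uniform(*cfg.isi_s))
    return pd.DataFrame(rows)


def simulate_exogenous_session(
    cfg: SimulationConfig, subject_id: str = "s01", seed: int | np.random.SeedSequence = 0
) -> tuple[Recording, EventTable, GroundTruth]:
    """One novel-sound session: randomized stimulus schedule plus stimulus-locked
    EMG bursts whose gain follows the configured (muscle, side, azimuth) matrix."""
    rng = np.random.default_rng(seed)
    sched = _exogenous_schedule(rng, cfg)
    last = sched.iloc[-1]
    total_s = float(last["onset"] + last["duration"]) + cfg.tail_s
    n = int(round(total_s * cfg.fs))
    t = np.arange(n) / cfg.fs
    chans = _channel_layout(cfg)
    data = np.empty((n, len(chans)))
    amp_rows = []
    sigma = math.sqrt(math.log(1.0 + cfg.trial_cv ** 2))
    trial_amp = np.exp(rng.normal(-sigma ** 2 / 2, sigma, (len(sched), len(chans))))
    gt = GroundTruth(gains=dict(
        ipsi_contra_ratio=cfg.ipsi_contra_ratio, back_front_ratio=cfg.back_front_ratio
    ))
    saccades: list = []
    for ci, ch in enumerate(chans):
        if ch.muscle is Muscle.EOG_H:
            gaze, saccades = simulate_gaze(rng, n, cfg.fs, cfg)
            data[:, ci] = cfg.eog_gain_uv_per_deg * gaze + cfg.eog_offset_uv
            continue
        mod = np.zeros(n)
        is_auricular = ch.muscle.value in [m for m in cfg.muscles]
        for ei, ev in sched.iterrows():
            if not is_auricular:
                continue
            corr = "ipsi" if (ch.side is Side.LEFT) == (ev["speaker_azimuth"] < 0) else "contra"
            ant = "front" if abs(ev["speaker_azimuth"]) == 30 else "back"
            g = cfg.exo_gain(ch.muscle.value, corr, ant) * trial_amp[ei, ci]
            lo = int((ev["onset"]) * cfg.fs)
            hi = min(n, int((ev["onset"] + ev["duration"] + 1.0) * cfg.fs))
            seg = slice(lo, hi)
            mod[seg] += g * _burst_envelope(t[seg], ev["onset"], ev["duration"], cfg)
            amp_rows.append(dict(event=ei, channel=ch.label, gain=g))
        data[:, ci] = _emg_channel(rng, mod, cfg.fs, cfg)
    gt.event_amplitudes = pd.DataFrame(amp_rows)
    gt.saccades = saccades
    rec = Recording(data, cfg.fs, chans, subject_id, "exogenous")
    return rec, EventTable(sched), gt


# ---------------------------------------------------------------------------
# endogenous runs
# ---------------------------------------------------------------------------

CONDITIONS = [(-30, "front"), (30, "front"), (-120, "back"), (120, "back")]


def simulate_endogenous_run(
    cfg: SimulationConfig,
    subject_id: str,
    attended_azimuth: float,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[Recording, EventTable, GroundTruth]:
    """One 5-min dichotic-listening run under the given attended speaker."""
    if attended_azimuth not in dict(CONDITIONS):
        raise ConfigError(f"attended azimuth must be one of {sorted(dict(CONDITIONS))}")
    rng = np.random.default_rng(seed)
    n = int(round(cfg.run_length_s * cfg.fs))
    chans = _channel_layout(cfg)
    data = np.empty((n, len(chans)))
    ant = "front" if abs(attended_azimuth) == 30 else "back"
    gt = GroundTruth(condition=(attended_azimuth, ant), gains=dict(
        tonic_ipsi_contra_ratio=cfg.tonic_ipsi_contra_ratio,
        tonic_back_front_ratio=cfg.tonic_back_front_ratio,
    ))
    seg_len = int(round(1.0 * cfg.fs))
    decline = np.linspace(1.0, 1.0 - cfg.pam_decline, n)
    saccades: list = []
    for ci, ch in enumerate(chans):
        if ch.muscle is Muscle.EOG_H:
            gaze, saccades = simulate_gaze(rng, n, cfg.fs, cfg)
            data[:, ci] = cfg.eog_gain_uv_per_deg * gaze + cfg.eog_offset_uv
            continue
        if ch.muscle.value in cfg.muscles:
            corr = "ipsi" if (ch.side is Side.LEFT) == (attended_azimuth < 0) else "contra"
            g = cfg.endo_gain(ch.muscle.value, corr, ant)
            if cfg.run_cv > 0:
                s = math.sqrt(math.log(1.0 + cfg.run_cv ** 2))
                g *= float(np.exp(rng.normal(-s * s / 2, s)))
            mod = np.full(n, g)
            if ch.muscle is Muscle.PAM:
                mod = g * decline
        else:
            mod = np.zeros(n)
        x = _emg_channel(rng, mod, cfg.fs, cfg)
        # sporadic high-energy artifact bursts: band-limited (they must survive
        # the analysis bandpass), each confined to one 1-s segment and scaled so
        # that segment's energy reaches artifact_energy_factor x the clean level
        n_art = rng.poisson(cfg.artifact_rate_per_min * cfg.run_length_s / 60.0)
        n_seg = n // seg_len
        base_power = float(np.mean(x * x))
        dur = min(int(round(cfg.artifact_duration_s * cfg.fs)), seg_len)
        hit_segments: set[int] = set()
        if n_art and n_seg:
            for si in rng.choice(n_seg, size=min(n_art, n_seg), replace=False):
                s0 = si * seg_len + int(rng.uniform(0, seg_len - dur + 1))
                burst = sps.windows.tukey(dur, 0.25) * _carrier(
                    rng, dur, cfg.fs, cfg.carrier_band
                )
                target = max(cfg.artifact_energy_factor - 1.0, 0.0) * base_power * seg_len
                e = float(np.sum(burst * burst))
                if e > 0:
                    x[s0 : s0 + dur] += burst * math.sqrt(target / e)
                hit_segments.add(int(si))
        if hit_segments:
            gt.artifact_segments[ch.label] = sorted(hit_segments)
        data[:, ci] = x
    gt.saccades = saccades
    rec = Recording(data, cfg.fs, chans, subject_id, f"endogenous_{attended_azimuth:+.0f}")
    ev = EventTable.from_rows([
        dict(onset=0.0, duration=cfg.run_length_s, speaker_azimuth=attended_azimuth,
             stimulus_type=np.nan, attended_azimuth=attended_azimuth,
             experiment="endogenous")
    ])
    return rec, ev, gt


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def _subject_ids(n_young: int, n_old: int) -> list[tuple[str, str]]:
    ids = [(f"s{i + 1:02d}", "young") for i in range(n_young)]
    ids += [(f"s{n_young + i + 1:02d}", "old") for i in range(n_old)]
    return ids


def _seedseq(seed) -> np.random.SeedSequence:
    return seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)


def iter_exogenous_cohort(
    cfg: SimulationConfig, seed: int | np.random.SeedSequence
) -> Iterator[tuple[str, str, Recording, EventTable, GroundTruth]]:
    """Yield (subject, age_group, recording, events, ground truth) per subject."""
    ss = _seedseq(seed)
    subjects = _subject_ids(cfg.n_young, cfg.n_old)
    for child, (sid, grp) in zip(ss.spawn(len(subjects)), subjects):
        rec, ev, gt = simulate_exogenous_session(cfg, sid, child)
        yield sid, grp, rec, ev, gt


def iter_endogenous_cohort(
    cfg: SimulationConfig, seed: int | np.random.SeedSequence
) -> Iterator[tuple[str, str, list[tuple[Recording, EventTable, GroundTruth]]]]:
    """Yield (subject, age_group, [four runs]) per subject."""
    ss = _seedseq(seed)
    subjects = _subject_ids(cfg.n_young_endo, cfg.n_old_endo)
    for child, (sid, grp) in zip(ss.spawn(len(subjects)), subjects):
        runs = []
        for rs, (az, _) in zip(child.spawn(len(CONDITIONS)), CONDITIONS):
            runs.append(simulate_endogenous_run(cfg, sid, az, rs))
        yield sid, grp, runs


def simulate_cohort(
    cfg: SimulationConfig,
    seed: int,
    out_dir: str | Path,
    dialect: str = "edf",
    experiments: tuple[str, ...] = ("exogenous", "endogenous"),
) -> pd.DataFrame:
    """Write a full cohort to disk and return (and save) its manifest.

    Layout: ``<out>/<subject>_<session>.{edf,tsv}`` plus a matching
    ``*_events.tsv`` per recording and one ``manifest.tsv``.  Deterministic
    given (cfg, seed): identical inputs rewrite identical manifests.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ext = "edf" if dialect == "edf" else "tsv"
    rows = []
    if "exogenous" in experiments:
        for sid, grp, rec, ev, gt in iter_exogenous_cohort(cfg, seed):
            stem = f"{sid}_exogenous"
            write_recording(rec, out / f"{stem}.{ext}", dialect)
            write_events(ev, out / f"{stem}_events.tsv")
            rows.append(dict(
                file=f"{stem}.{ext}", subject=sid, age_group=grp,
                experiment="exogenous", condition="",
                ipsi_contra_ratio=cfg.ipsi_contra_ratio,
                back_front_ratio=cfg.back_front_ratio,
                n_events=len(ev),
            ))
    if "endogenous" in experiments:
        for sid, grp, runs in iter_endogenous_cohort(cfg, seed):
            for (rec, ev, gt), (az, ant) in zip(runs, CONDITIONS):
                stem = f"{sid}_endogenous_{az:+d}"
                write_recording(rec, out / f"{stem}.{ext}", dialect)
                write_events(ev, out / f"{stem}_events.tsv")
                rows.append(dict(
                    file=f"{stem}.{ext}", subject=sid, age_group=grp,
                    experiment="endogenous", condition=f"{az:+d}",
                    ipsi_contra_ratio=cfg.tonic_ipsi_contra_ratio,
                    back_front_ratio=cfg.tonic_back_front_ratio,
                    n_events=len(ev),
                ))
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    return manifest
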