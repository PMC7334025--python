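"""Oculomotor confound controls: EOG calibration, macrosaccade detection,
event-locked gaze averaging, and saccade-to-stimulus timing density.

Auricular activity secondary to large gaze shifts (the oculo-auricular
phenomenon) is the main alternative explanation for lateralized ear-muscle
responses, so the horizontal EOG is calibrated to degrees of visual angle
(per-participant linear fit against a ±35° cursor-tracking protocol),
screened for macrosaccades, and averaged around stimulus events to verify
the absence of systematic gaze diversion toward the attended side.
Positive angles are rightward.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_core import ConfigError, DataError, EventTable, logger

__all__ = [
    "CalibrationModel",
    "SaccadeEvent",
    "fit_calibration",
    "detect_macrosaccades",
    "event_locked_eog",
    "saccade_event_density",
]


@dataclass
class CalibrationModel:
    """Linear voltage-to-angle map for one participant's horizontal EOG."""

    gain: float       # degrees per µV
    offset: float     # degrees at 0 µV
    residual_sd: float  # degrees
    span: float = 35.0  # ± degrees covered by the tracking protocol

    def __post_init__(self) -> None:
        if not np.isfinite(self.gain) or self.gain == 0:
            raise DataError("calibration gain must be finite and nonzero")

    def to_degrees(self, voltage: np.ndarray) -> np.ndarray:
        return self.gain * np.asarray(voltage, float) + self.offset

    def to_voltage(self, degrees: np.ndarray) -> np.ndarray:
        return (np.asarray(degrees, float) - self.offset) / self.gain


def fit_calibration(
    eog_voltage: np.ndarray, target_degrees: np.ndarray, span: float = 35.0
) -> CalibrationModel:
    """Least-squares linear fit of gaze angle on EOG voltage."""
    v = np.asarray(eog_voltage, float)
    d = np.asarray(target_degrees, float)
    if v.shape != d.shape or v.size < 2:
        raise DataError("need paired voltage/angle series of equal length >= 2")
    if np.ptp(d) == 0 or np.ptp(v) == 0:
        raise DataError("degenerate calibration: constant targets or voltages")
    gain, offset = np.polyfit(v, d, 1)
    resid = d - (gain * v + offset)
    return CalibrationModel(float(gain), float(offset), float(np.std(resid)), span)


@dataclass
class SaccadeEvent:
    """A detected macrosaccade (signed amplitude, + rightward)."""

    onset: float          # s
    amplitude: float      # degrees
    peak_velocity: float  # degrees/s
    duration: float       # s

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise DataError("saccade duration must be > 0")


def detect_macrosaccades(
    gaze: np.ndarray,
    fs: float,
    velocity_threshold: float = 30.0,
    min_amplitude: float = 2.0,
    smooth_ms: float = 20.0,
    merge_gap_ms: float = 20.0,
) -> list[SaccadeEvent]:
    """Velocity-threshold detector on the calibrated gaze signal (degrees).

    The derivative is smoothed with a *smooth_ms* moving average; contiguous
    supra-threshold stretches separated by less than *merge_gap_ms* are
    merged; events are kept when |amplitude| (gaze change across the event)
    reaches *min_amplitude* degrees.
    """
    if fs < 100:
        raise ConfigError(f"fs = {fs} Hz too low for saccade detection")
    g = np.asarray(gaze, float)
    if g.size < 3:
        return []
    vel = np.gradient(g) * fs
    w = max(1, int(round(smooth_ms / 1000.0 * fs)))
    vel = np.convolve(vel, np.ones(w) / w, mode="same")
    above = np.abs(vel) > velocity_threshold
    if not above.any():
        return []
    idx = np.flatnonzero(above)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    regions = []
    lo = idx[0]
    for b in breaks:
        regions.append((lo, idx[b]))
        lo = idx[b + 1]
    regions.append((lo, idx[-1]))
    # merge nearby regions
    gap = int(round(merge_gap_ms / 1000.0 * fs))
    merged = [list(regions[0])]
    for s, e in regions[1:]:
        if s - merged[-1][1] <= gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    events = []
    for s, e in merged:
        s0 = max(0, s - w)
        e0 = min(g.size - 1, e + w)
        amp = g[e0] - g[s0]
        if abs(amp) < min_amplitude:
            continue
        events.append(
            SaccadeEvent(
                onset=s / fs,
                amplitude=float(amp),
                peak_velocity=float(np.max(np.abs(vel[s : e + 1]))),
                duration=max(e - s + 1, 1) / fs,
            )
        )
    return events


def event_locked_eog(
    gaze: np.ndarray,
    fs: float,
    events: EventTable,
    window_s: tuple[float, float] = (-1.0, 3.0),
    post_s: tuple[float, float] = (0.0, 1.0),
) -> dict:
    """Average calibrated gaze around stimulus events.

    Returns the subject's mean event-locked trace, the overall gaze SD, the
    systematic-shift statistic (|mean post-event gaze re pre-event mean| in
    degrees), and a ``no_systematic_diversion`` flag that is true when the
    shift stays within one SD of the gaze signal.
    """
    g = np.asarray(gaze, float)
    pre = int(round(-window_s[0] * fs))
    post = int(round(window_s[1] * fs))
    segs = []
    for ev in events:
        c = int(round(ev["onset"] * fs))
        if c - pre < 0 or c + post > g.size:
            continue
        segs.append(g[c - pre : c + post])
    if not segs:
        raise DataError("no events lie within the gaze record")
    trace = np.mean(segs, axis=0)
    t0 = pre  # index of event onset in trace
    lo = t0 + int(round(post_s[0] * fs))
    hi = t0 + int(round(post_s[1] * fs))
    baseline = float(np.mean(trace[:t0])) if t0 > 0 else 0.0
    shift = abs(float(np.mean(trace[lo:hi])) - baseline)
    gaze_sd = float(np.std(g))
    return dict(
        trace=trace,
        fs=fs,
        onset_index=t0,
        gaze_mean=float(np.mean(g)),
        gaze_sd=gaze_sd,
        shift_deg=shift,
        no_systematic_diversion=bool(shift < gaze_sd),
    )


def saccade_event_density(
    saccades: list[SaccadeEvent],
    events: EventTable,
    lags: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Rate of saccade onsets vs. time since the nearest preceding stimulus.

    Returns (bin_centers_s, rate_per_s).  Empty inputs yield empty output
    with a warning, mirroring the plotting use of this quantity.
    """
    if lags is None:
        lags = np.linspace(0.0, 10.0, 21)
    lags = np.asarray(lags, float)
    onsets = np.asarray([s.onset for s in saccades], float)
    ev_onsets = events.df["onset"].to_numpy(float) if len(events) else np.array([])
    if onsets.size == 0 or ev_onsets.size == 0:
        logger.warning("saccade_event_density: empty saccade or event list")
        return (lags[:-1] + np.diff(lags) / 2, np.zeros(max(lags.size - 1, 0)))
    idx = np.searchsorted(ev_onsets, onsets, side="right") - 1
    ok = idx >= 0
    rel = onsets[ok] - ev_onsets[idx[ok]]
    counts, edges = np.histogram(rel, bins=lags)
    widths = np.diff(edges)
    rate = counts / (len(ev_onsets) * widths)
    centers = edges[:-1] + widths / 2
    return centers, rate
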