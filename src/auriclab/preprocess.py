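"""Role-specific zero-phase filtering, 50 Hz notch, and downsampling.

Auricular EMG channels get a 10–1000 Hz zero-phase FIR bandpass (order 2000
at 9600 Hz) followed by a 2nd-order IIR notch at 50 Hz; the
sternocleidomastoid gets 60–1000 Hz FIR(2000); the horizontal EOG gets a
0.01–20 Hz 2nd-order IIR bandpass.  All chains are applied forward-backward
(zero net phase, squared single-pass magnitude) and the filtered signals are
then downsampled by plain sample picking — the 1000 Hz low-pass edge already
bounds the band below the decimated Nyquist.

Long FIR chains are applied in the frequency domain: a linear-phase kernel
convolved with its time reverse is itself zero-phase, so one centered FFT
convolution of the reflect-padded signal reproduces the forward-backward
result without the O(N·order) cost of a direct recursion.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import signal as sps

from .io_core import AnalysisConfig, ConfigError, DataError, Recording, Role

__all__ = [
    "FilterSpec",
    "zero_phase_filter",
    "notch_50",
    "decimate_after_filter",
    "preprocess_recording",
]


@dataclass(frozen=True)
class FilterSpec:
    """A realizable filter: kind, band edges (Hz), order, design sampling rate."""

    kind: str  # fir_bandpass | iir_bandpass | iir_notch
    edges: tuple[float, ...]
    order: int
    fs: float
    q: float = 30.0  # notch quality factor (only iir_notch)

    def __post_init__(self) -> None:
        if self.kind not in ("fir_bandpass", "iir_bandpass", "iir_notch"):
            raise ConfigError(f"unknown filter kind {self.kind!r}")
        if self.order < 1:
            raise ConfigError("filter order must be >= 1")
        nyq = self.fs / 2.0
        if self.kind == "iir_notch":
            (f0,) = self.edges
            if not 0 < f0 < nyq:
                raise ConfigError(f"notch frequency {f0} outside (0, {nyq})")
        else:
            lo, hi = self.edges
            if not 0 < lo < hi < nyq:
                raise ConfigError(f"band edges {self.edges} not inside (0, {nyq})")


@lru_cache(maxsize=64)
def _design(spec: FilterSpec):
    """Design coefficients; FIR returns taps, IIR returns stable SOS."""
    if spec.kind == "fir_bandpass":
        taps = sps.firwin(
            spec.order + 1,
            spec.edges,
            pass_zero=False,
            window="hamming",
            fs=spec.fs,
        )
        return ("fir", taps)
    if spec.kind == "iir_bandpass":
        sos = sps.butter(spec.order, spec.edges, btype="bandpass", fs=spec.fs, output="sos")
        return ("sos", sos)
    b, a = sps.iirnotch(spec.edges[0], spec.q, fs=spec.fs)
    return ("sos", sps.tf2sos(b, a))


def _padlen(order: int, n: int) -> int:
    return min(3 * order, n - 1)


def zero_phase_filter(x: np.ndarray, spec: FilterSpec) -> np.ndarray:
    """Forward-backward filtering: zero net phase, squared magnitude response.

    Reflective padding of 3x the filter order (capped at signal length - 1)
    controls edge transients.  Output length equals input length.
    """
    x = np.asarray(x, dtype=np.float64)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    n = x.shape[0]
    if n < 2:
        raise DataError(f"signal of length {n} too short to filter")
    kind, coef = _design(spec)
    pad = _padlen(spec.order if kind == "fir" else 3 * spec.order, n)
    if kind == "fir":
        xp = np.pad(x, ((pad, pad), (0, 0)), mode="reflect")
        # b is linear-phase (firwin, symmetric); b * reversed(b) is zero-phase
        kernel = np.convolve(coef, coef[::-1])[:, None]
        y = sps.fftconvolve(xp, kernel, mode="same", axes=0)
        y = y[pad : pad + n]
    else:
        y = sps.sosfiltfilt(coef, x, axis=0, padtype="even", padlen=min(pad, n - 1))
    return y[:, 0] if squeeze else y


def notch_50(x: np.ndarray, fs: float, f0: float = 50.0, q: float = 30.0) -> np.ndarray:
    """Zero-phase 2nd-order IIR notch; rejects the line component at *f0*."""
    if fs <= 2 * f0:
        raise ConfigError(f"fs = {fs} Hz too low for a {f0} Hz notch")
    return zero_phase_filter(x, FilterSpec("iir_notch", (f0,), 2, fs, q=q))


def decimate_after_filter(x: np.ndarray, factor: int) -> np.ndarray:
    """Keep every *factor*-th sample (the preceding band limit prevents aliasing)."""
    if factor < 1 or int(factor) != factor:
        raise ConfigError(f"decimation factor must be a positive integer, got {factor}")
    return np.asarray(x)[:: int(factor)]


_CHAIN_BUILDERS = {
    Role.AURICULAR_EMG: lambda cfg: [
        FilterSpec("fir_bandpass", tuple(cfg.emg_band), cfg.emg_fir_order, cfg.raw_fs),
        FilterSpec("iir_notch", (cfg.notch_hz,), cfg.notch_order, cfg.raw_fs, q=cfg.notch_q),
    ],
    Role.NECK_EMG: lambda cfg: [
        FilterSpec("fir_bandpass", tuple(cfg.scm_band), cfg.scm_fir_order, cfg.raw_fs),
    ],
    Role.FACIAL_EMG: lambda cfg: [
        FilterSpec("fir_bandpass", tuple(cfg.emg_band), cfg.emg_fir_order, cfg.raw_fs),
        FilterSpec("iir_notch", (cfg.notch_hz,), cfg.notch_order, cfg.raw_fs, q=cfg.notch_q),
    ],
    Role.EOG: lambda cfg: [
        FilterSpec("iir_bandpass", tuple(cfg.eog_band), cfg.eog_iir_order, cfg.raw_fs),
    ],
}


def filter_chain(role: Role, cfg: AnalysisConfig) -> list[FilterSpec]:
    """The role-specific filter chain (bandpass first, then notch where used)."""
    try:
        return _CHAIN_BUILDERS[role](cfg)
    except KeyError:
        raise ConfigError(f"no filter chain configured for role {role}") from None


def preprocess_recording(rec: Recording, cfg: AnalysisConfig) -> Recording:
    """Apply every channel's role chain and decimate; µV in, µV out.

    The applied chain is recorded in each channel's ``processing`` metadata.
    """
    if rec.fs != cfg.raw_fs:
        raise ConfigError(
            f"recording fs {rec.fs} != configured acquisition fs {cfg.raw_fs}"
        )
    out_cols = []
    out_channels = []
    for i, ch in enumerate(rec.channels):
        x = rec.data[:, i]
        steps = []
        for spec in filter_chain(ch.role, cfg):
            x = zero_phase_filter(x, spec)
            if spec.kind == "iir_notch":
                steps.append(f"notch{spec.edges[0]:g}Hz(iir{spec.order})")
            else:
                steps.append(
                    f"bp{spec.edges[0]:g}-{spec.edges[1]:g}Hz"
                    f"({'fir' if spec.kind == 'fir_bandpass' else 'iir'}{spec.order})"
                )
        x = decimate_after_filter(x, cfg.decim_factor)
        steps.append(f"decim{cfg.decim_factor}")
        out_cols.append(x)
        out_channels.append(ch.with_processing(*steps))
    data = np.column_stack(out_cols) if out_cols else np.empty((0, 0))
    return Recording(data, cfg.processed_fs, out_channels, rec.subject_id, rec.session)
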