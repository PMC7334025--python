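"""Eight-band nonsubsampled octave filter-bank decomposition of the EMG.

Sustained low-level muscle activity can concentrate in narrow mid-frequency
bands, so the endogenous energy pipeline is repeated per octave band.  The
decomposition is the à-trous stationary wavelet transform (db5, 8 levels,
normalized filters): every band has the same length as the input, the bands
are shift-equivariant away from the boundaries, and detail level j nominally
covers [fs/2^(j+1), fs/2^j).  The lowest approximation band is retained for
(perfect) reconstruction but the eight reported frequency bands are the
detail levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt

from .io_core import (
    AnalysisConfig,
    ConfigError,
    EventTable,
    Recording,
)
from .endogenous import subject_endogenous_measures

__all__ = ["SubbandSet", "decompose", "reconstruct", "per_band_endogenous"]


@dataclass
class SubbandSet:
    """Nonsubsampled octave bands of one signal (details high->low + approximation)."""

    bands: list[np.ndarray]       # detail levels 1..L, each len == input
    approximation: np.ndarray
    band_edges: list[tuple[float, float]]  # nominal (lo, hi) Hz per detail level
    wavelet: str
    fs: float
    _pad: tuple[int, int] = (0, 0)  # symmetric padding used to reach 2^L multiple
    _full_coeffs: list | None = None  # untrimmed SWT coefficients of the padded signal

    @property
    def levels(self) -> int:
        return len(self.bands)


def decompose(
    x: np.ndarray, levels: int = 8, wavelet: str = "db5", fs: float = 2400.0
) -> SubbandSet:
    """À-trous (stationary) wavelet decomposition into octave bands.

    The signal is symmetrically padded to a multiple of ``2**levels`` (the
    padding is remembered and trimmed from the bands and at reconstruction).
    """
    x = np.asarray(x, dtype=np.float64)
    if levels < 1:
        raise ConfigError("levels must be >= 1")
    block = 2 ** levels
    if x.size < 2:
        raise ConfigError(f"signal of {x.size} samples too short for {levels} levels")
    total = int(np.ceil(x.size / block)) * block
    extra = total - x.size
    left = extra // 2
    right = extra - left
    xp = np.pad(x, (left, right), mode="symmetric")
    coeffs = pywt.swt(xp, wavelet, level=levels, trim_approx=True, norm=True)
    approx = coeffs[0]
    details = coeffs[1:]          # ordered level L .. level 1
    sl = slice(left, left + x.size)
    bands = [d[sl].copy() for d in reversed(details)]  # level 1 (highest band) first
    edges = [(fs / 2 ** (j + 1), fs / 2 ** j) for j in range(1, levels + 1)]
    return SubbandSet(
        bands, approx[sl].copy(), edges, wavelet, fs, (left, right), list(coeffs)
    )


def reconstruct(sb: SubbandSet) -> np.ndarray:
    """Invert :func:`decompose`; exact to numerical precision on the interior."""
    if sb.approximation is None or not sb.bands:
        raise ConfigError("SubbandSet incomplete: approximation and all bands required")
    n = sb.bands[0].size
    left, right = sb._pad
    sl = slice(left, left + n)
    trimmed = [sb.approximation] + [b for b in reversed(sb.bands)]
    if sb._full_coeffs is not None:
        # overlay the (possibly modified) interior onto the stored padded
        # coefficients so boundary context stays consistent
        coeffs = []
        for full, band in zip(sb._full_coeffs, trimmed):
            c = np.array(full, dtype=np.float64, copy=True)
            c[sl] = band
            coeffs.append(c)
    else:
        coeffs = [
            np.pad(b, (left, right), mode="symmetric") if (left or right) else b
            for b in trimmed
        ]
    y = pywt.iswt(coeffs, sb.wavelet, norm=True)
    return y[sl]


def band_energies(sb: SubbandSet) -> np.ndarray:
    """Total energy (sum of squares) per detail band, highest band first."""
    return np.array([float(np.sum(b * b)) for b in sb.bands])


def per_band_endogenous(
    runs: list[tuple[Recording, EventTable]], cfg: AnalysisConfig
) -> pd.DataFrame:
    """Run the endogenous pipeline independently on every octave band.

    Each auricular channel of each run is decomposed; band *j* of every
    channel is reassembled into a per-band Recording and passed through the
    broadband endogenous analysis.  The output table gains ``band`` (1 =
    highest octave) and ``band_lo_hz``/``band_hi_hz`` columns.
    """
    frames = []
    decomposed: list[tuple[list[SubbandSet], Recording, EventTable]] = []
    for rec, events in runs:
        sbs = [
            decompose(rec.data[:, i], cfg.subband_levels, cfg.wavelet_name, rec.fs)
            for i in range(rec.data.shape[1])
        ]
        decomposed.append((sbs, rec, events))
    for j in range(cfg.subband_levels):
        band_runs = []
        for sbs, rec, events in decomposed:
            data = np.column_stack([sb.bands[j] for sb in sbs])
            band_runs.append(
                (Recording(data, rec.fs, rec.channels, rec.subject_id, rec.session), events)
            )
        df = subject_endogenous_measures(band_runs, cfg)
        lo, hi = decomposed[0][0][0].band_edges[j]
        df["band"] = j + 1
        df["band_lo_hz"] = lo
        df["band_hi_hz"] = hi
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
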