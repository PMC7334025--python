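"""Sustained-attention (dichotic listening) analysis: segment energies,
artifact rejection, run-normalized condition means, and 10-s time-resolved
lateralization traces.

Each 5-min listening run is reduced per channel to mean signal energies of
1-s non-overlapping segments; segments deviating from the run mean by more
than two standard deviations are rejected (single pass — mean/SD include
the artifacts being tested).  A channel's run summary is its mean retained
energy divided by a per-run normalization reference, pooled into
ipsilateral/contralateral by comparing the channel side with the attended
azimuth.  The time-resolved view computes 10-s segment energies and
normalizes each ipsi/contra pair to unit sum, yielding lateralization
proportions over the run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import (
    AnalysisConfig,
    DataError,
    DesignError,
    EventTable,
    Muscle,
    Recording,
    Role,
    Side,
)

__all__ = [
    "SegmentEnergies",
    "RunSummary",
    "segment_energy",
    "reject_artifacts",
    "condition_mean_energy",
    "time_resolved",
    "endogenous_run_summary",
]


@dataclass
class SegmentEnergies:
    """Mean energy (µV²) of consecutive non-overlapping segments plus a retain mask."""

    energies: np.ndarray
    retained: np.ndarray  # boolean, same length
    segment_s: float

    @property
    def n_rejected(self) -> int:
        return int((~self.retained).sum())


def segment_energy(x: np.ndarray, fs: float, segment_s: float) -> SegmentEnergies:
    """Mean of squared samples per *segment_s*-long segment; trailing partial dropped."""
    x = np.asarray(x, dtype=np.float64)
    seg = int(round(segment_s * fs))
    if seg < 1 or x.size < seg:
        raise DataError(f"signal of {x.size} samples shorter than one {segment_s} s segment")
    n = x.size // seg
    e = (x[: n * seg] ** 2).reshape(n, seg).mean(axis=1)
    return SegmentEnergies(e, np.ones(n, dtype=bool), segment_s)


def reject_artifacts(se: SegmentEnergies, k: float = 2.0) -> SegmentEnergies:
    """Mask segments whose energy deviates from the mean by more than k·SD.

    Statistics are computed in a single pass over all segments (the
    artifacts are included in the mean/SD against which they are tested).
    Zero-variance runs retain everything.
    """
    if se.energies.size < 3:
        raise DataError("need at least 3 segments for artifact statistics")
    mu = float(se.energies.mean())
    sd = float(se.energies.std())
    if sd == 0:
        mask = np.ones_like(se.retained)
    else:
        mask = np.abs(se.energies - mu) <= k * sd
    return SegmentEnergies(se.energies.copy(), mask, se.segment_s)


@dataclass
class RunSummary:
    """One listening run: condition labels plus per-channel energy measures."""

    attended_azimuth: float
    anteriority: str
    values: pd.DataFrame  # channel, muscle, correspondence, mean_energy,
                          # max_segment_energy, norm_energy, n_rejected
    traces: dict[tuple[Muscle, str], np.ndarray]  # 10-s lateralization proportions


def _correspondence(side: Side, attended_azimuth: float) -> str:
    ipsi = (side is Side.LEFT) == (attended_azimuth < 0)
    return "ipsi" if ipsi else "contra"


def condition_mean_energy(se: SegmentEnergies, reference: float | None = None) -> float:
    """Mean retained segment energy of one channel, optionally normalized.

    With *reference* (µV²) the mean is divided by it — the caller supplies
    the per-channel maximum across the four listening conditions
    (``run_norm='max_condition'``, the default analysis) or the run's own
    largest retained segment energy (``'max_segment'``).
    """
    kept = se.energies[se.retained]
    if kept.size == 0:
        raise DesignError("all segments rejected; empty run")
    mean = float(kept.mean())
    if reference is None:
        return mean
    if reference <= 0:
        raise DesignError("non-positive normalization reference")
    return mean / float(reference)


def time_resolved(
    ipsi: np.ndarray, contra: np.ndarray, fs: float, segment_s: float = 10.0
) -> np.ndarray:
    """Per 10-s bin, (ipsi, contra) energies normalized to unit sum.

    Returns an array of shape (n_bins, 2); bins with zero total energy are
    marked missing (NaN).  With a 5-min run and 10-s segments this yields
    30 points per trace.
    """
    ei = segment_energy(ipsi, fs, segment_s).energies
    ec = segment_energy(contra, fs, segment_s).energies
    n = min(ei.size, ec.size)
    ei, ec = ei[:n], ec[:n]
    tot = ei + ec
    out = np.full((n, 2), np.nan)
    ok = tot > 0
    out[ok, 0] = ei[ok] / tot[ok]
    out[ok, 1] = ec[ok] / tot[ok]
    return out


def endogenous_run_summary(
    rec: Recording, events: EventTable, cfg: AnalysisConfig
) -> RunSummary:
    """Full analysis of one preprocessed listening run.

    The run's condition comes from its (single) endogenous event.  For every
    auricular muscle the left/right channels are assigned ipsi/contra by the
    attended side; each channel contributes its artifact-cleaned, normalized
    mean 1-s energy and the pair contributes a 10-s lateralization trace.
    """
    endo = events.df[events.df["experiment"] == "endogenous"]
    if len(endo) != 1:
        raise DesignError(f"expected exactly one endogenous event, got {len(endo)}")
    att = float(endo["attended_azimuth"].iloc[0])
    anteriority = "front" if abs(att) == 30 else "back"

    rows = []
    traces: dict[tuple[Muscle, str], np.ndarray] = {}
    by_muscle: dict[Muscle, dict[str, np.ndarray]] = {}
    for i, ch in enumerate(rec.channels):
        if ch.role is not Role.AURICULAR_EMG:
            continue
        x = rec.data[:, i]
        se = reject_artifacts(
            segment_energy(x, rec.fs, cfg.energy_segment_s), cfg.artifact_k
        )
        corr = _correspondence(ch.side, att)
        mean_e = condition_mean_energy(se)
        max_seg = float(se.energies[se.retained].max())
        rows.append(
            dict(
                channel=ch.label,
                muscle=ch.muscle.value,
                correspondence=corr,
                mean_energy=mean_e,
                max_segment_energy=max_seg,
                norm_energy=mean_e / max_seg if max_seg > 0 else np.nan,
                n_rejected=se.n_rejected,
            )
        )
        by_muscle.setdefault(ch.muscle, {})[corr] = x
    for muscle, sides in by_muscle.items():
        if {"ipsi", "contra"} <= sides.keys():
            tr = time_resolved(
                sides["ipsi"], sides["contra"], rec.fs, cfg.timecourse_segment_s
            )
            traces[(muscle, "ipsi")] = tr[:, 0]
            traces[(muscle, "contra")] = tr[:, 1]
    return RunSummary(att, anteriority, pd.DataFrame(rows), traces)


def subject_endogenous_measures(
    runs: list[tuple[Recording, EventTable]], cfg: AnalysisConfig
) -> pd.DataFrame:
    """Condition-cell table for one subject from their four listening runs.

    With the default ``run_norm='max_condition'`` each channel's per-run mean
    energies are first divided by that channel's largest mean energy across
    the runs (so every channel's normalized values lie in (0, 1] and relative
    condition differences survive); ``'max_segment'`` instead uses each run's
    own largest retained 1-s segment as the reference.  Cells then average
    the normalized energies of the runs/channels that populate them (left-
    and right-attended runs both contribute an ipsi and a contra value).
    """
    frames = []
    subject = runs[0][0].subject_id if runs else ""
    for rec, events in runs:
        rs = endogenous_run_summary(rec, events, cfg)
        df = rs.values.copy()
        df["anteriority"] = rs.anteriority
        frames.append(df)
    big = pd.concat(frames, ignore_index=True)
    if cfg.run_norm == "max_condition":
        ref = big.groupby("channel")["mean_energy"].transform("max")
        big["norm_energy"] = big["mean_energy"] / ref
    elif cfg.run_norm != "max_segment":
        raise DataError(f"unknown run normalization {cfg.run_norm!r}")
    out = (
        big.groupby(["muscle", "correspondence", "anteriority"], as_index=False)
        .agg(norm_energy=("norm_energy", "mean"),
             mean_energy=("mean_energy", "mean"),
             n_rejected=("n_rejected", "sum"))
    )
    out.insert(0, "subject", subject)
    return out
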