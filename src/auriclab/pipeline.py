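"""Cohort-level glue: simulation or disk input -> condition tables -> ANOVA.

These runners chain the stage modules end to end for whole cohorts and are
what the simulation studies (type-I calibration, effect and onset recovery)
and the command-line ``report`` step build on.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .endogenous import subject_endogenous_measures
from .exogenous import (
    estimate_onset_latency,
    exogenous_epochs,
    mean_amplitude,
    pool_laterality,
)
from .io_core import AnalysisConfig, Muscle
from .preprocess import preprocess_recording
from .stats import AnovaResult, mixed_rm_anova
from .synthetic import SimulationConfig, iter_endogenous_cohort, iter_exogenous_cohort

__all__ = [
    "exogenous_cohort_table",
    "endogenous_cohort_table",
    "cohort_anova",
    "grand_average_onset_latency",
]


def exogenous_cohort_table(
    sim: SimulationConfig,
    cfg: AnalysisConfig,
    seed: int,
    measure_window_ms: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Simulate, preprocess and measure a whole exogenous cohort.

    Returns the tidy condition table (subject, group, muscle, correspondence,
    anteriority, value = mean amplitude over the measurement window) that
    feeds :func:`auriclab.stats.mixed_rm_anova`.
    """
    window = measure_window_ms or cfg.measure_window_ms
    rows = []
    for sid, grp, rec, ev, _gt in iter_exogenous_cohort(sim, seed):
        proc = preprocess_recording(rec, cfg)
        avg = pool_laterality(exogenous_epochs(proc, ev, cfg))
        for (muscle, corr, ant), val in mean_amplitude(avg, window).items():
            rows.append(
                dict(subject=sid, group=grp, muscle=muscle.value,
                     correspondence=corr, anteriority=ant, value=val)
            )
    return pd.DataFrame(rows)


def endogenous_cohort_table(
    sim: SimulationConfig, cfg: AnalysisConfig, seed: int
) -> pd.DataFrame:
    """Simulate, preprocess and measure a whole endogenous cohort
    (value = run-normalized mean energy per condition cell)."""
    rows = []
    for sid, grp, runs in iter_endogenous_cohort(sim, seed):
        prepared = [(preprocess_recording(rec, cfg), ev) for rec, ev, _gt in runs]
        df = subject_endogenous_measures(prepared, cfg)
        df = df.rename(columns={"norm_energy": "value"})
        df["group"] = grp
        rows.append(df[["subject", "group", "muscle", "correspondence",
                        "anteriority", "value"]])
    return pd.concat(rows, ignore_index=True)


def cohort_anova(table: pd.DataFrame, muscle: str) -> list[AnovaResult]:
    """Per-muscle mixed RM-ANOVA on a cohort condition table."""
    sub = table[table["muscle"] == muscle]
    return mixed_rm_anova(sub)


def grand_average_onset_latency(
    sim: SimulationConfig,
    cfg: AnalysisConfig,
    seed: int,
    muscle: Muscle = Muscle.PAM,
    cell: tuple[str, str] = ("ipsi", "back"),
) -> float | None:
    """Onset latency (ms) of the cohort grand-average waveform in one cell.

    Subject condition waveforms are truncated to the shortest and averaged;
    the onset estimate is the first sustained crossing of the grand-average
    baseline mean + 3 SD.
    """
    waves = []
    fs = onset_index = None
    for _sid, _grp, rec, ev, _gt in iter_exogenous_cohort(sim, seed):
        proc = preprocess_recording(rec, cfg)
        avg = pool_laterality(exogenous_epochs(proc, ev, cfg))
        wf = avg.waveforms[(muscle, *cell)]
        waves.append(wf)
        fs, onset_index = avg.fs, avg.onset_index
    n = min(w.size for w in waves)
    grand = np.mean([w[:n] for w in waves], axis=0)
    return estimate_onset_latency(grand, fs, onset_index)
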