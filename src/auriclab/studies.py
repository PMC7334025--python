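"""Simulation studies validating the analysis chain against generator truth.

Each study runs the full pipeline (simulate -> preprocess -> envelope/energy
-> measures -> ANOVA) on reduced-scale cohorts and reports a calibration or
recovery statistic:

* type-I error of the correspondence effect under the null generator,
* effect recovery under a 2:1 ipsi/contra gain ratio,
* onset-latency recovery of the 70 ms burst parameter,
* artifact-segment rejection and clean-segment retention,
* macrosaccade recovery and EOG calibration-gain recovery.

Problem sizes: null and effect-recovery cohorts use ~30 s sessions at 480 Hz
(one muscle pair, 62.5 ms RMS window preserved); onset recovery uses 2400 Hz
raw / 1200 Hz processed for millisecond envelope resolution.  All studies are
deterministic given their seed.
"""

from __future__ import annotations

import numpy as np

from .endogenous import reject_artifacts, segment_energy
from .oculomotor import detect_macrosaccades, fit_calibration
from .pipeline import cohort_anova, exogenous_cohort_table, grand_average_onset_latency
from .preprocess import preprocess_recording
from .synthetic import null_sim, reduced_analysis, reduced_sim, simulate_endogenous_run

__all__ = [
    "type_one_error_study",
    "effect_recovery_study",
    "onset_recovery_study",
    "artifact_rejection_study",
    "saccade_recovery_study",
    "calibration_recovery_study",
]


def _spawn_ints(seed: int, n: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(seed).spawn(n)


def type_one_error_study(
    n_replicates: int = 2000, seed: int = 0, alpha: float = 0.05
) -> dict:
    """Rejection rate of the correspondence effect under the null generator.

    Each replicate simulates a 28-subject (16 young / 12 old) cohort of
    ~30 s sessions with all condition gains equal, runs the full exogenous
    pipeline, and tests the correspondence main effect at *alpha*.
    """
    sim = null_sim(reduced_sim(fs=480.0, carrier_band=(20.0, 90.0)))
    cfg = reduced_analysis(480.0, 2)
    rejections = 0
    for child in _spawn_ints(seed, n_replicates):
        table = exogenous_cohort_table(sim, cfg, child)
        res = {r.effect: r for r in cohort_anova(table, "PAM")}
        rejections += res["correspondence"].p < alpha
    return dict(rate=rejections / n_replicates, n=n_replicates,
                alpha=alpha, n_subjects=sim.n_young + sim.n_old)


def effect_recovery_study(n_replicates: int = 100, seed: int = 0) -> dict:
    """Recovery of a 2:1 ipsi/contra burst-gain ratio at default noise.

    Reports the fraction of simulated subjects whose ipsi mean amplitude
    exceeds contra, and the fraction of replicate cohorts in which the
    correspondence effect reaches p < 0.05.
    """
    sim = reduced_sim(fs=480.0, carrier_band=(20.0, 90.0),
                      n_young=8, n_old=4, n_stimulus_types=2)
    cfg = reduced_analysis(480.0, 2)
    detected = 0
    subj_ipsi_gt = 0
    subj_total = 0
    for child in _spawn_ints(seed, n_replicates):
        table = exogenous_cohort_table(sim, cfg, child)
        res = {r.effect: r for r in cohort_anova(table, "PAM")}
        detected += res["correspondence"].p < 0.05
        piv = table.pivot_table(index="subject", columns="correspondence",
                                values="value", aggfunc="mean")
        subj_ipsi_gt += int((piv["ipsi"] > piv["contra"]).sum())
        subj_total += len(piv)
    return dict(
        subject_fraction=subj_ipsi_gt / subj_total,
        detection_rate=detected / n_replicates,
        n=n_replicates,
        gain_ratio=sim.ipsi_contra_ratio,
    )


def onset_recovery_study(n_replicates: int = 20, seed: int = 0) -> dict:
    """Grand-average onset-latency estimate vs. the 70 ms generator parameter."""
    sim = reduced_sim(fs=2400.0, carrier_band=(20.0, 500.0),
                      n_young=8, n_old=4, n_stimulus_types=4,
                      stimulus_duration_s=(1.2, 1.8), isi_s=(4.5, 6.5))
    cfg = reduced_analysis(2400.0, 2)
    estimates = []
    for child in _spawn_ints(seed, n_replicates):
        est = grand_average_onset_latency(sim, cfg, child)
        if est is not None:
            estimates.append(est)
    return dict(
        mean_onset_ms=float(np.mean(estimates)) if estimates else np.nan,
        estimates=estimates,
        true_onset_ms=sim.burst_onset_ms,
        n=n_replicates,
    )


def artifact_rejection_study(n_runs: int = 10, seed: int = 0) -> dict:
    """Rejection of injected 10x-energy artifact segments by the 2 SD rule."""
    sim = reduced_sim(fs=480.0, carrier_band=(20.0, 90.0), run_length_s=60.0,
                      artifact_rate_per_min=5.0)
    cfg = reduced_analysis(480.0, 2)
    art_total = art_rejected = clean_total = clean_rejected = 0
    for i, child in enumerate(_spawn_ints(seed, n_runs)):
        az = [-30, 30, -120, 120][i % 4]
        rec, _ev, gt = simulate_endogenous_run(sim, f"s{i:02d}", az, child)
        proc = preprocess_recording(rec, cfg)
        for label in proc.labels:
            se = reject_artifacts(
                segment_energy(proc.channel(label), proc.fs, cfg.energy_segment_s),
                cfg.artifact_k,
            )
            art = set(gt.artifact_segments.get(label, []))
            rejected = set(np.flatnonzero(~se.retained))
            clean = set(range(se.energies.size)) - art
            art_total += len(art)
            art_rejected += len(art & rejected)
            clean_total += len(clean)
            clean_rejected += len(clean & rejected)
    return dict(
        rejection_rate=art_rejected / art_total if art_total else np.nan,
        clean_rejection_rate=clean_rejected / clean_total,
        n=art_total,
    )


def saccade_recovery_study(
    seed: int = 0, n_saccades: int = 50, noise_deg: float = 0.3, fs: float = 480.0
) -> dict:
    """Recovery of injected >= 4 degree saccades in fixation noise."""
    rng = np.random.default_rng(seed)
    times = 3.0 + np.arange(n_saccades) * 5.0
    n = int((times[-1] + 3.0) * fs)
    gaze = np.zeros(n)
    pos = 0.0
    rise = int(0.02 * fs)
    ramp = 0.5 * (1 - np.cos(np.pi * np.arange(rise) / rise))
    prev = 0
    onsets = []
    for t0 in times:
        amp = rng.uniform(4.0, 12.0) * rng.choice([-1.0, 1.0])
        if abs(pos + amp) > 25:
            amp = -amp
        i = int(t0 * fs)
        gaze[prev:i] = pos
        gaze[i : i + rise] = pos + amp * ramp
        onsets.append(t0)
        pos += amp
        prev = i + rise
    gaze[prev:] = pos
    gaze = gaze + rng.normal(0.0, noise_deg, n)
    detected = detect_macrosaccades(gaze, fs)
    hits = sum(any(abs(d.onset - t) < 0.1 for d in detected) for t in onsets)
    false_pos = sum(not any(abs(d.onset - t) < 0.1 for t in onsets) for d in detected)
    return dict(recovery_rate=hits / n_saccades, false_positives=false_pos,
                n=n_saccades)


def calibration_recovery_study(
    seed: int = 0, true_gain_deg_per_uv: float = 0.1, noise_uv: float = 1.0
) -> dict:
    """EOG calibration-gain recovery from a noisy ±35 degree tracking protocol."""
    rng = np.random.default_rng(seed)
    t = np.linspace(0, 60, 1000)
    degrees = 35.0 * np.sin(2 * np.pi * 0.05 * t)
    voltage = degrees / true_gain_deg_per_uv + rng.normal(0.0, noise_uv, t.size)
    model = fit_calibration(voltage, degrees)
    rel_err = abs(model.gain - true_gain_deg_per_uv) / true_gain_deg_per_uv
    return dict(gain_rel_error=rel_err, gain=model.gain, n=t.size)
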