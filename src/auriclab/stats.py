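"""Mixed repeated-measures ANOVA (2 within x 2 within x between-group) with
partial eta squared, computed from sums of squares.

The design behind every reported effect is: within-subject factors
stimulus-muscle correspondence (ipsi vs. contra) and anteriority (front vs.
back speakers), between-subject factor age group, one value per subject and
cell.  With two-level within factors the univariate mixed ANOVA reduces to
one-way analyses of per-subject orthogonal contrast scores:

* the subject mean score carries the between-group effect (error stratum:
  subjects within groups);
* the correspondence difference score carries the correspondence main effect
  (tested against its subject-by-factor stratum) and, via its group term,
  the correspondence x group interaction; likewise for anteriority and for
  the correspondence x anteriority interaction contrast.

Group means enter the main-effect tests unweighted (Type III), so unequal
group sizes (e.g. 16 young / 12 old) reproduce the conventional
statistical-package output.  No sphericity correction is needed: every
within effect has a single numerator degree of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as spstats

from .io_core import DesignError, ValidationError, logger

__all__ = [
    "AnovaResult",
    "validate_condition_table",
    "mixed_rm_anova",
    "partial_eta_squared",
    "confound_screen",
    "anova_to_frame",
]

WITHIN_LEVELS = {"correspondence": ("ipsi", "contra"), "anteriority": ("front", "back")}
CELLS = [("ipsi", "front"), ("ipsi", "back"), ("contra", "front"), ("contra", "back")]


@dataclass
class AnovaResult:
    effect: str
    F: float
    df_num: int
    df_den: int
    p: float
    eta_p2: float
    ss_effect: float
    ss_error: float


def partial_eta_squared(ss_effect: float, ss_error: float) -> float:
    """SS_effect / (SS_effect + SS_error)."""
    if ss_effect < 0 or ss_error < 0:
        raise ValidationError("sums of squares must be non-negative")
    if ss_effect == 0 and ss_error == 0:
        raise ValidationError("effect size undefined: both sums of squares are zero")
    return ss_effect / (ss_effect + ss_error)


def validate_condition_table(table: pd.DataFrame, value: str = "value") -> pd.DataFrame:
    """Check the balanced subject x cell layout and return a clean copy."""
    required = {"subject", "group", "correspondence", "anteriority", value}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"condition table missing columns {sorted(missing)}")
    df = table.copy()
    offenders = []
    for subj, sub in df.groupby("subject"):
        cells = set(zip(sub["correspondence"], sub["anteriority"]))
        if len(sub) != 4 or cells != set(CELLS):
            offenders.append(subj)
        if sub["group"].nunique() != 1:
            offenders.append(subj)
    if offenders:
        raise DesignError(f"unbalanced design for subjects {sorted(set(offenders))}")
    return df


def _cell_matrix(df: pd.DataFrame, value: str) -> tuple[np.ndarray, np.ndarray, list]:
    """Per-subject 4-vector of cell values (CELLS order), group codes, subject ids."""
    wide = df.pivot_table(
        index=["subject", "group"],
        columns=["correspondence", "anteriority"],
        values=value,
        aggfunc="first",
        observed=True,
    )
    wide = wide[[c for c in CELLS]]
    y = wide.to_numpy(float)
    groups = np.asarray([g for _, g in wide.index])
    subjects = [s for s, _ in wide.index]
    return y, groups, subjects


# orthogonal contrasts over CELLS = (ipsi,front),(ipsi,back),(contra,front),(contra,back)
# scaled so the stratum sums of squares match the classical ANOVA table
_CONTRASTS = {
    "mean": np.array([0.5, 0.5, 0.5, 0.5]),          # 2 * mean of 4 cells
    "correspondence": np.array([0.5, 0.5, -0.5, -0.5]),
    "anteriority": np.array([0.5, -0.5, 0.5, -0.5]),
    "correspondence:anteriority": np.array([0.5, -0.5, -0.5, 0.5]),
}


def _oneway_strata(scores: np.ndarray, groups: np.ndarray):
    """Type III intercept/group/error decomposition of a one-way layout.

    Returns (ss_intercept, ss_group, df_group, ss_error, df_error).
    The intercept is tested on the unweighted mean of group means.
    """
    levels = np.array(sorted(set(groups)))
    g = levels.size
    n_g = np.array([(groups == lv).sum() for lv in levels])
    if np.any(n_g < 2):
        raise DesignError(f"need >= 2 subjects per group, got sizes {dict(zip(levels, n_g))}")
    means = np.array([scores[groups == lv].mean() for lv in levels])
    ss_error = float(sum(((scores[groups == lv] - m) ** 2).sum() for lv, m in zip(levels, means)))
    df_error = scores.size - g
    grand_w = float(scores.mean())
    ss_group = float(np.sum(n_g * (means - grand_w) ** 2))
    mu = float(means.mean())  # unweighted
    ss_intercept = mu ** 2 * g ** 2 / float(np.sum(1.0 / n_g))
    return ss_intercept, ss_group, g - 1, ss_error, df_error


def _f_test(ss_eff: float, df_eff: int, ss_err: float, df_err: int, name: str) -> AnovaResult:
    if ss_err <= 0 and ss_eff <= 0:
        raise DesignError(f"singular error stratum for effect {name}")
    ms_err = ss_err / df_err
    F = (ss_eff / df_eff) / ms_err if ms_err > 0 else np.inf
    p = float(spstats.f.sf(F, df_eff, df_err)) if np.isfinite(F) else 0.0
    return AnovaResult(
        name, float(F), df_eff, df_err, p,
        partial_eta_squared(ss_eff, ss_err), float(ss_eff), float(ss_err),
    )


def mixed_rm_anova(table: pd.DataFrame, value: str = "value") -> list[AnovaResult]:
    """All main and interaction effects of the 2x2(xgroup) mixed design.

    Returns results for: group; correspondence; anteriority;
    correspondence x anteriority; and each within-effect x group interaction.
    """
    df = validate_condition_table(table, value)
    y, groups, _ = _cell_matrix(df, value)
    single_group = len(set(groups)) == 1
    results: list[AnovaResult] = []
    for term, c in _CONTRASTS.items():
        scores = y @ c
        ss_int, ss_grp, df_grp, ss_err, df_err = _oneway_strata(scores, groups)
        if term == "mean":
            if not single_group:
                results.append(_f_test(ss_grp, df_grp, ss_err, df_err, "group"))
        else:
            results.append(_f_test(ss_int, 1, ss_err, df_err, term))
            if not single_group:
                results.append(_f_test(ss_grp, df_grp, ss_err, df_err, f"{term}:group"))
    return results


def anova_to_frame(results: list[AnovaResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                effect=r.effect, F=r.F, df_num=r.df_num, df_den=r.df_den,
                p=r.p, eta_p2=r.eta_p2, ss_effect=r.ss_effect, ss_error=r.ss_error,
            )
            for r in results
        ]
    )


# ---------------------------------------------------------------------------
# covariate screen (ANCOVA-style)
# ---------------------------------------------------------------------------

def _type3_f(yv: np.ndarray, X: np.ndarray, cols: list[int], df_extra: int = 0):
    """General-linear-hypothesis F for the columns *cols* of design X."""
    n, p = X.shape
    XtX = X.T @ X
    XtXi = np.linalg.pinv(XtX)
    beta = XtXi @ X.T @ yv
    resid = yv - X @ beta
    df_err = n - np.linalg.matrix_rank(X)
    ss_err = float(resid @ resid)
    L = np.zeros((len(cols), p))
    for i, c in enumerate(cols):
        L[i, c] = 1.0
    M = L @ XtXi @ L.T
    lb = L @ beta
    ss_eff = float(lb @ np.linalg.solve(M, lb))
    return ss_eff, len(cols), ss_err, df_err


def confound_screen(
    table: pd.DataFrame, covariate: str, value: str = "value"
) -> list[AnovaResult]:
    """Re-run the mixed ANOVA with a per-subject-and-cell covariate entered.

    The covariate (e.g. sternocleidomastoid energy or EOG shift, measured in
    the same cells) is reduced by the same orthogonal contrasts as the
    response and enters each stratum's model as a regressor; effects are
    then tested by Type III general linear hypotheses.  A constant covariate
    triggers a collinearity warning and is dropped (results then equal
    :func:`mixed_rm_anova`).
    """
    df = validate_condition_table(table, value)
    if covariate not in df.columns:
        raise ValidationError(f"covariate column {covariate!r} not in table")
    y, groups, _ = _cell_matrix(df, value)
    z, _, _ = _cell_matrix(df, covariate)
    levels = sorted(set(groups))
    if np.any([(np.asarray(groups) == lv).sum() < 2 for lv in levels]):
        raise DesignError("need >= 2 subjects per group")
    # effect-coded group columns
    G = np.zeros((y.shape[0], len(levels) - 1))
    for j, lv in enumerate(levels[:-1]):
        G[:, j] = np.where(groups == lv, 1.0, np.where(groups == levels[-1], -1.0, 0.0))

    def safe(ss_eff, df_eff, ss_err, df_err, name, scale):
        # a covariate identical to the response leaves ~0 in both strata:
        # report the effect as fully absorbed rather than 0/0
        tol = 1e-10 * max(scale, 1.0)
        if ss_err <= tol and ss_eff <= tol:
            return AnovaResult(name, 0.0, df_eff, df_err, 1.0, 0.0, ss_eff, ss_err)
        return _f_test(ss_eff, df_eff, ss_err, df_err, name)

    results: list[AnovaResult] = []
    for term, c in _CONTRASTS.items():
        s = y @ c
        cz = z @ c if term != "mean" else z @ _CONTRASTS["mean"]
        use_cov = np.ptp(cz) > 1e-12
        if not use_cov:
            logger.warning("confound_screen: constant covariate in stratum %s; dropped", term)
        ones = np.ones((s.size, 1))
        blocks = [ones, G] + ([cz[:, None]] if use_cov else [])
        X = np.hstack(blocks)
        g_cols = list(range(1, 1 + G.shape[1]))
        scale = float(s @ s)
        if term == "mean":
            ss_eff, df_eff, ss_err, df_err = _type3_f(s, X, g_cols)
            results.append(safe(ss_eff, df_eff, ss_err, df_err, "group", scale))
        else:
            ss_eff, df_eff, ss_err, df_err = _type3_f(s, X, [0])
            results.append(safe(ss_eff, df_eff, ss_err, df_err, term, scale))
            ss_eff, df_eff, ss_err, df_err = _type3_f(s, X, g_cols)
            results.append(safe(ss_eff, df_eff, ss_err, df_err, f"{term}:group", scale))
    return results
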