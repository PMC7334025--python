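"""Mixed repeated-measures ANOVA: oracle equivalence, degrees of freedom,
effect sizes, invariances, and the covariate screen."""

import numpy as np
import pandas as pd
import pytest

import auriclab as al
from auriclab.io_core import DesignError, ValidationError
from auriclab.stats import (
    CELLS,
    confound_screen,
    mixed_rm_anova,
    partial_eta_squared,
)

EFFECTS = [
    "group",
    "correspondence",
    "correspondence:group",
    "anteriority",
    "anteriority:group",
    "correspondence:anteriority",
    "correspondence:anteriority:group",
]


def make_table(y, groups, extra=None):
    """Long-format condition table from an (N, 4) cell matrix (CELLS order)."""
    rows = []
    for i, grp in enumerate(groups):
        for j, (c, a) in enumerate(CELLS):
            row = dict(subject=f"s{i:02d}", group=grp, correspondence=c,
                       anteriority=a, value=y[i, j])
            if extra is not None:
                row["cov"] = extra[i, j]
            rows.append(row)
    return pd.DataFrame(rows)


def enumeration_oracle(y, groups):
    """Definitional-means mixed-ANOVA sums of squares (equal group sizes).

    Independent of the implementation: every stratum is computed directly
    from marginal means of the subject x correspondence x anteriority array.
    """
    levels = sorted(set(groups))
    g = len(levels)
    n = len(groups) // g
    arr = y.reshape(len(groups), 2, 2)  # subject x corr x ant
    Y = np.stack([arr[[i for i, x in enumerate(groups) if x == lv]] for lv in levels])
    GM = Y.mean()
    subj = Y.mean(axis=(2, 3))           # g x n
    grp = subj.mean(axis=1)              # g
    A_g = Y.mean(axis=(1, 3))            # g x 2
    B_g = Y.mean(axis=(1, 2))
    a_m = Y.mean(axis=(0, 1, 3))
    b_m = Y.mean(axis=(0, 1, 2))
    ab_m = Y.mean(axis=(0, 1))
    YsA = Y.mean(axis=3)
    YsB = Y.mean(axis=2)
    AB_g = Y.mean(axis=1)
    N = g * n
    out = {}
    ss_bs = 4 * ((subj - GM) ** 2).sum()
    ss_G = 4 * n * ((grp - GM) ** 2).sum()
    out["group"] = (ss_G, g - 1, ss_bs - ss_G, N - g)
    ss_A = 2 * n * g * ((a_m - GM) ** 2).sum()
    ss_AG = 2 * n * ((A_g - grp[:, None] - a_m[None, :] + GM) ** 2).sum()
    ss_As = 2 * ((YsA - subj[:, :, None] - A_g[:, None, :] + grp[:, None, None]) ** 2).sum()
    out["correspondence"] = (ss_A, 1, ss_As, N - g)
    out["correspondence:group"] = (ss_AG, g - 1, ss_As, N - g)
    ss_B = 2 * n * g * ((b_m - GM) ** 2).sum()
    ss_BG = 2 * n * ((B_g - grp[:, None] - b_m[None, :] + GM) ** 2).sum()
    ss_Bs = 2 * ((YsB - subj[:, :, None] - B_g[:, None, :] + grp[:, None, None]) ** 2).sum()
    out["anteriority"] = (ss_B, 1, ss_Bs, N - g)
    out["anteriority:group"] = (ss_BG, g - 1, ss_Bs, N - g)
    ss_AB = n * g * ((ab_m - a_m[:, None] - b_m[None, :] + GM) ** 2).sum()
    ss_ABG = n * ((AB_g - A_g[:, :, None] - B_g[:, None, :] - ab_m[None]
                   + a_m[None, :, None] + b_m[None, None, :]
                   + grp[:, None, None] - GM) ** 2).sum()
    ss_ABs = ((Y - YsA[:, :, :, None] - YsB[:, :, None, :] - AB_g[:, None]
               + subj[:, :, None, None] + A_g[:, None, :, None]
               + B_g[:, None, None, :] - grp[:, None, None, None]) ** 2).sum()
    out["correspondence:anteriority"] = (ss_AB, 1, ss_ABs, N - g)
    out["correspondence:anteriority:group"] = (ss_ABG, g - 1, ss_ABs, N - g)
    return out


class TestOracleEquivalence:
    @pytest.mark.parametrize("n_per_group", [2, 3])
    def test_all_small_balanced_designs_match_enumeration(self, n_per_group):
        rng = np.random.default_rng(77)
        groups = ["young"] * n_per_group + ["old"] * n_per_group
        for rep in range(25):
            y = rng.normal(size=(len(groups), 4))
            results = {r.effect: r for r in mixed_rm_anova(make_table(y, groups))}
            oracle = enumeration_oracle(y, groups)
            assert set(results) == set(EFFECTS)
            for eff, (ss, dfn, sse, dfe) in oracle.items():
                r = results[eff]
                F = (ss / dfn) / (sse / dfe)
                assert r.F == pytest.approx(F, abs=1e-10, rel=1e-10)
                assert r.ss_effect == pytest.approx(ss, abs=1e-10)
                assert r.ss_error == pytest.approx(sse, abs=1e-10)
                assert (r.df_num, r.df_den) == (dfn, dfe)


class TestDegreesOfFreedom:
    @pytest.mark.parametrize(
        "n_young, n_old, df_den", [(16, 12, 26), (10, 11, 19), (3, 3, 4)]
    )
    def test_within_effect_denominator_df(self, n_young, n_old, df_den):
        rng = np.random.default_rng(1)
        groups = ["young"] * n_young + ["old"] * n_old
        res = {r.effect: r for r in mixed_rm_anova(make_table(
            rng.normal(size=(len(groups), 4)), groups))}
        assert res["correspondence"].df_den == df_den
        assert res["correspondence"].df_num == 1
        assert res["group"].df_den == df_den


class TestEffectSize:
    def test_partial_eta_squared_values(self):
        assert partial_eta_squared(3.0, 1.0) == 0.75
        assert partial_eta_squared(0.0, 5.0) == 0.0

    def test_undefined_when_both_zero(self):
        with pytest.raises(ValidationError):
            partial_eta_squared(0.0, 0.0)

    def test_identity_with_f_and_df(self, rng):
        groups = ["young"] * 5 + ["old"] * 4
        res = mixed_rm_anova(make_table(rng.normal(size=(9, 4)), groups))
        for r in res:
            expect = r.F * r.df_num / (r.F * r.df_num + r.df_den)
            assert r.eta_p2 == pytest.approx(expect, abs=1e-12)


class TestInvariances:
    def test_constant_shift_leaves_f_unchanged(self, rng):
        groups = ["young"] * 4 + ["old"] * 4
        y = rng.normal(size=(8, 4))
        res1 = mixed_rm_anova(make_table(y, groups))
        res2 = mixed_rm_anova(make_table(y + 100.0, groups))
        for a, b in zip(res1, res2):
            if a.effect == "group":
                continue  # the between effect is not shift-free in SS, F is
            assert a.F == pytest.approx(b.F, rel=1e-9)

    def test_within_level_relabeling_preserves_f(self, rng):
        groups = ["young"] * 4 + ["old"] * 4
        y = rng.normal(size=(8, 4))
        swapped = y[:, [2, 3, 0, 1]]  # swap ipsi <-> contra
        res1 = {r.effect: r for r in mixed_rm_anova(make_table(y, groups))}
        res2 = {r.effect: r for r in mixed_rm_anova(make_table(swapped, groups))}
        for eff in EFFECTS:
            assert res1[eff].F == pytest.approx(res2[eff].F, rel=1e-9)


class TestValidation:
    def test_unbalanced_subject_named(self, rng):
        groups = ["young"] * 3 + ["old"] * 3
        tab = make_table(rng.normal(size=(6, 4)), groups)
        tab = tab[~((tab.subject == "s02") & (tab.correspondence == "ipsi")
                    & (tab.anteriority == "back"))]
        with pytest.raises(DesignError, match="s02"):
            mixed_rm_anova(tab)

    def test_single_subject_group_rejected(self, rng):
        groups = ["young"] * 4 + ["old"]
        with pytest.raises(DesignError):
            mixed_rm_anova(make_table(rng.normal(size=(5, 4)), groups))


class TestConfoundScreen:
    def test_zero_covariate_matches_plain_anova(self, rng):
        groups = ["young"] * 5 + ["old"] * 5
        y = rng.normal(size=(10, 4))
        tab = make_table(y, groups, extra=np.zeros((10, 4)))
        plain = {r.effect: r for r in mixed_rm_anova(tab)}
        screened = {r.effect: r for r in confound_screen(tab, "cov")}
        for eff in EFFECTS:
            assert screened[eff].F == pytest.approx(plain[eff].F, rel=1e-9)
            assert screened[eff].p == pytest.approx(plain[eff].p, abs=1e-12)

    def test_covariate_equal_to_response_absorbs_effect(self, rng):
        groups = ["young"] * 5 + ["old"] * 5
        y = rng.normal(size=(10, 4))
        y[:, :2] += 2.0  # strong correspondence effect
        tab = make_table(y, groups, extra=y)
        screened = {r.effect: r for r in confound_screen(tab, "cov")}
        assert screened["correspondence"].F < 1e-6

    def test_independent_covariate_leaves_effect_intact(self, rng):
        groups = ["young"] * 8 + ["old"] * 8
        y = rng.normal(size=(16, 4))
        y[:, :2] += 3.0
        cov = rng.normal(size=(16, 4))
        tab = make_table(y, groups, extra=cov)
        plain = {r.effect: r for r in mixed_rm_anova(tab)}
        screened = {r.effect: r for r in confound_screen(tab, "cov")}
        assert screened["correspondence"].F == pytest.approx(
            plain["correspondence"].F, rel=0.25
        )
        assert screened["correspondence"].p < 0.001
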