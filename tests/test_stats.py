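"""Normality screening, mixed rm-ANOVA, contrasts, TSBKY FDR, regression."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from coordkin.stats import (
    AnovaSpec,
    InferenceError,
    bky_fdr,
    cohens_d,
    mixed_rm_anova,
    pairwise_with_d,
    regress_r2,
    screen_and_transform,
)


class TestScreening:
    def test_normal_sample_passes_unchanged(self):
        x = np.random.default_rng(0).normal(0, 1, 100)
        res = screen_and_transform(x)
        assert not res.rejected_normality
        np.testing.assert_array_equal(res.x, x)

    def test_lognormal_sample_transformed_to_normality(self):
        x = np.exp(np.random.default_rng(1).normal(0, 1, 200))
        res = screen_and_transform(x)
        assert res.rejected_normality and res.lmbda is not None
        assert not screen_and_transform(res.x).rejected_normality

    def test_unit_lambda_is_affine(self):
        # Box-Cox with lambda = 1 maps x -> x - 1: a pure shift
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = sps.boxcox(x, lmbda=1.0)
        np.testing.assert_allclose(y, x - 1.0, atol=1e-12)

    def test_constant_sample_passes_through(self):
        res = screen_and_transform(np.full(10, 2.0))
        assert not res.rejected_normality

    def test_negative_values_shifted_before_boxcox(self):
        x = np.exp(np.random.default_rng(2).normal(0, 1, 150)) - 5.0
        res = screen_and_transform(x)
        assert res.shift > 0 and np.isfinite(res.x).all()


def _hand_ss_oracle(df):
    """Split-plot sums of squares from cell totals (textbook formulas),
    for a 2-group x 2-within design with n subjects per group."""
    piv = df.pivot_table(index=["group", "subject"], columns="phase", values="y")
    a_levels = piv.index.get_level_values(0).unique()
    b_levels = piv.columns
    a, b = len(a_levels), len(b_levels)
    N = piv.shape[0]
    T = piv.values.sum()
    CT = T**2 / (N * b)
    ss_between_subjects = (piv.values.sum(axis=1) ** 2 / b).sum() - CT
    Tg = piv.groupby(level=0).sum().sum(axis=1)
    ng = piv.groupby(level=0).size()
    ss_A = float((Tg**2 / (ng * b)).sum() - CT)
    ss_subj = ss_between_subjects - ss_A
    Tb = piv.sum(axis=0)
    ss_B = float((Tb**2 / N).sum() - CT)
    Tgb = piv.groupby(level=0).sum()
    ss_cells_gb = float((Tgb.values**2 / (ng.values[:, None])).sum() - CT)
    ss_AB = ss_cells_gb - ss_A - ss_B
    ss_total = float((piv.values**2).sum() - CT)
    ss_BS = ss_total - ss_between_subjects - ss_B - ss_AB
    return dict(
        A=(ss_A, a - 1, ss_subj, N - a),
        B=(ss_B, b - 1, ss_BS, (N - a) * (b - 1)),
        AB=(ss_AB, (a - 1) * (b - 1), ss_BS, (N - a) * (b - 1)),
    )


@pytest.fixture(scope="module")
def fixture_2x2():
    vals = {
        1: ("A", 3, 5), 2: ("A", 4, 7), 3: ("A", 2, 4), 4: ("A", 5, 8),
        5: ("B", 6, 6), 6: ("B", 7, 8), 7: ("B", 5, 5), 8: ("B", 8, 9),
    }
    rows = []
    for s, (g, pre, post) in vals.items():
        rows.append(dict(subject=s, group=g, phase="post", y=post))
        rows.append(dict(subject=s, group=g, phase="pre", y=pre))
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_matches_hand_worked_ss_oracle(self, fixture_2x2):
        spec = AnovaSpec(response="y", subject="subject",
                         between="group", within=("phase",))
        got = {r.effect: r for r in mixed_rm_anova(fixture_2x2, spec)}
        oracle = _hand_ss_oracle(fixture_2x2)
        for effect, key in (("group", "A"), ("phase", "B"), ("group x phase", "AB")):
            ss_e, df_e, ss_err, df_err = oracle[key]
            F = (ss_e / df_e) / (ss_err / df_err)
            assert got[effect].F == pytest.approx(F, abs=1e-9)
            assert got[effect].partial_eta_sq == pytest.approx(
                ss_e / (ss_e + ss_err), abs=1e-9
            )
            assert (got[effect].df_num, got[effect].df_den) == (df_e, df_err)

    def test_matches_pingouin_mixed_anova(self, fixture_2x2):
        pg = pytest.importorskip("pingouin")
        spec = AnovaSpec(response="y", subject="subject",
                         between="group", within=("phase",))
        got = {r.effect: r for r in mixed_rm_anova(fixture_2x2, spec)}
        ref = pg.mixed_anova(data=fixture_2x2, dv="y", within="phase",
                             between="group", subject="subject")
        for src, effect in (("group", "group"), ("phase", "phase"),
                            ("Interaction", "group x phase")):
            row = ref[ref["Source"] == src].iloc[0]
            assert got[effect].F == pytest.approx(row["F"], abs=1e-9)
            assert got[effect].p == pytest.approx(row["p_unc"], abs=1e-9)

    def test_two_within_factors_match_statsmodels(self):
        sm = pytest.importorskip("statsmodels.stats.anova")
        rng = np.random.default_rng(0)
        rows = []
        for s in range(10):
            for b in ("x", "y"):
                for d in ("p", "q", "r"):
                    rows.append(
                        dict(subject=s, B=b, D=d,
                             y=rng.normal() + (0.5 if b == "x" else 0))
                    )
        df = pd.DataFrame(rows)
        spec = AnovaSpec(response="y", subject="subject", within=("B", "D"))
        got = {r.effect: r for r in mixed_rm_anova(df, spec)}
        ref = sm.AnovaRM(df, "y", "subject", within=["B", "D"]).fit().anova_table
        for eff, key in (("B", "B"), ("D", "D"), ("B x D", "B:D")):
            assert got[eff].F == pytest.approx(ref.loc[key, "F Value"], abs=1e-9)

    def test_null_data_mostly_nonsignificant(self):
        rng = np.random.default_rng(3)
        rows = [
            dict(subject=s, group="A" if s < 6 else "B", w=w, y=rng.normal())
            for s in range(12) for w in ("u", "v")
        ]
        res = mixed_rm_anova(
            pd.DataFrame(rows),
            AnovaSpec(response="y", subject="subject",
                      between="group", within=("w",)),
        )
        assert all(r.p > 0.05 for r in res)

    def test_location_shift_leaves_F_unchanged(self, fixture_2x2):
        spec = AnovaSpec(response="y", subject="subject",
                         between="group", within=("phase",))
        base = mixed_rm_anova(fixture_2x2, spec)
        shifted = fixture_2x2.assign(y=fixture_2x2["y"] + 100.0)
        moved = mixed_rm_anova(shifted, spec)
        for r0, r1 in zip(base, moved):
            assert r1.F == pytest.approx(r0.F, rel=1e-9)

    def test_incomplete_subject_listwise_deleted(self, fixture_2x2):
        df = fixture_2x2[~((fixture_2x2.subject == 8) & (fixture_2x2.phase == "pre"))]
        spec = AnovaSpec(response="y", subject="subject",
                         between="group", within=("phase",))
        res = mixed_rm_anova(df, spec)
        # subject 8 dropped -> error df shrinks by one
        assert {r.effect: r for r in res}["group"].df_den == 5

    def test_single_level_factor_rejected(self, fixture_2x2):
        df = fixture_2x2[fixture_2x2.phase == "pre"]
        with pytest.raises(InferenceError):
            mixed_rm_anova(
                df,
                AnovaSpec(response="y", subject="subject",
                          between="group", within=("phase",)),
            )


class TestPairwise:
    def test_identical_groups_zero_d(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = pairwise_with_d([("same", x, x.copy())])
        assert res[0].cohen_d == 0.0

    def test_unit_shift_gaussians_d_near_one(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 50), rng.normal(1, 1, 50)
        res = pairwise_with_d([("shift", a, b)])
        assert -1.3 <= res[0].cohen_d <= -0.7  # a below b

    def test_paired_degenerate_guarded(self):
        a = np.arange(10.0)
        with pytest.raises(InferenceError):
            pairwise_with_d([("const", a + 2.0, a)], paired=True)

    def test_paired_d_definition(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, 30)
        b = a + rng.normal(0.5, 0.3, 30)
        d = cohens_d(a, b, paired=True)
        diff = a - b
        assert d == pytest.approx(diff.mean() / diff.std(ddof=1))


class TestBkyFdr:
    PVEC = [0.001, 0.008, 0.039, 0.041, 0.042, 0.06, 0.074, 0.205, 0.212,
            0.216, 0.222, 0.251, 0.269, 0.275, 0.34, 0.341, 0.384, 0.569,
            0.594, 0.696, 0.762, 0.94, 0.942, 0.975, 0.986]

    def test_all_ones_reject_nothing(self):
        flags, _ = bky_fdr([1.0] * 10)
        assert not flags.any()

    def test_all_zeros_reject_everything(self):
        flags, _ = bky_fdr([0.0] * 10)
        assert flags.all()

    @staticmethod
    def _manual_two_stage(pvals, alpha):
        """Literal step-by-step trace of the two-stage procedure."""
        m = len(pvals)
        a1 = alpha / (1 + alpha)
        order = sorted(range(m), key=lambda i: pvals[i])

        def step_up(level):
            kmax = 0
            for rank, i in enumerate(order, start=1):
                if pvals[i] <= rank * level / m:
                    kmax = rank
            return set(order[:kmax])

        r1 = len(step_up(a1))
        if r1 == 0:
            return set()
        if r1 == m:
            return set(range(m))
        return step_up(a1 * m / (m - r1))

    def test_25_element_vector_matches_manual_trace(self):
        flags, _ = bky_fdr(self.PVEC, alpha=0.05)
        manual = self._manual_two_stage(self.PVEC, 0.05)
        assert set(np.nonzero(flags)[0]) == manual
        # on this vector only the smallest p survives both stages
        assert manual == {0}

    def test_agrees_with_statsmodels_on_random_vectors(self):
        mt = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(6)
        for _ in range(200):
            m = int(rng.integers(1, 40))
            p = rng.uniform(0, 1, m) ** rng.uniform(0.5, 3)
            mine, _ = bky_fdr(p, 0.05)
            ref = mt.multipletests(p, 0.05, method="fdr_tsbky")[0]
            np.testing.assert_array_equal(mine, ref)

    def test_dominates_bh_at_shrunk_level(self):
        # TSBKY rejects at least as much as plain BH run at alpha/(1+alpha)
        from coordkin.stats import _bh_rejections

        rng = np.random.default_rng(7)
        for _ in range(1000):
            m = int(rng.integers(1, 30))
            p = rng.uniform(0, 1, m) ** rng.uniform(0.5, 4)
            tsbky, _ = bky_fdr(p, 0.05)
            bh = _bh_rejections(p, 0.05 / 1.05)
            assert tsbky.sum() >= bh.sum()

    def test_flags_returned_in_input_order(self):
        p = [0.9, 0.0001, 0.8]
        flags, _ = bky_fdr(p)
        assert flags[1] and not flags[0] and not flags[2]

    def test_empty_input(self):
        flags, lvl = bky_fdr([])
        assert flags.size == 0


class TestRegression:
    def test_exact_line_r2_one(self):
        x = np.arange(10.0)
        r2, p, slope = regress_r2(x, 2 * x)
        assert r2 == pytest.approx(1.0) and slope == pytest.approx(2.0)

    def test_independent_samples_low_r2(self):
        rng = np.random.default_rng(8)
        r2, _p, _ = regress_r2(rng.normal(0, 1, 100), rng.normal(0, 1, 100))
        assert r2 < 0.05

    def test_r2_equals_squared_pearson(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0, 1, 40)
        y = 0.5 * x + rng.normal(0, 1, 40)
        r2, _, _ = regress_r2(x, y)
        assert r2 == pytest.approx(sps.pearsonr(x, y).statistic ** 2, abs=1e-12)

    def test_constant_predictor_rejected(self):
        with pytest.raises(InferenceError):
            regress_r2(np.ones(10), np.arange(10.0))
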