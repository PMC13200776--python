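import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from dfigrade.agreement_stats import (
    AgreementError,
    ICCType,
    ICCUnit,
    RaterTable,
    bland_altman,
    classify_alpha,
    classify_icc,
    cronbach_alpha,
    icc_two_way,
    paired_change_test,
    spearman_rho,
)

from _oracles import cronbach_oracle, icc_oracle


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman_rho([1, 2, 3, 4], [10, 20, 25, 80]) == pytest.approx(1.0)

    def test_perfect_inverse(self):
        x = [1.0, 2.5, 3.0, 7.0]
        assert spearman_rho(x, x[::-1]) == pytest.approx(-1.0)

    def test_hand_ranked_example(self):
        assert spearman_rho([1, 2, 3, 4, 5], [1, 3, 2, 5, 4]) == pytest.approx(0.8)

    def test_constant_vector_rejected(self):
        with pytest.raises(AgreementError, match="zero rank variance"):
            spearman_rho([1, 2, 3], [4, 4, 4])


class TestBlandAltman:
    def test_identical_vectors(self):
        r = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (r.bias, r.sd_bias, r.loa_low, r.loa_high, r.n_outside) == (0, 0, 0, 0, 0)

    def test_constant_offset(self):
        r = bland_altman([12.0, 22.0, 32.0], [10.0, 20.0, 30.0])
        assert r.bias == pytest.approx(2.0)
        assert r.sd_bias == 0.0

    def test_hand_computed_triple(self):
        r = bland_altman([10, 20, 30], [12, 18, 33])
        assert r.bias == pytest.approx(-1.0)
        assert r.sd_bias == pytest.approx(np.sqrt(7), abs=1e-12)
        assert r.loa_low == pytest.approx(-1.0 - 1.96 * np.sqrt(7))
        assert r.loa_high == pytest.approx(-1.0 + 1.96 * np.sqrt(7))

    def test_length_mismatch_rejected(self):
        with pytest.raises(AgreementError):
            bland_altman([1, 2, 3], [1, 2])

    def test_few_outliers_for_normal_differences(self):
        rng = np.random.default_rng(20)
        n = 200
        b = rng.uniform(20, 80, n)
        a = b + rng.normal(0, 5, n)
        r = bland_altman(a, b)
        assert r.n_outside <= int(np.ceil(0.05 * n)) + 2


class TestICC:
    def test_toy_table_matches_brute_force_oracle(self, toy_rater_table):
        table = RaterTable(toy_rater_table)
        oracle = icc_oracle(toy_rater_table)
        # values frozen from the oracle
        assert oracle["consistency_single"] == pytest.approx(0.9660056657223797)
        assert oracle["absolute_average"] == pytest.approx(0.9827089337175793)
        for typ, unit, key in [
            (ICCType.CONSISTENCY, ICCUnit.SINGLE, "consistency_single"),
            (ICCType.CONSISTENCY, ICCUnit.AVERAGE, "consistency_average"),
            (ICCType.ABSOLUTE_AGREEMENT, ICCUnit.SINGLE, "absolute_single"),
            (ICCType.ABSOLUTE_AGREEMENT, ICCUnit.AVERAGE, "absolute_average"),
        ]:
            got = icc_two_way(table, typ, unit).icc_value
            assert got == pytest.approx(oracle[key], abs=1e-9)

    def test_random_small_tables_match_oracle(self):
        """All four forms agree with the from-definition ANOVA oracle on
        random integer tables up to 6x4."""
        rng = np.random.default_rng(99)
        for _ in range(200):
            n = rng.integers(2, 7)
            k = rng.integers(2, 5)
            vals = rng.integers(0, 11, size=(n, k)).astype(float)
            if np.ptp(vals.mean(axis=1)) == 0 or np.allclose(vals, vals.mean()):
                continue
            oracle = icc_oracle(vals)
            if oracle["mse"] <= 1e-12 or oracle["msr"] <= 1e-12:
                continue
            table = RaterTable(vals)
            for typ, unit, key in [
                (ICCType.CONSISTENCY, ICCUnit.SINGLE, "consistency_single"),
                (ICCType.CONSISTENCY, ICCUnit.AVERAGE, "consistency_average"),
                (ICCType.ABSOLUTE_AGREEMENT, ICCUnit.SINGLE, "absolute_single"),
                (ICCType.ABSOLUTE_AGREEMENT, ICCUnit.AVERAGE, "absolute_average"),
            ]:
                assert icc_two_way(table, typ, unit).icc_value == pytest.approx(
                    oracle[key], abs=1e-9
                )

    def test_identical_raters_give_unity(self):
        vals = np.array([[1.0], [4.0], [9.0], [2.0]]) @ np.ones((1, 3))
        table = RaterTable(vals)
        for typ in ICCType:
            for unit in ICCUnit:
                rep = icc_two_way(table, typ, unit)
                assert rep.icc_value == pytest.approx(1.0)
                assert rep.significant

    def test_pure_noise_columns_near_zero(self):
        rng = np.random.default_rng(1234)
        vals = rng.normal(size=(500, 3))
        rep = icc_two_way(RaterTable(vals), ICCType.CONSISTENCY, ICCUnit.SINGLE)
        assert abs(rep.icc_value) < 0.1

    def test_zero_between_subject_variance_degenerate(self):
        vals = np.array([[1.0, 2.0, 3.0], [3.0, 1.0, 2.0], [2.0, 3.0, 1.0]])
        rep = icc_two_way(RaterTable(vals), ICCType.CONSISTENCY, ICCUnit.SINGLE)
        assert rep.icc_value == 0.0
        assert rep.degenerate

    def test_variance_component_recovery(self):
        """Mean ICC estimate over 500 simulated two-way tables is within 0.02
        of the closed-form population value."""
        rng = np.random.default_rng(7)
        sig_s, sig_c, sig_e = 3.0, 1.0, 2.0
        pop = sig_s**2 / (sig_s**2 + sig_c**2 + sig_e**2)
        estimates = []
        for _ in range(500):
            vals = (
                50.0
                + rng.normal(0, sig_s, size=(50, 1))
                + rng.normal(0, sig_c, size=(1, 3))
                + rng.normal(0, sig_e, size=(50, 3))
            )
            estimates.append(
                icc_two_way(RaterTable(vals), ICCType.ABSOLUTE_AGREEMENT,
                            ICCUnit.SINGLE).icc_value
            )
        assert abs(np.mean(estimates) - pop) < 0.02

    def test_cross_check_against_pingouin(self, toy_rater_table):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        n, k = toy_rater_table.shape
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(n), k),
            "rater": np.tile(np.arange(k), n),
            "score": toy_rater_table.ravel(),
        })
        res = pingouin.intraclass_corr(df, targets="subject", raters="rater",
                                       ratings="score").set_index("Type")
        table = RaterTable(toy_rater_table)
        pairs = [
            ("ICC(C,1)", ICCType.CONSISTENCY, ICCUnit.SINGLE),
            ("ICC(C,k)", ICCType.CONSISTENCY, ICCUnit.AVERAGE),
            ("ICC(A,1)", ICCType.ABSOLUTE_AGREEMENT, ICCUnit.SINGLE),
            ("ICC(A,k)", ICCType.ABSOLUTE_AGREEMENT, ICCUnit.AVERAGE),
        ]
        for ptype, typ, unit in pairs:
            assert icc_two_way(table, typ, unit).icc_value == pytest.approx(
                float(res.loc[ptype, "ICC"]), abs=1e-6
            )


class TestCronbachAlpha:
    def test_identical_columns_unity(self):
        vals = np.array([[1.0], [4.0], [9.0]]) @ np.ones((1, 4))
        assert cronbach_alpha(RaterTable(vals)) == pytest.approx(1.0)

    def test_uncorrelated_columns_near_zero(self):
        rng = np.random.default_rng(55)
        vals = rng.normal(size=(2000, 2))
        assert abs(cronbach_alpha(RaterTable(vals))) < 0.1

    def test_matches_definition_oracle(self, toy_rater_table):
        assert cronbach_alpha(RaterTable(toy_rater_table)) == pytest.approx(
            cronbach_oracle(toy_rater_table), abs=1e-12
        )

    @settings(deadline=None, max_examples=60)
    @given(
        vals=arrays(
            float,
            st.tuples(st.integers(3, 8), st.integers(2, 5)),
            elements=st.floats(0, 10, allow_nan=False, width=32),
        )
    )
    def test_alpha_equals_consistency_average_icc(self, vals):
        """Algebraic identity: Cronbach alpha == two-way consistency,
        average-measures ICC."""
        vals = np.asarray(vals, dtype=float)
        if np.var(vals.sum(axis=1)) < 1e-8 or np.var(vals.mean(axis=1)) < 1e-8:
            return
        table = RaterTable(vals)
        alpha = cronbach_alpha(table)
        icc = icc_two_way(table, ICCType.CONSISTENCY, ICCUnit.AVERAGE).icc_value
        assert alpha == pytest.approx(icc, abs=1e-9)

    def test_zero_total_variance_rejected(self):
        with pytest.raises(AgreementError):
            cronbach_alpha(RaterTable(np.array([[1.0, 2.0], [2.0, 1.0]])))


class TestClassification:
    @pytest.mark.parametrize("icc,label", [
        (0.828, "excellent"), (0.75, "excellent"), (0.74, "good"), (0.6, "good"),
        (0.59, "fair"), (0.4, "fair"), (0.39, "unacceptable"), (-0.2, "unacceptable"),
    ])
    def test_icc_bins(self, icc, label):
        assert classify_icc(icc) == label

    @pytest.mark.parametrize("alpha,label", [
        (0.95, "excellent"), (0.9, "excellent"), (0.89, "good"), (0.8, "good"),
        (0.79, "fair"), (0.7, "fair"), (0.69, "unacceptable"),
    ])
    def test_alpha_bins(self, alpha, label):
        assert classify_alpha(alpha) == label


class TestPairedChangeTest:
    def test_normal_differences_use_paired_t(self):
        rng = np.random.default_rng(8)
        pre = rng.normal(50, 10, 40)
        post = pre + rng.normal(5, 3, 40)
        res = paired_change_test(pre, post)
        assert res["test_used"] == "paired t"
        assert res["p"] < 0.05

    def test_skewed_differences_use_wilcoxon(self):
        rng = np.random.default_rng(9)
        pre = rng.normal(50, 5, 60)
        post = pre + rng.lognormal(1.0, 1.2, 60)  # heavily right-skewed change
        res = paired_change_test(pre, post)
        assert res["test_used"] == "Wilcoxon signed-rank"
        assert res["p"] < 0.05

    def test_identical_pre_post_rejected(self):
        x = np.arange(10, dtype=float)
        with pytest.raises(AgreementError, match="degenerate differences"):
            paired_change_test(x, x)


class TestRaterTable:
    def test_missing_cells_rejected(self):
        vals = np.array([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(AgreementError):
            RaterTable(vals)

    def test_listwise_deletion_from_dataframe(self):
        import pandas as pd

        df = pd.DataFrame({"r1": [1.0, 2.0, np.nan], "r2": [2.0, 3.0, 4.0]},
                          index=["a", "b", "c"])
        table = RaterTable.from_dataframe(df)
        assert table.n == 2
        assert table.subject_ids == ["a", "b"]

    def test_too_small_rejected(self):
        with pytest.raises(AgreementError):
            RaterTable(np.array([[1.0, 2.0]]))
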