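"""Delta referencing, RM-ANOVA/Tukey, ICC, Pearson, power and units."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from kneestress.errors import (
    DataError,
    DegenerateDataError,
    DesignError,
    ParameterError,
)
from kneestress.stats import (
    compute_deltas,
    icc_two_readers,
    kilopond_to_newton,
    pearson,
    required_sample_size,
    rm_anova_tukey,
    two_sample_t_power,
)

CELLS = [("intact", "d0"), ("intact", "d1"), ("partial", "d0"),
         ("partial", "d1"), ("complete", "d0"), ("complete", "d1")]


def long_table(values: np.ndarray, measure="y_ABI") -> pd.DataFrame:
    """values[subject, cell] -> long study table."""
    rows = []
    for s in range(values.shape[0]):
        for c, (cond, conf) in enumerate(CELLS):
            rows.append({"specimen": f"S{s:02d}", "condition": cond,
                         "configuration": conf, "measure": measure,
                         "value": float(values[s, c])})
    return pd.DataFrame(rows)


class TestComputeDeltas:
    def test_published_mean_arithmetic(self, published_means_table):
        deltas = compute_deltas(published_means_table)
        d = deltas.set_index(["measure", "condition", "configuration"])["value"]
        assert d["y_ABI", "partial", "d1"] == pytest.approx(8.1)
        assert d["y_ABI", "complete", "d1"] == pytest.approx(12.6)
        assert d["y_landmarks", "partial", "d1"] == pytest.approx(11.4)
        assert d["y_landmarks", "complete", "d1"] == pytest.approx(14.8)
        assert d["LTP_LFC", "intact", "d1"] == pytest.approx(-3.0)

    def test_reference_cell_is_zero(self, published_means_table):
        deltas = compute_deltas(published_means_table)
        ref = deltas[(deltas["condition"] == "intact") & (deltas["configuration"] == "d0")]
        assert (ref["value"] == 0).all()

    def test_missing_reference_cell(self):
        values = np.arange(12, dtype=float).reshape(2, 6)
        table = long_table(values)
        broken = table[~((table["specimen"] == "S01") & (table["condition"] == "intact")
                         & (table["configuration"] == "d0"))]
        with pytest.raises(DesignError, match="S01"):
            compute_deltas(broken)

    def test_mean_delta_equals_difference_of_cell_means(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=(10, 6))
        deltas = compute_deltas(long_table(values))
        wide = deltas.pivot(index="specimen",
                            columns=["condition", "configuration"], values="value")
        for c, (cond, conf) in enumerate(CELLS):
            expected = values[:, c].mean() - values[:, 0].mean()
            assert wide[(cond, conf)].mean() == pytest.approx(expected)

    def test_per_condition_reference(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=(4, 6))
        deltas = compute_deltas(long_table(values), reference="per_condition_d0")
        wide = deltas.pivot(index="specimen",
                            columns=["condition", "configuration"], values="value")
        for cond in ("intact", "partial", "complete"):
            assert (wide[(cond, "d0")] == 0).all()


def manual_rm_anova(values: np.ndarray):
    """Textbook one-way within-subject ANOVA decomposition (oracle)."""
    n, k = values.shape
    grand = values.mean()
    ss_cells = n * ((values.mean(axis=0) - grand) ** 2).sum()
    ss_subjects = k * ((values.mean(axis=1) - grand) ** 2).sum()
    ss_total = ((values - grand) ** 2).sum()
    ss_error = ss_total - ss_cells - ss_subjects
    df1, df2 = k - 1, (n - 1) * (k - 1)
    f = (ss_cells / df1) / (ss_error / df2)
    return f, float(sps.f.sf(f, df1, df2)), ss_error / df2


class TestRmAnovaTukey:
    def test_matches_sum_of_squares_oracle(self):
        rng = np.random.default_rng(7)
        values = rng.normal(size=(10, 6)) + np.array([0, 1, 0, 2, 0, 3.0])
        res = rm_anova_tukey(long_table(values), "y_ABI")
        f, p, mse = manual_rm_anova(values)
        assert res.f_value == pytest.approx(f, rel=1e-8)
        assert res.p_value == pytest.approx(p, rel=1e-6)
        assert res.ms_error == pytest.approx(mse, rel=1e-8)
        assert res.df_error == 45

    def test_tukey_uses_studentized_range(self):
        rng = np.random.default_rng(8)
        values = rng.normal(size=(8, 6)) + np.array([0, 0, 0, 5, 0, 9.0])
        res = rm_anova_tukey(long_table(values), "y_ABI")
        _, _, mse = manual_rm_anova(values)
        row = res.tukey.iloc[0]
        q_expected = abs(row["mean_diff"]) / np.sqrt(mse / 8)
        assert row["q"] == pytest.approx(q_expected, rel=1e-8)
        # the largest contrast must be flagged significant
        big = res.tukey[(res.tukey["cell_a"] == "intact_d0")
                        & (res.tukey["cell_b"] == "complete_d1")].iloc[0]
        assert big["significant"]

    def test_all_equal_degenerate_path(self):
        res = rm_anova_tukey(long_table(np.full((10, 6), 3.25)), "y_ABI")
        assert res.p_value == 1.0
        assert not res.significant
        assert not res.tukey["significant"].any()

    def test_incomplete_design(self):
        values = np.arange(12, dtype=float).reshape(2, 6)
        table = long_table(values)
        with pytest.raises(DesignError):
            rm_anova_tukey(table[table["configuration"] == "d0"], "y_ABI")

    def test_invariant_to_constant_shift_and_relabeling(self):
        rng = np.random.default_rng(9)
        values = rng.normal(size=(6, 6)) + np.array([0, 1, 0, 2, 0, 3.0])
        base = rm_anova_tukey(long_table(values), "y_ABI")
        shifted = rm_anova_tukey(long_table(values + 17.3), "y_ABI")
        assert shifted.p_value == pytest.approx(base.p_value, rel=1e-9)
        relabeled = long_table(values)
        relabeled["specimen"] = relabeled["specimen"].map(
            lambda s: f"K{99 - int(s[1:]):02d}")
        assert rm_anova_tukey(relabeled, "y_ABI").p_value == pytest.approx(
            base.p_value, rel=1e-9)

    def test_detects_study_scale_effects(self):
        # loading effects of 0 / 8.1 / 12.6 mm at d1 with 3 mm within-specimen
        # noise are detected at p <= 0.01 in at least 90% of replicates
        effects = np.array([0, 0, 0, 8.1, 0, 12.6])
        hits = 0
        n_reps = 200
        rng = np.random.default_rng(12345)
        for _ in range(n_reps):
            subj = rng.normal(0, 2, size=(10, 1))
            values = subj + effects + rng.normal(0, 3, size=(10, 6))
            if rm_anova_tukey(long_table(values), "y_ABI").p_value <= 0.01:
                hits += 1
        assert hits / n_reps >= 0.90


class TestIcc:
    def test_duplicate_readers(self):
        a = np.random.default_rng(0).normal(size=12)
        assert icc_two_readers(a, a.copy()) == pytest.approx(1.0)

    def test_independent_noise_is_near_zero(self):
        rng = np.random.default_rng(1)
        assert abs(icc_two_readers(rng.normal(size=400), rng.normal(size=400))) < 0.15

    def test_common_affine_invariance(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=30)
        b = a + rng.normal(0, 0.3, size=30)
        assert icc_two_readers(2.0 * a + 5.0, 2.0 * b + 5.0) == pytest.approx(
            icc_two_readers(a, b), abs=1e-10)

    def test_reader_noise_regime(self):
        # reader noise at one fifth of the between-target SD puts agreement
        # in the near-perfect regime the 2D measures are designed for
        rng = np.random.default_rng(3)
        truth = rng.normal(0, 5.0, size=60)
        sd = truth.std() / 5
        a = truth + rng.normal(0, sd, size=60)
        b = truth + rng.normal(0, sd, size=60)
        assert icc_two_readers(a, b) >= 0.95

    def test_too_few_pairs(self):
        with pytest.raises(DataError):
            icc_two_readers([1.0], [1.0])


class TestPearson:
    def test_perfect_correlations(self):
        x = np.arange(10.0)
        assert pearson(x, x) == pytest.approx(1.0)
        assert pearson(x, -x) == pytest.approx(-1.0)

    def test_zero_variance(self):
        with pytest.raises(DegenerateDataError):
            pearson(np.ones(5), np.arange(5.0))

    def test_too_short(self):
        with pytest.raises(DataError):
            pearson([1.0, 2.0], [3.0, 4.0])


class TestPowerAndUnits:
    def test_study_sample_size(self):
        assert required_sample_size(0.8, 0.05, 1.6, "two") == 8

    def test_huge_effect_floor(self):
        assert required_sample_size(0.8, 0.05, 50.0, "two") == 2

    def test_matches_statsmodels_oracle(self):
        from statsmodels.stats.power import TTestIndPower
        continuous = TTestIndPower().solve_power(effect_size=0.8, alpha=0.05,
                                                 power=0.8, alternative="two-sided")
        assert required_sample_size(0.8, 0.05, 0.8, "two") == int(np.ceil(continuous))
        # boundary property: n-1 under-powers, n reaches the target
        n = required_sample_size(0.8, 0.05, 0.8, "two")
        assert two_sample_t_power(n - 1, 0.8, 0.05) < 0.8 <= two_sample_t_power(n, 0.8, 0.05)

    def test_invalid_parameters(self):
        with pytest.raises(ParameterError):
            required_sample_size(1.5, 0.05, 1.0)
        with pytest.raises(ParameterError):
            required_sample_size(0.8, 0.05, -1.0)

    @pytest.mark.parametrize("kp, newton", [(15.0, 147.09975), (0.0, 0.0),
                                            (1.0, 9.80665)])
    def test_kilopond_conversion(self, kp, newton):
        assert kilopond_to_newton(kp) == pytest.approx(newton)

    def test_loading_force_rounds_to_147(self):
        assert round(kilopond_to_newton(15.0)) == 147

    def test_negative_force_rejected(self):
        with pytest.raises(ParameterError):
            kilopond_to_newton(-1.0)
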