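"""Block ANOVA against a design-matrix oracle; exact and GLM categorical tests."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from penflux import design

DOSES = (0.0, 1.38, 5.5, 22.0)
SEXES = ("steer", "heifer")


def random_table(rng, effects=True):
    rows = []
    block_eff = rng.normal(0, 2, 3)
    dose_eff = rng.normal(0, 1.5, 4) if effects else np.zeros(4)
    sex_eff = rng.normal(0, 1, 2) if effects else np.zeros(2)
    int_eff = rng.normal(0, 0.5, (4, 2)) if effects else np.zeros((4, 2))
    for b in range(3):
        for j, d in enumerate(DOSES):
            for k, s in enumerate(SEXES):
                rows.append(
                    {
                        "cycle": b + 1,
                        "dose": d,
                        "sex": s,
                        "value": 10
                        + block_eff[b]
                        + dose_eff[j]
                        + sex_eff[k]
                        + int_eff[j, k]
                        + rng.normal(0, 1),
                    }
                )
    return pd.DataFrame(rows)


def oracle_fit(table):
    """Independent least-squares route: statsmodels OLS + classical ANOVA."""
    fit = smf.ols(
        "value ~ C(cycle) + C(dose) + C(sex) + C(dose):C(sex)", data=table
    ).fit()
    aov = sm.stats.anova_lm(fit, typ=2)
    mse = aov.loc["Residual", "sum_sq"] / aov.loc["Residual", "df"]
    dose_means = table.groupby("dose")["value"].mean()
    contrasts = {}
    for d in DOSES[1:]:
        diff = dose_means[d] - dose_means[0.0]
        se = np.sqrt(2 * mse / 6)
        t = diff / se
        p = 2 * scipy.stats.t.sf(abs(t), int(aov.loc["Residual", "df"]))
        contrasts[d] = (diff, p)
    return aov, mse, dose_means, contrasts


class TestRcbdAgainstOracle:
    @pytest.mark.parametrize("seed", range(25))
    def test_sums_of_squares_f_lsmeans_contrasts(self, seed):
        rng = np.random.default_rng(seed)
        table = random_table(rng)
        res = design.rcbd_fit(table)
        aov, mse, dose_means, contrasts = oracle_fit(table)

        own = res.anova_table.set_index("source")
        assert own.loc["block", "ss"] == pytest.approx(aov.loc["C(cycle)", "sum_sq"], rel=1e-10)
        assert own.loc["dose", "ss"] == pytest.approx(aov.loc["C(dose)", "sum_sq"], rel=1e-10)
        assert own.loc["sex", "ss"] == pytest.approx(aov.loc["C(sex)", "sum_sq"], rel=1e-10)
        assert own.loc["dose:sex", "ss"] == pytest.approx(
            aov.loc["C(dose):C(sex)", "sum_sq"], rel=1e-10
        )
        assert own.loc["residual", "ss"] == pytest.approx(
            aov.loc["Residual", "sum_sq"], rel=1e-10
        )
        assert own.loc["dose", "F"] == pytest.approx(aov.loc["C(dose)", "F"], rel=1e-10)
        assert res.mse == pytest.approx(mse, rel=1e-10)
        # balanced design: LSMeans are arithmetic marginal means
        for d in DOSES:
            assert res.lsmeans_dose[d] == pytest.approx(dose_means[d], rel=1e-12)
        for d in DOSES[1:]:
            row = res.contrasts.set_index("dose").loc[d]
            assert row["diff"] == pytest.approx(contrasts[d][0], rel=1e-10)
            assert row["p"] == pytest.approx(contrasts[d][1], rel=1e-10)

    def test_df_partition(self):
        res = design.rcbd_fit(random_table(np.random.default_rng(0)))
        t = res.anova_table.set_index("source")
        assert t["df"].sum() == 23
        assert t.loc["residual", "df"] == 14

    def test_all_equal_responses(self):
        table = random_table(np.random.default_rng(1))
        table["value"] = 5.0
        res = design.rcbd_fit(table)
        t = res.anova_table.set_index("source")
        assert t.loc["dose", "F"] == 0 and t.loc["dose", "p"] == 1.0

    def test_zero_residual_distinct_doses(self):
        rows = [
            {"cycle": b, "dose": d, "sex": s, "value": 10 + 2 * j}
            for b in (1, 2, 3)
            for j, d in enumerate(DOSES)
            for s in SEXES
        ]
        res = design.rcbd_fit(pd.DataFrame(rows))
        assert (res.contrasts["p"] == 0).all()
        for j, d in enumerate(DOSES):
            assert res.lsmeans_dose[d] == pytest.approx(10 + 2 * j)

    def test_unbalanced_rejected(self):
        table = random_table(np.random.default_rng(2)).iloc[:-1]
        with pytest.raises(ValueError, match="unbalanced"):
            design.rcbd_fit(table)


class TestInteractionGate:
    def _result_with_interaction_p(self, target_p):
        # brute force a table whose interaction p is close to target via search
        rng = np.random.default_rng(3)
        best, best_gap = None, np.inf
        for _ in range(200):
            t = random_table(rng)
            r = design.rcbd_fit(t)
            gap = abs(r.interaction_p - target_p)
            if gap < best_gap:
                best, best_gap = r, gap
        return best

    def test_nonsignificant_interaction_pools(self):
        res = self._result_with_interaction_p(0.5)
        assert res.interaction_p > 0.05
        assert design.interaction_gate(res).route == "pooled"

    def test_significant_interaction_routes_within_sex(self):
        res = self._result_with_interaction_p(0.01)
        assert res.interaction_p <= 0.05
        gate = design.interaction_gate(res)
        assert gate.route == "within_sex"
        assert {"sex", "dose"} <= set(gate.contrasts.columns)

    def test_significance_labels(self):
        assert design.significance_label(0.04) == "significant"
        assert design.significance_label(0.05) == "significant"
        assert design.significance_label(0.07) == "tendency"
        assert design.significance_label(0.2) == "ns"


class TestFisherExact:
    def test_balanced_2x2_p_is_one(self):
        assert design.fisher_exact_2xk([[1, 1], [1, 1]]) == pytest.approx(1.0)

    def test_diagonal_table(self):
        assert design.fisher_exact_2xk([[5, 0], [0, 5]]) == pytest.approx(2 / 252)

    def test_proportional_rows_p_one(self):
        assert design.fisher_exact_2xk([[2, 4, 6], [1, 2, 3]]) == pytest.approx(1.0)

    def test_matches_scipy_on_random_2x2(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            table = rng.integers(0, 12, size=(2, 2))
            if table.sum() == 0:
                continue
            ours = design.fisher_exact_2xk(table)
            _, scipy_p = scipy.stats.fisher_exact(table, alternative="two-sided")
            assert ours == pytest.approx(scipy_p, rel=1e-9, abs=1e-12)

    def test_2xk_against_enumeration_oracle(self):
        """Direct enumeration over all first-row completions for small 2x3."""
        from itertools import product
        from math import comb

        table = np.array([[3, 1, 0], [1, 2, 4]])
        col = table.sum(axis=0)
        r1 = table[0].sum()
        n = table.sum()

        def prob(top):
            return np.prod([comb(c, a) for c, a in zip(col, top)]) / comb(n, r1)

        p_obs = prob(table[0])
        total = sum(
            prob(top)
            for top in product(*(range(c + 1) for c in col))
            if sum(top) == r1 and prob(top) <= p_obs * (1 + 1e-9)
        )
        assert design.fisher_exact_2xk(table) == pytest.approx(total, rel=1e-9)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            design.fisher_exact_2xk([[0, 0], [0, 0]])


def category_counts(rng, probs_by_dose, n=14):
    rows = []
    for cyc in (1, 2, 3):
        for d in DOSES:
            for s in SEXES:
                rows.append(
                    {
                        "cycle": cyc,
                        "dose": d,
                        "sex": s,
                        "k": rng.binomial(n, probs_by_dose[d]),
                        "n": n,
                    }
                )
    return pd.DataFrame(rows)


class TestBinomialCategoryFit:
    def test_equal_proportions_not_significant(self):
        rng = np.random.default_rng(5)
        counts = category_counts(rng, {d: 0.4 for d in DOSES})
        res = design.binomial_category_fit(counts)
        assert res.method == "binomial_glm"
        assert (res.contrasts["p"] > 0.05).all()

    def test_strong_control_excess_detected(self):
        """Control pens show the category far more often than treated pens
        (the discrete yield-grade-3 pattern); contrasts must flag it."""
        rng = np.random.default_rng(6)
        counts = category_counts(rng, {0.0: 0.65, 1.38: 0.25, 5.5: 0.25, 22.0: 0.25})
        res = design.binomial_category_fit(counts)
        assert res.method == "binomial_glm"
        assert (res.contrasts["p"] < 0.05).all()
        assert res.probs_by_dose[0.0] > res.probs_by_dose[22.0]

    def test_sparse_arm_falls_back_to_exact_test(self):
        rng = np.random.default_rng(7)
        counts = category_counts(rng, {0.0: 0.5, 1.38: 0.3, 5.5: 0.3, 22.0: 0.3})
        counts.loc[counts["dose"] == 5.5, "k"] = 0
        res = design.binomial_category_fit(counts)
        assert res.method == "fisher_fallback"
        assert 0 <= res.fallback_p <= 1
        assert res.fallback_table.shape == (2, 2)


def test_null_type_i_error_of_dose_f_test():
    """On null data the dose F-test should reject at ~ the nominal 5% rate."""
    rng = np.random.default_rng(2024)
    rejections = 0
    n_sim = 400  # quick check; the acceptance suite runs 2,000
    for _ in range(n_sim):
        y = rng.normal(0, 1, (3, 4, 2)) + rng.normal(0, 1, (3, 1, 1))
        res = design.rcbd_fit_cube(y, doses=DOSES)
        rejections += res.dose_p <= 0.05
    rate = rejections / n_sim
    assert 0.02 <= rate <= 0.08
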