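import math

import numpy as np
import pytest

from ccprs.association import (MODELS, association_scan, bonferroni,
                               contingency_or, covariate_design, covariate_table,
                               fit_logistic, model_tables)
from ccprs.errors import SeparationWarning, UndefinedStatisticError
from ccprs.freq_hwe import GenotypeCounts
from conftest import make_cohort


# -- contingency odds ratios ----------------------------------------------------


def test_equal_odds_give_or_one():
    est, p, corrected = contingency_or(((20, 80), (20, 80)))
    assert est.odds_ratio == pytest.approx(1.0)
    assert not corrected


def test_woolf_interval_matches_hand_formula():
    est, p, corrected = contingency_or(((40, 97), (17, 133)))
    assert est.odds_ratio == pytest.approx(5320 / 1649)
    se = math.sqrt(1 / 40 + 1 / 97 + 1 / 17 + 1 / 133)
    assert est.ci_low == pytest.approx((5320 / 1649) * math.exp(-1.96 * se))
    assert est.ci_high == pytest.approx((5320 / 1649) * math.exp(1.96 * se))
    assert round(est.ci_low, 2) == 1.73 and round(est.ci_high, 2) == 6.03


def test_zero_cell_triggers_haldane_anscombe_correction():
    est, p, corrected = contingency_or(((0, 10), (5, 5)))
    assert corrected
    assert est.odds_ratio == pytest.approx((0.5 * 5.5) / (10.5 * 5.5))


def test_zero_margin_is_undefined():
    with pytest.raises(UndefinedStatisticError):
        contingency_or(((0, 0), (5, 5)))


def test_group_swap_inverts_the_odds_ratio():
    table = ((13, 24), (7, 41))
    est, *_ = contingency_or(table)
    swapped, *_ = contingency_or((table[1], table[0]))
    assert swapped.odds_ratio == pytest.approx(1 / est.odds_ratio)


# -- model tables ---------------------------------------------------------------


def test_model_tables_collapse_genotype_counts():
    case = GenotypeCounts(45, 73, 19)
    control = GenotypeCounts(74, 69, 7)
    assert model_tables(case, control, "recessive") == ((19, 118), (7, 143))
    assert model_tables(case, control, "dominant") == ((92, 45), (76, 74))
    assert model_tables(case, control, "allelic_2x2") == ((111, 163), (83, 217))
    assert model_tables(case, control, "codominant") == ((45, 73, 19), (74, 69, 7))


def test_dominant_equals_recessive_without_heterozygotes():
    case = GenotypeCounts(30, 0, 12)
    control = GenotypeCounts(40, 0, 5)
    dom, *_ = contingency_or(model_tables(case, control, "dominant"))
    rec, *_ = contingency_or(model_tables(case, control, "recessive"))
    assert dom.odds_ratio == pytest.approx(rec.odds_ratio)


# -- logistic fitting -----------------------------------------------------------


def test_independent_regressor_has_zero_slope():
    y = np.array([1, 1, 0, 0] * 25, float)
    x = np.array([1, 0, 1, 0] * 25, float)
    fit = fit_logistic(y, np.column_stack([np.ones(100), x]))
    assert fit.converged
    assert fit.params[1] == pytest.approx(0.0, abs=1e-8)


def test_saturated_2x2_slope_equals_sample_log_odds_difference():
    y = np.concatenate([np.ones(137), np.zeros(150)])
    x = np.concatenate([np.repeat([1.0, 0.0], [40, 97]),
                        np.repeat([1.0, 0.0], [17, 133])])
    fit = fit_logistic(y, np.column_stack([np.ones(287), x]))
    target = math.log(40 * 133 / (97 * 17))
    assert abs(fit.params[1] - target) <= 1e-10 * abs(target)


def test_perfect_separation_is_flagged():
    y = np.concatenate([np.ones(20), np.zeros(20)])
    x = y.copy()
    with pytest.warns(SeparationWarning):
        fit = fit_logistic(y, np.column_stack([np.ones(40), x]))
    assert fit.separation and not fit.converged


def test_fit_matches_statsmodels_on_multivariate_data():
    statsmodels = pytest.importorskip("statsmodels.api")
    rng = np.random.default_rng(7)
    n = 400
    X = np.column_stack([np.ones(n), rng.binomial(2, 0.3, n),
                         rng.normal(50, 10, n), rng.integers(0, 2, n)])
    beta = np.array([-1.0, 0.6, 0.01, -0.4])
    y = (rng.random(n) < 1 / (1 + np.exp(-X @ beta))).astype(float)
    ours = fit_logistic(y, X)
    ref = statsmodels.Logit(y, X).fit(disp=0)
    np.testing.assert_allclose(ours.params, ref.params, rtol=1e-6)
    np.testing.assert_allclose(ours.loglik, ref.llf, rtol=1e-8)
    np.testing.assert_allclose(ours.se(), ref.bse, rtol=1e-5)


# -- bonferroni -----------------------------------------------------------------


def test_bonferroni_thresholds():
    eleven = bonferroni(0.05, 11)
    assert eleven.threshold == pytest.approx(0.05 / 11)
    assert eleven.display == "0.0045"
    assert bonferroni(0.05, 1).threshold == 0.05
    assert bonferroni(0.01, 5).threshold == pytest.approx(0.002)
    with pytest.raises(ValueError):
        bonferroni(0.05, 0)


# -- association scan -----------------------------------------------------------


def _scan_cohort():
    rng = np.random.default_rng(42)
    from ccprs.cohort import Locus
    loci = [Locus("L1", "A", "B", "B"), Locus("L2", "C", "D", "D")]
    n1, n0 = 120, 140
    geno = np.column_stack([
        np.concatenate([rng.binomial(2, 0.45, n1), rng.binomial(2, 0.3, n0)]),
        rng.binomial(2, 0.25, n1 + n0),
    ]).astype(float)
    status = ["case"] * n1 + ["control"] * n0
    age = rng.normal(55, 10, n1 + n0)
    sex = rng.choice(["male", "female"], n1 + n0)
    return make_cohort(loci, geno, status, age=age, sex=sex)


def test_scan_covers_every_locus_and_model():
    cohort = _scan_cohort()
    results = association_scan(cohort, MODELS, covariates=("sex", "age"))
    crude = {(r.locus_id, r.model) for r in results if not r.adjusted}
    adjusted = {(r.locus_id, r.model) for r in results if r.adjusted}
    assert crude == {(l, m) for l in ("L1", "L2") for m in MODELS}
    # allelic 2x2 has no regression representation, hence no adjusted result
    assert adjusted == {(l, m) for l in ("L1", "L2") for m in MODELS
                        if m != "allelic_2x2"}


def test_crude_results_do_not_depend_on_the_covariate_list():
    cohort = _scan_cohort()
    with_cov = association_scan(cohort, ("log_additive", "dominant"),
                                covariates=("sex", "age"))
    without = association_scan(cohort, ("log_additive", "dominant"), covariates=())
    lhs = [r.estimates[0].odds_ratio for r in with_cov if not r.adjusted]
    rhs = [r.estimates[0].odds_ratio for r in without if not r.adjusted]
    assert lhs == rhs  # bitwise-identical crude odds ratios


def test_wholly_missing_covariate_is_dropped_with_warning():
    cohort = _scan_cohort()  # smoking column is all-missing
    with pytest.warns(UserWarning, match="smoking"):
        _, names, _, dropped = covariate_design(cohort.samples, ("sex", "smoking"))
    assert "smoking" in dropped and names == ["sex_male"]


# -- covariate comparison table --------------------------------------------------


def test_sex_chi_square_matches_hand_pearson():
    # 37/100 male/female in cases vs 64/84 in controls
    sex = ["male"] * 37 + ["female"] * 100 + ["male"] * 64 + ["female"] * 84
    status = ["case"] * 137 + ["control"] * 148
    from ccprs.cohort import Locus
    cohort = make_cohort([Locus("L1", "A", "B", "B")], [[0]] * 285, status, sex=sex)
    table = covariate_table(cohort)
    row = table[table["covariate"] == "sex"].iloc[0]
    n = 285
    hand = n * (37 * 84 - 100 * 64) ** 2 / (137 * 148 * 101 * 184)
    assert row["statistic"] == pytest.approx(hand)
    assert row["statistic"] == pytest.approx(8.196, abs=0.01)


def test_identical_group_distributions_give_p_one():
    from ccprs.cohort import Locus
    status = ["case"] * 4 + ["control"] * 4
    cohort = make_cohort([Locus("L1", "A", "B", "B")], [[0]] * 8, status,
                         age=[50.0, 50.0, 60.0, 60.0] * 2,
                         sex=["male", "female"] * 4)
    table = covariate_table(cohort).set_index("covariate")
    assert table.loc["sex", "p_value"] == pytest.approx(1.0)


def test_equal_constant_ages_give_t_zero():
    from ccprs.cohort import Locus
    cohort = make_cohort([Locus("L1", "A", "B", "B")], [[0]] * 4,
                         ["case", "case", "control", "control"],
                         age=[50.0, 50.0, 50.0, 50.0])
    table = covariate_table(cohort).set_index("covariate")
    assert table.loc["age", "statistic"] == 0.0
    assert table.loc["age", "p_value"] == 1.0
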