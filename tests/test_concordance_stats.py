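"""McNemar variants, committee, Fleiss kappa, agreement, correlation."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import rankdata
from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar
from statsmodels.stats.inter_rater import fleiss_kappa as sm_fleiss
from statsmodels.stats.multitest import multipletests

from pairedeval import concordance_stats as cs
from pairedeval.selection_scoring import model_selections, quiz_accuracy
from pairedeval.synthetic_cohort import (
    SimulationConfig,
    calibrate_sigma,
    simulate_cohort,
)
from pairedeval.types import (
    ChoiceMatrix,
    PairRecord,
    RaterPerformance,
    RaterRecord,
    SelectionVector,
    ValidationError,
)


def make_matrix(choices, pair_prefix="P"):
    choices = np.asarray(choices, dtype=np.int8)
    n_raters, n_pairs = choices.shape
    pairs = [
        PairRecord(f"{pair_prefix}{j}", "A", f"p{j}", f"n{j}")
        for j in range(n_pairs)
    ]
    return ChoiceMatrix([f"R{i}" for i in range(n_raters)], pairs, choices)


def selection(values, selector="s", ties=False):
    values = np.asarray(values, dtype=float)
    return SelectionVector(
        selector, [f"P{j}" for j in range(values.size)], values, allow_ties=ties
    )


class TestDiscordantCounts:
    def test_hand_count(self):
        b, c = cs.discordant_counts(selection([1, 0, 0, 1]), selection([0, 1, 0, 1]))
        assert (b, c) == (1, 1)

    def test_identical_vectors(self):
        sel = selection([1, 0, 1])
        assert cs.discordant_counts(sel, sel) == (0, 0)

    def test_mismatched_pairs_rejected(self):
        a = selection([1, 0])
        b = SelectionVector("t", ["Q0", "Q1"], np.array([1.0, 0.0]))
        with pytest.raises(ValidationError):
            cs.discordant_counts(a, b)

    def test_ties_rejected(self):
        with pytest.raises(ValidationError, match="tie"):
            cs.discordant_counts(selection([0.5, 1], ties=True), selection([1, 0]))

    def test_matches_enumeration_on_synthetic_run(self, small_cohort):
        model = model_selections(small_cohort.pairs, small_cohort.model_scores)
        sel = small_cohort.choices.rater_selection("R01")
        b, c = cs.discordant_counts(sel, model)
        # brute-force: walk the pairs and compare correctness by hand
        mv = dict(zip(model.pair_ids, model.values))
        eb = sum(1 for pid, v in zip(sel.pair_ids, sel.values)
                 if v == 1.0 and mv[pid] == 0.0)
        ec = sum(1 for pid, v in zip(sel.pair_ids, sel.values)
                 if v == 0.0 and mv[pid] == 1.0)
        assert (b, c) == (eb, ec)
        disagreements = sum(
            1 for pid, v in zip(sel.pair_ids, sel.values) if v != mv[pid]
        )
        assert b + c == disagreements


def exact_p_enumeration(b, c):
    """Two-sided conditional binomial by explicit coefficient sums."""
    n = b + c
    if n == 0:
        return 1.0
    tail = sum(math.comb(n, k) for k in range(min(b, c) + 1)) / 2**n
    return min(1.0, 2.0 * tail)


class TestMcNemar:
    def test_study_worked_example(self):
        res = cs.mcnemar_test(127, 167)
        assert round(res.p_exact, 2) == 0.02
        assert round(res.p_chi2, 2) == 0.02
        assert round(res.p_chi2_cc, 2) == 0.02
        assert res.statistic_chi2 == pytest.approx((127 - 167) ** 2 / 294)

    def test_no_discordance_degenerate(self):
        res = cs.mcnemar_test(0, 0)
        assert res.degenerate
        assert res.p_exact == res.p_chi2 == res.p_chi2_cc == 1.0
        assert res.statistic_chi2 == 0.0

    def test_exact_matches_binomial_enumeration(self):
        res = cs.mcnemar_test(5, 15)
        assert res.p_exact == pytest.approx(exact_p_enumeration(5, 15), abs=1e-15)

    @given(b=st.integers(0, 60), c=st.integers(0, 60))
    def test_symmetry(self, b, c):
        x, y = cs.mcnemar_test(b, c), cs.mcnemar_test(c, b)
        assert x.p_exact == y.p_exact
        assert x.p_chi2 == y.p_chi2
        assert x.p_chi2_cc == y.p_chi2_cc

    @pytest.mark.parametrize("b,c", [(5, 15), (127, 167), (0, 4), (10, 10)])
    def test_cross_check_statsmodels(self, b, c):
        table = [[0, b], [c, 0]]
        res = cs.mcnemar_test(b, c)
        assert res.p_exact == pytest.approx(
            sm_mcnemar(table, exact=True).pvalue, abs=1e-12
        )
        assert res.p_chi2_cc == pytest.approx(
            sm_mcnemar(table, exact=False, correction=True).pvalue, abs=1e-12
        )
        assert res.p_chi2 == pytest.approx(
            sm_mcnemar(table, exact=False, correction=False).pvalue, abs=1e-12
        )

    def test_power_monotone_in_accuracy_gap(self):
        # rejection frequency must not decrease as the gap widens
        rng = np.random.default_rng(5)
        n_pairs, n_rep = 400, 300
        rates = []
        for p2 in (0.65, 0.70, 0.75):
            r1 = rng.random((n_rep, n_pairs)) < 0.65
            r2 = rng.random((n_rep, n_pairs)) < p2
            b = np.sum(r1 & ~r2, axis=1)
            c = np.sum(~r1 & r2, axis=1)
            rates.append(np.mean(cs.mcnemar_exact_pvalues(b, c) <= 0.05))
        assert rates[0] <= rates[1] <= rates[2]


class TestCommittee:
    def test_majority_and_tie(self):
        # 3 raters: P0 2-1 positive, P1 1-2 negative; add a 2x2 tie case
        cm = make_matrix([[1, 0], [1, 1], [0, 0]])
        res = cs.committee_votes(cm)
        assert res.selection.values.tolist() == [1.0, 0.0]
        cm_tie = make_matrix([[1, 1], [0, 1]])
        res_tie = cs.committee_votes(cm_tie)
        assert res_tie.selection.values.tolist() == [0.5, 1.0]
        assert res_tie.n_tie == 1

    def test_accuracy_credits_ties_half(self):
        # 100 pairs: 60 clear-correct, 20 clear-wrong, 20 ties -> 0.70
        votes = [1.0] * 60 + [0.0] * 20 + [0.5] * 20
        cm = make_matrix(
            [[1] * 60 + [0] * 20 + [1] * 20, [1] * 60 + [0] * 20 + [0] * 20]
        )
        res = cs.committee_votes(cm)
        assert res.selection.values.tolist() == votes
        assert res.accuracy == pytest.approx(0.70)

    def test_unanswered_pair_excluded_and_reported(self):
        cm = make_matrix([[1, -1], [0, -1]])
        res = cs.committee_votes(cm)
        assert res.selection.pair_ids == ["P0"]
        assert res.excluded_pair_ids == ["P1"]

    def test_dominance_over_mean_individual(self):
        # >=11 equally accurate raters at 0.65: majority should beat the
        # mean individual in nearly every replicate
        sigma = calibrate_sigma(0.65, 1.0)
        wins = 0
        for seed in range(200):
            cohort = simulate_cohort(
                SimulationConfig(
                    {"X": 1000}, 11, 1.0, [sigma] * 11, 1.0,
                    [5.0] * 11, seed=seed,
                )
            )
            committee = cs.committee_votes(cohort.choices).accuracy
            mean_ind = np.mean(
                [
                    quiz_accuracy(cohort.choices.rater_selection(r)).accuracy
                    for r in cohort.choices.rater_ids
                ]
            )
            wins += committee > mean_ind
        assert wins >= 0.95 * 200


class TestCommitteeVsModel:
    def test_no_ties_policies_coincide(self):
        committee = cs.committee_votes(make_matrix([[1, 0, 1], [1, 0, 1], [1, 0, 0]]))
        model = selection([0, 1, 1], "model", ties=True)
        base_b, base_c = cs.discordant_counts(
            committee.selection, model
        )
        base = cs.mcnemar_test(base_b, base_c)
        rand = cs.committee_vs_model_mcnemar(committee, model, "randomized", 9, 0)
        frac = cs.committee_vs_model_mcnemar(committee, model, "fractional")
        assert rand.p_exact_median == pytest.approx(base.p_exact)
        assert rand.p_exact_q25 == rand.p_exact_q75 == rand.p_exact_median
        assert (frac.b, frac.c) == (base.b, base.c)
        assert frac.p_chi2 == pytest.approx(base.p_chi2)

    def test_all_ties_under_exact_null(self):
        # Every committee vote tied and the model correct on exactly half
        # the pairs: coin tie-breaks make b and c independent Bin(n/2, 1/2),
        # so b - c is under-dispersed relative to the conditional binomial
        # reference and the exact p concentrates near 0.67 (simulated), far
        # from significance.  Frozen band from a 10-draw simulation.
        rng = np.random.default_rng(0)
        n = 400
        cm = make_matrix(np.stack([np.ones(n), np.zeros(n)]).astype(int))
        committee = cs.committee_votes(cm)
        assert committee.n_tie == n
        vals = rng.permutation(np.r_[np.ones(n // 2), np.zeros(n // 2)])
        model = selection(vals, "model", ties=True)
        res = cs.committee_vs_model_mcnemar(committee, model, "randomized", 499, 1)
        assert 0.6 <= res.p_exact_median <= 0.75
        assert res.p_exact_median > 0.5  # clearly non-significant under the null

    def test_fractional_symmetry_zero_statistic(self):
        cm = make_matrix(np.array([[1, 1, 0, 0, 1], [0, 0, 1, 1, 1]]))
        committee = cs.committee_votes(cm)  # four ties + one definite
        model = selection([1, 0, 1, 0, 1], "model", ties=True)
        res = cs.committee_vs_model_mcnemar(committee, model, "fractional")
        assert res.b == res.c
        assert res.statistic_chi2 == 0.0
        assert not res.exact_available

    def test_resamples_must_be_positive(self):
        cm = make_matrix([[1], [0]])
        committee = cs.committee_votes(cm)
        model = selection([1], "model", ties=True)
        with pytest.raises(ValidationError):
            cs.committee_vs_model_mcnemar(committee, model, "randomized", 0, 1)


class TestFleissKappa:
    def test_perfect_agreement(self):
        cm = make_matrix([[1, 0, 1], [1, 0, 1], [1, 0, 1]])
        assert cs.fleiss_kappa(cm).kappa == 1.0

    def test_toy_matrix_against_hand_definition(self):
        cm = make_matrix([[1, 1, 0], [1, 0, 0], [0, 1, 0]])
        # items: positive-votes 2,2,0 of n=3 raters
        p_i = [(2**2 + 1**2 - 3) / 6, (2**2 + 1**2 - 3) / 6, (0 + 9 - 3) / 6]
        p_bar = sum(p_i) / 3
        p_pos = 4 / 9
        p_e = p_pos**2 + (1 - p_pos) ** 2
        expected = (p_bar - p_e) / (1 - p_e)
        res = cs.fleiss_kappa(cm)
        assert res.kappa == pytest.approx(expected, abs=1e-15)

    def test_cross_check_statsmodels(self, rng):
        choices = rng.integers(0, 2, (6, 200))
        cm = make_matrix(choices)
        table = np.stack(
            [choices.sum(axis=0), (1 - choices).sum(axis=0)], axis=1
        )
        assert cs.fleiss_kappa(cm).kappa == pytest.approx(
            sm_fleiss(table), abs=1e-12
        )

    def test_null_band_independent_raters(self, rng):
        cm = make_matrix(rng.integers(0, 2, (20, 5000)))
        assert abs(cs.fleiss_kappa(cm).kappa) < 0.02

    def test_single_rater_rejected(self):
        with pytest.raises(ValidationError):
            cs.fleiss_kappa(make_matrix([[1, 0]]))

    def test_schemes_coincide_in_forced_choice_design(self, small_cohort):
        a = cs.fleiss_kappa(small_cohort.choices, "choice-identity")
        b = cs.fleiss_kappa(small_cohort.choices, "correctness")
        assert a.kappa == b.kappa

    @given(
        data=st.lists(
            st.lists(st.integers(0, 1), min_size=4, max_size=4),
            min_size=2,
            max_size=6,
        )
    )
    def test_bounds_and_rater_permutation_invariance(self, data):
        cm = make_matrix(np.array(data))
        res = cs.fleiss_kappa(cm)
        if not res.undefined:
            assert -1.0 - 1e-12 <= res.kappa <= 1.0 + 1e-12
        perm = make_matrix(np.array(data)[::-1])
        res_p = cs.fleiss_kappa(perm)
        assert (res.undefined and res_p.undefined) or res.kappa == pytest.approx(
            res_p.kappa, abs=1e-12
        )

    def test_missing_responses_use_per_item_counts(self):
        cm = make_matrix([[1, 1, -1], [1, 0, 1], [1, 0, 1]])
        res = cs.fleiss_kappa(cm)  # item 2 has 2 raters, both positive-chosen
        assert res.n_items == 3
        assert np.isfinite(res.kappa)


class TestAgreementSummary:
    def _setup(self, rater_rows, model_vals, tie_model=True):
        cm = make_matrix(np.array(rater_rows))
        committee = cs.committee_votes(cm)
        model = selection(np.array(model_vals, float), "model", ties=True)
        return cm, model, committee

    def test_identical_and_complementary(self):
        cm, model, committee = self._setup(
            [[1, 0, 1, 0], [1, 0, 1, 0]], [1, 0, 1, 0]
        )
        agg = cs.agreement_summary(cm, model, committee)
        assert agg.matrix[0, 1] == 1.0  # identical raters
        assert agg.mean_model_rater == 1.0
        cm2, model2, committee2 = self._setup(
            [[1, 0, 1, 0], [0, 1, 0, 1]], [1, 0, 1, 0]
        )
        agg2 = cs.agreement_summary(cm2, model2, committee2)
        assert agg2.matrix[0, 1] == 0.0  # complementary raters

    def test_matrix_symmetric_unit_diagonal(self, small_cohort):
        model = model_selections(small_cohort.pairs, small_cohort.model_scores)
        committee = cs.committee_votes(small_cohort.choices)
        agg = cs.agreement_summary(small_cohort.choices, model, committee)
        assert np.allclose(agg.matrix, agg.matrix.T)
        assert np.allclose(np.diag(agg.matrix), 1.0)
        assert np.nanmin(agg.matrix) >= 0.0 and np.nanmax(agg.matrix) <= 1.0

    def test_agree_or_better_worked_example(self, rng):
        # 100 pairs, no ties: model matches committee on 80; on the 20
        # disagreements the model is correct on 10 -> 0.90
        committee_vals = np.ones(100)
        model_vals = np.ones(100)
        disagree = rng.choice(100, 20, replace=False)
        model_vals[disagree] = 0.0  # model disagrees by choosing negative
        committee_vals[disagree[:10]] = 0.0  # committee wrong there, model right
        model_vals[disagree[:10]] = 1.0
        n_raters = 3  # committee values realized via unanimous raters
        rows = np.tile(committee_vals, (n_raters, 1)).astype(int)
        cm = make_matrix(rows)
        committee = cs.committee_votes(cm)
        model = selection(model_vals, "model", ties=True)
        agg = cs.agreement_summary(cm, model, committee)
        assert agg.agree_or_better == pytest.approx(0.90)
        assert agg.model_committee == pytest.approx(0.80)


class TestExperienceCorrelation:
    def _perf(self, accs):
        return [
            RaterPerformance(f"R{i}", 100, a * 100, a) for i, a in enumerate(accs)
        ]

    def _raters(self, years):
        return [RaterRecord(f"R{i}", y) for i, y in enumerate(years)]

    def test_exact_linear_relation(self):
        years = [2.0, 10.0, 20.0, 30.0]
        accs = [0.5 + 0.01 * y for y in years]
        res = cs.experience_correlation(self._perf(accs), self._raters(years))
        assert res.pearson_r == pytest.approx(1.0)
        assert res.spearman_rho == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_constant_accuracy_flagged_undefined(self):
        res = cs.experience_correlation(
            self._perf([0.6, 0.6, 0.6]), self._raters([2.0, 5.0, 9.0])
        )
        assert res.undefined
        assert np.isnan(res.pearson_r)

    def test_against_from_definition_oracle(self, rng):
        years = rng.uniform(2, 37, 15)
        accs = rng.uniform(0.55, 0.75, 15)
        res = cs.experience_correlation(self._perf(accs), self._raters(years))
        x, y = years - years.mean(), accs - accs.mean()
        pearson = float(np.sum(x * y) / np.sqrt(np.sum(x**2) * np.sum(y**2)))
        rx, ry = rankdata(years), rankdata(accs)
        rxc, ryc = rx - rx.mean(), ry - ry.mean()
        spearman = float(
            np.sum(rxc * ryc) / np.sqrt(np.sum(rxc**2) * np.sum(ryc**2))
        )
        assert res.pearson_r == pytest.approx(pearson, abs=1e-12)
        assert res.spearman_rho == pytest.approx(spearman, abs=1e-12)
        assert res.r_squared == pytest.approx(pearson**2, abs=1e-12)

    def test_too_few_raters_rejected(self):
        with pytest.raises(ValidationError):
            cs.experience_correlation(
                self._perf([0.5, 0.6]), self._raters([1.0, 2.0])
            )


def test_holm_adjust_matches_statsmodels(rng):
    p = rng.uniform(0, 1, 12)
    expected = multipletests(p, method="holm")[1]
    assert np.allclose(cs.holm_adjust(p), expected, atol=1e-12)
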