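import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cvdms.data import PersonPeriodTable
from cvdms.estimation import (
    CovariateSpec,
    SeparationError,
    TransitionModel,
    TransitionProbs,
    aggregate_transitions,
    fit_stratified,
    fit_transition_model,
    fit_transitions,
    multinomial_loglik,
    predict_transition_probs,
)
from cvdms.states import CVD, DEAD, FREE, PERIODS

INTERCEPT_ONLY = CovariateSpec(include_age=False, include_age2=False, include_period=False)


def _counts(rows):
    return pd.DataFrame(
        rows,
        columns=["age_month", "period", "gender", "education", "state_now",
                 "state_next", "count"],
    )


class TestFitTransitionModel:
    def test_saturated_intercept_only_fit_reproduces_empirical_fractions(self):
        # single age, single period: the MLE is the observed outcome fractions
        cells = _counts([
            (600, "1996-2000", "women", "basic", "free", "free", 70),
            (600, "1996-2000", "women", "basic", "free", "cvd", 20),
            (600, "1996-2000", "women", "basic", "free", "dead", 10),
        ])
        m = fit_transition_model(cells, FREE, INTERCEPT_ONLY)
        probs = m.step_probs(FREE, np.array([600]), "1996-2000")
        assert probs[FREE][0] == pytest.approx(0.70, abs=1e-9)
        assert probs[CVD][0] == pytest.approx(0.20, abs=1e-9)
        assert probs[DEAD][0] == pytest.approx(0.10, abs=1e-9)

    def test_agrees_with_statsmodels_mnlogit_on_row_level_data(self, baseline_table):
        sm = pytest.importorskip("statsmodels.api")
        sub = PersonPeriodTable(
            baseline_table.df[baseline_table.df["person_id"] < 4000].reset_index(drop=True)
        )
        mine = fit_transition_model(sub, FREE)
        df = sub.df[sub.df["state_now"] == FREE]
        spec = CovariateSpec()
        pidx = pd.Categorical(df["period"], categories=list(spec.periods)).codes
        X = spec.design(df["age_month"].to_numpy(), pidx)
        y = pd.Categorical(df["state_next"], categories=[FREE, CVD, DEAD]).codes
        ref = sm.MNLogit(y, X).fit(disp=0, method="newton", maxiter=200)
        params, bse = np.asarray(ref.params), np.asarray(ref.bse)
        assert np.allclose(params[:, 0], mine.coef[FREE][CVD], atol=1e-8)
        assert np.allclose(params[:, 1], mine.coef[FREE][DEAD], atol=1e-8)
        assert np.allclose(bse[:, 0], mine.bse[FREE][CVD], atol=1e-8)

    def test_cvd_origin_is_binary_logit_with_zero_recovery(self, baseline_table):
        m = fit_transition_model(baseline_table, CVD)
        assert set(m.coef[CVD]) == {DEAD}
        tp = predict_transition_probs(m.merged_with(fit_transition_model(baseline_table, FREE)))
        assert (tp.prob(CVD, FREE) == 0.0).all()

    def test_loglik_at_mle_beats_generating_parameters(self, baseline_model, baseline_table):
        spec = CovariateSpec()
        fitted = fit_transition_model(baseline_table, FREE, spec)
        cells = aggregate_transitions(baseline_table)
        cells = cells[cells["state_now"] == FREE]
        pidx = pd.Categorical(cells["period"], categories=list(spec.periods)).codes
        grp = cells.groupby(["age_month", pd.Series(pidx, index=cells.index)])
        keys = list(grp.groups)
        Y = np.zeros((len(keys), 3))
        dmap = {FREE: 0, CVD: 1, DEAD: 2}
        for i, (key, sub) in enumerate(grp):
            for _, r in sub.iterrows():
                Y[i, dmap[r["state_next"]]] += r["count"]
        X = spec.design(np.array([k[0] for k in keys], float), np.array([k[1] for k in keys]))
        beta_hat = np.vstack([fitted.coef[FREE][CVD], fitted.coef[FREE][DEAD]])
        beta_true = np.vstack(
            [baseline_model.base.coef[FREE][CVD], baseline_model.base.coef[FREE][DEAD]]
        )
        assert multinomial_loglik(X, Y, beta_hat) >= multinomial_loglik(X, Y, beta_true)

    def test_empty_origin_subset_raises(self):
        cells = _counts([(600, "1996-2000", "women", "basic", "cvd", "cvd", 5)])
        with pytest.raises(ValueError, match="no rows with state_now"):
            fit_transition_model(cells, FREE)

    def test_perfect_separation_raises_naming_covariate(self):
        # destination 'dead' never occurs in the second period: its dummy
        # coefficient runs to -infinity
        cells = _counts([
            (600, "1996-2000", "women", "basic", "free", "free", 50),
            (600, "1996-2000", "women", "basic", "free", "cvd", 20),
            (600, "1996-2000", "women", "basic", "free", "dead", 30),
            (600, "2001-2005", "women", "basic", "free", "free", 60),
            (600, "2001-2005", "women", "basic", "free", "cvd", 40),
        ])
        spec = CovariateSpec(include_age=False, include_age2=False)
        with pytest.raises(SeparationError, match=r"period\[2001-2005\]"):
            fit_transition_model(cells, FREE, spec)


class TestPredictTransitionProbs:
    def test_softmax_arithmetic_from_known_linear_predictors(self):
        # eta(CVD) = -4, eta(DEAD) = -5 against the stay reference
        spec = INTERCEPT_ONLY
        m = TransitionModel(
            spec=spec,
            coef={
                FREE: {CVD: np.array([-4.0]), DEAD: np.array([-5.0])},
                CVD: {DEAD: np.array([-30.0])},
            },
        )
        tp = predict_transition_probs(m, period="1996-2000")
        assert tp.prob(FREE, CVD)[0] == pytest.approx(0.017868, abs=1e-6)
        assert tp.prob(FREE, DEAD)[0] == pytest.approx(0.006573, abs=1e-6)
        assert tp.prob(FREE, FREE)[0] == pytest.approx(0.975559, abs=1e-6)

    def test_minus_thirty_intercept_is_numerically_zero_probability(self):
        m = TransitionModel(
            spec=INTERCEPT_ONLY,
            coef={
                FREE: {CVD: np.array([-2.0]), DEAD: np.array([-30.0])},
                CVD: {DEAD: np.array([-30.0])},
            },
        )
        tp = predict_transition_probs(m, period="1996-2000")
        assert tp.prob(FREE, DEAD).max() < 1e-12
        assert tp.prob(CVD, DEAD).max() < 1e-12

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.lists(st.floats(-8, 8), min_size=9, max_size=9))
    def test_rows_sum_to_one_for_arbitrary_coefficients(self, vals):
        m = TransitionModel(
            spec=CovariateSpec(include_period=False),
            coef={
                FREE: {CVD: np.array(vals[0:3]), DEAD: np.array(vals[3:6])},
                CVD: {DEAD: np.array(vals[6:9])},
            },
        )
        tp = predict_transition_probs(m, period="1996-2000")
        assert np.max(np.abs(tp.array.sum(axis=2) - 1.0)) < 1e-12

    def test_unknown_period_label_raises(self, baseline_model):
        with pytest.raises(ValueError, match="unknown period"):
            predict_transition_probs(baseline_model.base, period="2021-2025")

    def test_age_scaling_invariance_of_predictions(self, baseline_table):
        tp1 = predict_transition_probs(fit_transitions(baseline_table))
        spec2 = CovariateSpec(age_center=480.0, age_scale=240.0)
        tp2 = predict_transition_probs(fit_transitions(baseline_table, spec2))
        assert np.max(np.abs(tp1.array - tp2.array)) < 1e-10


class TestFitStratified:
    def test_scheme_cardinalities(self, baseline_table):
        assert set(fit_stratified(baseline_table, "total")) == {"total"}
        assert set(fit_stratified(baseline_table, "by_gender")) == {"women", "men"}
        six = fit_stratified(baseline_table, "by_gender_education")
        assert set(six) == {
            f"{g}/{e}" for g in ("women", "men")
            for e in ("basic", "secondary", "tertiary")
        }

    def test_identically_generated_strata_agree_within_three_se(self, baseline_table):
        # the baseline generator is homogeneous across gender, so the two
        # gender fits estimate the same truth
        models = fit_stratified(baseline_table, "by_gender")
        for origin, dest in [(FREE, CVD), (FREE, DEAD), (CVD, DEAD)]:
            bw, bm = (models[g].coef[origin][dest] for g in ("women", "men"))
            sw, sm_ = (models[g].bse[origin][dest] for g in ("women", "men"))
            z = (bw - bm) / np.hypot(sw, sm_)
            assert np.abs(z).max() < 3

    def test_empty_stratum_raises_naming_it(self, baseline_table):
        women_only = PersonPeriodTable(
            baseline_table.df[baseline_table.df["gender"] == "women"].reset_index(drop=True)
        )
        with pytest.raises(ValueError, match="men"):
            fit_stratified(women_only, "by_gender")

    def test_unknown_scheme_rejected(self, baseline_table):
        with pytest.raises(ValueError, match="unknown scheme"):
            fit_stratified(baseline_table, "by_star_sign")

    def test_total_scheme_on_empty_table_raises(self):
        with pytest.raises(ValueError):
            fit_stratified(PersonPeriodTable.empty_table(), "total")


class TestSerialization:
    def test_model_json_roundtrip_preserves_predictions(self, baseline_table, tmp_path):
        m = fit_transitions(baseline_table)
        path = tmp_path / "m.json"
        m.to_json(path)
        back = TransitionModel.from_json(path)
        tp1 = predict_transition_probs(m, period=PERIODS[2])
        tp2 = predict_transition_probs(back, period=PERIODS[2])
        assert np.array_equal(tp1.array, tp2.array)
        assert back.bse is not None

    def test_probs_csv_roundtrip(self, baseline_probs, tmp_path):
        path = tmp_path / "p.csv"
        baseline_probs.to_csv(path)
        back = TransitionProbs.from_csv(path)
        assert np.allclose(back.array, baseline_probs.array, atol=1e-12)
        assert back.period == baseline_probs.period
        back.validate()
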