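import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

from scinfer import (
    DataError,
    DisruptionMatrix,
    ParameterError,
    encode_stage,
    firth_lrt,
    fit_firth_cox,
    fit_multivariate,
    kaplan_meier,
    make_pair_design,
    partition_by_pair,
    partner_burden,
    stratify_pair_groups,
)
from _oracles import km_empirical_oracle


@pytest.fixture
def patient_matrix():
    data = pd.DataFrame(
        [[1, 1, 0], [1, 0, 1], [0, 1, 1], [0, 0, 0], [1, 1, 1]],
        index=pd.Index([f"p{i}" for i in range(5)], name="sample_id"),
        columns=["TP53", "SYNE2", "SON"],
    )
    return DisruptionMatrix(data)


class TestStratification:
    def test_labels(self, patient_matrix):
        labels = stratify_pair_groups(patient_matrix, "TP53", "SYNE2")
        assert labels.tolist() == ["both_mut", "anchor_only", "partner_only", "wild_type", "both_mut"]

    def test_agrees_with_screen_partition(self, patient_matrix):
        labels = stratify_pair_groups(patient_matrix, "TP53", "SYNE2")
        part = partition_by_pair(patient_matrix, "TP53", "SYNE2")
        assert set(labels.index[labels == "both_mut"]) == set(part.both)
        assert set(labels.index[labels == "anchor_only"]) == set(part.a_only)
        assert set(labels.index[labels == "partner_only"]) == set(part.b_only)
        assert set(labels.index[labels == "wild_type"]) == set(part.neither)

    def test_partner_burden_and_stratum_flag(self, patient_matrix):
        pb = partner_burden(patient_matrix, "TP53", ["SYNE2", "SON"])
        assert pb["burden"].tolist() == [1, 1, 2, 0, 2]
        assert pb["anchor_mutant"].tolist() == [True, True, False, False, True]
        with pytest.raises(ParameterError):
            partner_burden(patient_matrix, "TP53", [])

    def test_pair_design_reference_coding(self, patient_matrix):
        labels = stratify_pair_groups(patient_matrix, "TP53", "SYNE2")
        clin = pd.DataFrame(
            {
                "patient_id": labels.index,
                "os_time": [5.0, 4.0, 3.0, 2.0, 1.0],
                "os_event": [1, 0, 1, 0, 1],
            }
        )
        design = make_pair_design(labels, clin)
        # reference group (both_mut) has all-zero dummies
        assert design.loc["p0", ["anchor_only", "partner_only", "wild_type"]].sum() == 0
        assert design.loc["p1", "anchor_only"] == 1


def _sim_cohort(seed, n=400, hr=2.5, censor_rate=1.55):
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 2, n).astype(float)
    lam = 1.0 * hr**x
    t_event = rng.exponential(1 / lam)
    t_cens = rng.exponential(1 / censor_rate, n)
    return pd.DataFrame(
        {"time": np.minimum(t_event, t_cens), "event": (t_event <= t_cens).astype(int), "x": x}
    )


class TestFirthCox:
    def test_symmetric_groups_give_null_effect(self):
        times = np.arange(1.0, 11.0)
        events = np.tile([1, 0], 5)
        df = pd.DataFrame(
            {
                "time": np.concatenate([times, times]),
                "event": np.concatenate([events, events]),
                "x": [0.0] * 10 + [1.0] * 10,
            }
        )
        fit = fit_firth_cox(df, ["x"])
        assert abs(fit.beta[0]) < 0.05
        assert fit.hazard_ratio[0] == pytest.approx(np.exp(fit.beta[0]))

    def test_complete_separation_stays_finite(self):
        # monotone likelihood: all events in one arm, all censored in the other
        df = pd.DataFrame(
            {
                "time": list(range(1, 11)) + list(range(1, 11)),
                "event": [1] * 10 + [0] * 10,
                "x": [1.0] * 10 + [0.0] * 10,
            }
        )
        fit = fit_firth_cox(df, ["x"])
        assert fit.converged
        assert abs(fit.beta[0]) < 10
        assert fit.penalized_loglik > fit.loglik_null

    def test_loglik_path_non_decreasing(self):
        df = _sim_cohort(0)
        fit = fit_firth_cox(df, ["x"])
        path = np.array(fit.loglik_path)
        assert (np.diff(path) >= -1e-9).all()

    def test_large_n_agrees_with_unpenalized_cox(self):
        df = _sim_cohort(1, n=2000)
        fit = fit_firth_cox(df, ["x"], compute_pvalues=False)
        cph = CoxPHFitter().fit(df, "time", "event")
        assert abs(fit.beta[0] - cph.params_["x"]) < 0.02

    def test_lrt_pvalue_matches_direct_lrt(self):
        df = _sim_cohort(2)
        fit = fit_firth_cox(df, ["x"])
        _, p = firth_lrt(df, ["x"], "x", 0.0)
        assert fit.p_value[0] == pytest.approx(p)

    def test_no_events_rejected(self):
        df = pd.DataFrame({"time": [1.0, 2.0], "event": [0, 0], "x": [0.0, 1.0]})
        with pytest.raises(DataError):
            fit_firth_cox(df, ["x"])

    def test_constant_covariate_named_in_error(self):
        df = _sim_cohort(3)
        df["flat"] = 1.0
        with pytest.raises(DataError, match="flat"):
            fit_firth_cox(df, ["x", "flat"])

    def test_collinear_covariates_rejected(self):
        df = _sim_cohort(4)
        df["x_copy"] = df["x"]
        with pytest.raises(DataError, match="collinear"):
            fit_firth_cox(df, ["x", "x_copy"])


class TestMultivariate:
    def test_stage_encoding(self):
        s = pd.Series(["I", "Stage II", "IV", None])
        codes = encode_stage(s)["stage_code"]
        assert codes.tolist()[:3] == [1.0, 2.0, 4.0]
        assert np.isnan(codes.iloc[3])
        dummies = encode_stage(s, dummies=True)
        assert list(dummies.columns) == ["stage_II", "stage_III", "stage_IV"]
        assert dummies.iloc[1].tolist() == [1.0, 0.0, 0.0]

    def test_independent_stage_leaves_estimate_stable(self):
        df = _sim_cohort(5, n=800)
        rng = np.random.default_rng(5)
        df["stage"] = rng.choice(["I", "II", "III", "IV"], size=len(df))
        uni = fit_firth_cox(df, ["x"], compute_pvalues=False)
        multi = fit_multivariate(df, ["x"], compute_pvalues=False)
        assert "stage_code" in multi.covariates
        assert abs(multi.beta[0] - uni.beta[0]) < 0.15

    def test_noise_covariate_leaves_lrt_stable(self):
        df = _sim_cohort(6, n=600)
        rng = np.random.default_rng(6)
        df["noise"] = rng.normal(size=len(df))
        _, p_alone = firth_lrt(df, ["x"], "x")
        _, p_joint = firth_lrt(df, ["x", "noise"], "x")
        assert np.log10(p_joint) == pytest.approx(np.log10(p_alone), abs=1.0)

    def test_confounded_stage_is_rejected(self):
        df = _sim_cohort(7)
        df["stage"] = np.where(df["x"] > 0, "II", "I")
        with pytest.raises(DataError, match="collinear"):
            fit_multivariate(df, ["x"])


class TestKaplanMeier:
    def test_hand_worked_product_limit(self):
        df = pd.DataFrame({"time": [1, 2, 3], "event": [0, 1, 1]})
        curve = kaplan_meier(df)["all"]
        assert curve.survival_at(1) == 1.0  # censoring removes no survival mass
        assert curve.survival_at(2) == pytest.approx(0.5)
        assert curve.survival_at(3) == pytest.approx(0.0)

    def test_no_events_flat_at_one(self):
        df = pd.DataFrame({"time": [1.0, 5.0, 9.0], "event": [0, 0, 0]})
        curve = kaplan_meier(df)["all"]
        assert (curve.survival == 1.0).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_uncensored_km_is_empirical_survival(self, seed):
        rng = np.random.default_rng(seed)
        times = rng.exponential(10, size=rng.integers(5, 40))
        df = pd.DataFrame({"time": times, "event": 1})
        curve = kaplan_meier(df)["all"]
        oracle = km_empirical_oracle(times)
        for t in times:
            assert curve.survival_at(t) == pytest.approx(oracle(t))

    def test_groups_and_risk_table(self):
        df = pd.DataFrame(
            {"time": [1, 2, 3, 4], "event": [1, 1, 0, 1], "g": ["a", "a", "b", "b"]}
        )
        curves = kaplan_meier(df, group_col="g", risk_times=[0, 2.5])
        assert set(curves) == {"a", "b"}
        assert curves["b"].risk_table[0.0] == 2
        assert curves["b"].risk_table[2.5] == 2

    def test_negative_time_rejected(self):
        df = pd.DataFrame({"time": [-1.0], "event": [1]})
        with pytest.raises(DataError):
            kaplan_meier(df)
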