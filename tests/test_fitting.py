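import math
import warnings

import numpy as np
import pytest

from diolkin import (
    ConfigurationError,
    DomainError,
    KineticParams,
    ModelVariant,
    NoiseModel,
    OptimizerConfig,
    Species,
    SyntheticScenario,
    TimeSeriesData,
    aic,
    analytic_linear_chain,
    compare_models,
    compute_rss,
    default_initial_state,
    fit_params,
    generate_timecourse,
    infer_n_k,
    staged_fit_protocol,
)
from diolkin.fitting import AIC_RSS_ZERO

Y0 = default_initial_state()  # 40 g/L glucose, matching the generator default
G0 = float(Y0[0])

DKO = ModelVariant.DKO_PHABJ


def dko_params(free=(), **over):
    values = {"Ka1": 0.03, "Km2": 0.05, "Ka3": 0.04, **over}
    return KineticParams.for_variant(DKO, values, free=free)


class TestTimeSeriesData:
    def test_n_counts_records(self):
        data = TimeSeriesData.from_records(
            [(t, "HDO", 1.0) for t in (0, 24, 48, 72, 96)]
        )
        assert data.n == 5

    def test_duplicates_rejected(self):
        with pytest.raises(ConfigurationError, match="duplicate"):
            TimeSeriesData.from_records([(0, "HDO", 1.0), (0, "HDO", 2.0)])

    def test_empty_rejected(self):
        with pytest.raises(ConfigurationError):
            TimeSeriesData(())

    def test_negative_value_rejected(self):
        with pytest.raises(DomainError):
            TimeSeriesData.from_records([(0, "HDO", -1.0)])

    def test_subset_by_species(self):
        data = TimeSeriesData.from_records(
            [(0, "HDO", 1.0), (0, "BUTYRATE", 2.0), (24, "HDO", 3.0)]
        )
        assert data.subset(Species.HDO).n == 2
        assert data.subset(Species.BUTYRATE).n == 1


class TestComputeRss:
    def test_noiseless_perfect_fit(self):
        params = dko_params()
        scenario = SyntheticScenario(
            variant=DKO, params=params, noise=NoiseModel(kind="none")
        )
        data, _ = generate_timecourse(scenario)
        assert compute_rss(DKO, params, Y0, data) == pytest.approx(0.0, abs=1e-8)

    def test_single_observation(self):
        # observation 3.0 vs an exactly known prediction of the zero-rate
        # model (constant 1.0): residual 2.0 -> RSS 4.0
        y0 = np.array([0.0, 0.0, 0.0, 0.0, 1.0])
        data = TimeSeriesData.from_records([(24.0, "HDO", 3.0)])
        rss = compute_rss(DKO, {"Ka1": 0, "Km2": 0, "Ka3": 0}, y0, data)
        assert rss == pytest.approx(4.0, abs=1e-12)

    def test_against_bateman_closed_form_oracle(self):
        # independent re-implementation: predictions from the Bateman
        # closed form instead of the integrator
        rates = (0.05, 0.04, 0.03)
        obs = [(24.0, 5.0), (48.0, 12.0), (72.0, 30.0), (96.0, 50.0), (12.0, 1.0)]
        data = TimeSeriesData.from_records([(t, "HDO", v) for t, v in obs])
        expected = sum(
            (v - analytic_linear_chain(rates, G0, t)[Species.HDO]) ** 2
            for t, v in obs
        )
        rss = compute_rss(
            DKO, {"Ka1": rates[0], "Km2": rates[1], "Ka3": rates[2]}, Y0, data
        )
        assert rss == pytest.approx(expected, rel=1e-6)


class TestAic:
    def test_printed_no_inhibition_value(self):
        assert aic(51.0431, 5, 1) == pytest.approx(13.6162, abs=1e-3)

    def test_printed_inhibition_value(self):
        assert aic(0.3964, 5, 2) == pytest.approx(-8.6733, abs=1e-3)

    def test_rss_equal_n_k_zero(self):
        assert aic(7.0, 7, 0) == 0.0

    def test_zero_rss_sentinel_with_warning(self):
        with pytest.warns(RuntimeWarning, match="RSS"):
            assert aic(0.0, 5, 1) == AIC_RSS_ZERO

    def test_identity_formula(self):
        assert aic(2.5, 5, 3) == pytest.approx(5 * math.log(0.5) + 6, abs=1e-15)

    @pytest.mark.parametrize("rss,n,k", [(-1, 5, 1), (1, 0, 1), (1, 5, -1)])
    def test_domain_errors(self, rss, n, k):
        with pytest.raises(DomainError):
            aic(rss, n, k)


class TestInferNK:
    def test_unique_recovery_no_inhibition(self):
        assert infer_n_k(51.0431, 13.6162) == [(5, 1)]

    def test_unique_recovery_inhibition(self):
        assert infer_n_k(0.3964, -8.6733) == [(5, 2)]

    def test_unreachable_target_empty(self):
        assert infer_n_k(1.0, 1e6) == []


class TestFitParams:
    def test_single_param_noiseless_recovery(self):
        truth = dko_params()
        data, _ = generate_timecourse(
            SyntheticScenario(variant=DKO, params=truth, noise=NoiseModel(kind="none"))
        )
        start = dko_params(free=("Km2",), Km2=0.02)
        result = fit_params(DKO, data, start, Y0)
        assert result.params.params["Km2"].value == pytest.approx(0.05, rel=1e-3)
        assert result.k == 1 and result.n == 5

    def test_two_param_inhibition_recovery(self):
        variant = ModelVariant.DKO_PHABJ_INHIB
        truth = KineticParams.for_variant(
            variant, {"Ka1": 0.03, "Ka3": 0.04, "Vmax": 15.0, "Km": 8.7e-4, "Ki": 2.6}
        )
        data, _ = generate_timecourse(
            SyntheticScenario(variant=variant, params=truth, noise=NoiseModel(kind="none"))
        )
        start = truth.with_free(("Vmax", "Ki")).with_values({"Vmax": 1.0, "Ki": 1.0})
        result = fit_params(variant, data, start, Y0)
        assert result.params.params["Vmax"].value == pytest.approx(15.0, rel=0.01)
        assert result.params.params["Ki"].value == pytest.approx(2.6, rel=0.01)

    def test_k_zero_evaluates_fixed_model(self):
        data = TimeSeriesData.from_records([(24.0, "HDO", 3.0), (48.0, "HDO", 9.0)])
        fixed = dko_params()
        result = fit_params(DKO, data, fixed, Y0)
        assert result.k == 0
        assert result.params.value_dict() == fixed.value_dict()
        assert result.rss == pytest.approx(compute_rss(DKO, fixed, Y0, data), rel=1e-12)
        assert result.aic == pytest.approx(aic(result.rss, 2, 0))

    def test_aic_identity_on_result(self):
        truth = dko_params()
        data, _ = generate_timecourse(
            SyntheticScenario(variant=DKO, params=truth, noise=NoiseModel())
        )
        result = fit_params(DKO, data, dko_params(free=("Km2",)), Y0)
        assert result.aic == result.n * math.log(result.rss / result.n) + 2 * result.k

    def test_determinism_same_seed_bit_identical(self):
        truth = dko_params()
        data, _ = generate_timecourse(
            SyntheticScenario(variant=DKO, params=truth, noise=NoiseModel())
        )
        start = dko_params(free=("Km2",), Km2=0.02)
        opt = OptimizerConfig(seed=42, restarts=3)
        a = fit_params(DKO, data, start, Y0, opt)
        b = fit_params(DKO, data, start, Y0, opt)
        assert a.rss == b.rss
        assert a.params.value_dict() == b.params.value_dict()
        assert a.aic == b.aic

    def test_n_less_than_k_rejected(self):
        data = TimeSeriesData.from_records([(24.0, "HDO", 3.0)])
        start = dko_params(free=("Ka1", "Km2", "Ka3"))
        with pytest.raises(ConfigurationError):
            fit_params(DKO, data, start, Y0)

    def test_monotone_penalty_nested_fits(self):
        # adding a free parameter (started from the restricted optimum)
        # never increases RSS; AIC may still increase
        truth = dko_params()
        data, _ = generate_timecourse(
            SyntheticScenario(variant=DKO, params=truth, noise=NoiseModel())
        )
        restricted = fit_params(DKO, data, dko_params(free=("Km2",)), Y0)
        start_full = restricted.params.with_free(("Km2", "Ka3"))
        full = fit_params(DKO, data, start_full, Y0)
        assert full.rss <= restricted.rss * (1 + 1e-9)


class TestCompareModels:
    def test_printed_pair_prefers_inhibition(self):
        comparison = compare_models(
            [("no_inhibition", 51.0431, 5, 1), ("inhibition", 0.3964, 5, 2)]
        )
        assert comparison.preferred == "inhibition"
        assert not comparison.inconclusive
        assert comparison.entries[1].delta_aic == pytest.approx(22.29, abs=0.01)

    def test_single_entry(self):
        comparison = compare_models([("only", 2.0, 5, 1)])
        assert comparison.preferred == "only"
        assert comparison.entries[0].delta_aic == 0.0

    def test_tie_is_inconclusive(self):
        comparison = compare_models([("a", 2.0, 5, 1), ("b", 2.0, 5, 1)])
        assert comparison.inconclusive

    def test_zero_rss_excluded_with_warning(self):
        with pytest.warns(RuntimeWarning, match="excluded"):
            comparison = compare_models([("perfect", 0.0, 5, 1), ("noisy", 2.0, 5, 1)])
        assert [e.label for e in comparison.entries] == ["noisy"]

    def test_empty_rejected(self):
        with pytest.raises(ConfigurationError):
            compare_models([])


class TestStagedFitProtocol:
    def test_missing_dataset_rejected(self, fixtures):
        with pytest.raises(ConfigurationError, match="missing dataset"):
            staged_fit_protocol(fixtures["mr40"][0], None, fixtures["dko_fadb"][0])

    def test_stage1_requires_butyrate(self, fixtures):
        hdo_only = fixtures["mr40"][0].subset(Species.HDO)
        with pytest.raises(ConfigurationError, match="butyrate"):
            staged_fit_protocol(
                hdo_only, fixtures["dko_phabj"][0], fixtures["dko_fadb"][0]
            )

    def test_inhibition_truth_selects_inhibition_model(self, staged_outcome):
        assert staged_outcome.comparison.preferred == "DKO_PHABJ_INHIB"
        assert not staged_outcome.comparison.inconclusive

    def test_stage_chaining_fixes_parameters(self, staged_outcome):
        s1 = staged_outcome.stage1_mr40.params.value_dict()
        s2 = staged_outcome.stage2_dko_linear.params.value_dict()
        s3 = staged_outcome.stage3_dko_inhibition.params.value_dict()
        s4 = staged_outcome.stage4_fadb.params.value_dict()
        assert s2["Ka1"] == s1["Ka1"] and s2["Ka3"] == s1["Ka3"]
        assert s3["Ka1"] == s1["Ka1"] and s3["Ka3"] == s1["Ka3"]
        assert s3["Km"] == pytest.approx(8.7e-4)
        assert s4["Vmax"] == s3["Vmax"] and s4["Ki"] == s3["Ki"]
        assert s4["Ka3"] == s1["Ka3"]

    def test_free_counts_per_stage(self, staged_outcome):
        assert staged_outcome.stage1_mr40.k == 4
        assert staged_outcome.stage2_dko_linear.k == 1
        assert staged_outcome.stage3_dko_inhibition.k == 2
        assert staged_outcome.stage4_fadb.k == 1

    def test_stage4_recovers_inflow_constant(self, staged_outcome, fixtures):
        truth = fixtures["dko_fadb"][1]["params"]["Kb1"]
        fitted = staged_outcome.stage4_fadb.params.params["Kb1"].value
        assert fitted == pytest.approx(truth, rel=0.05)

    def test_linear_truth_does_not_select_inhibition(self, staged_outcome_linear):
        comparison = staged_outcome_linear.comparison
        entries = {e.label: e for e in comparison.entries}
        if comparison.preferred == "DKO_PHABJ_INHIB":
            assert entries["DKO_PHABJ"].delta_aic < 2.0
        else:
            assert comparison.preferred == "DKO_PHABJ"
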