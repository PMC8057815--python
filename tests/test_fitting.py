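"""Bounded least-squares rate fitting, RSE and model comparison."""

import dataclasses
import math

import numpy as np
import pytest

import saccadapt as sa
from saccadapt.fitting import (
    ALPHA_UPPER,
    ETA_WEIGHTS,
    FitConfig,
    ProbeSeries,
    compare_models,
    fit,
    fit_shared,
    initial_state,
    objective,
    probe_predictions,
)
from saccadapt.gains import PROBE_TRIALS, ProbeBlockMeasure
from saccadapt.learning import LearningRates
from saccadapt.model import GainState


def series_from_model(state0, rates, cond, mode="postdiction", subject=None):
    """Noiseless ProbeSeries generated by the forward model itself."""
    paradigm = sa.condition(cond)
    pred = probe_predictions(state0, rates, paradigm, mode)
    blocks = tuple(
        ProbeBlockMeasure(V1=row[0], M=row[1], V2_hat=row[2], block_index=i + 1)
        for i, row in enumerate(pred)
    )
    return ProbeSeries(blocks=blocks, paradigm=paradigm, subject=subject)


START = GainState(1.0, 0.95, 0.985)
TRUE = LearningRates(2e-6, 1.5e-5, 8e-6)


class TestInitialState:
    def test_identity_block(self):
        s = series_from_model(GainState(1, 1, 1), LearningRates(0, 0, 0), "CTS_in")
        assert initial_state(s).as_tuple() == (1, 1, 1)

    def test_hypometric_block(self):
        blocks = tuple(
            ProbeBlockMeasure(13.0, 12.4, 0.8, block_index=i + 1) for i in range(5)
        )
        s = ProbeSeries(blocks=blocks, paradigm=sa.condition("CTS_in"))
        st = initial_state(s)
        assert st.as_tuple() == pytest.approx((1.0, 0.9538, 0.9839), abs=1e-4)

    def test_degenerate_block_signals(self):
        blocks = tuple(
            ProbeBlockMeasure(0.0, 12.4, 0.8, block_index=i + 1) for i in range(5)
        )
        s = ProbeSeries(blocks=blocks, paradigm=sa.condition("CTS_in"))
        with pytest.raises(ValueError):
            initial_state(s)


class TestObjective:
    def test_self_consistency_zero(self):
        s = series_from_model(START, TRUE, "CTS_in")
        assert objective(TRUE, s, FitConfig()) == pytest.approx(0.0, abs=1e-20)

    def test_zero_rates_positive_on_learning_series(self):
        s = series_from_model(START, TRUE, "CTS_in")
        assert objective(LearningRates(0, 0, 0), s, FitConfig()) > 0

    def test_block3_perturbation_weight_arithmetic(self):
        """+1 deg on block-3 M raises the objective by exactly eta = 0.65."""
        s = series_from_model(START, TRUE, "CTS_in")
        blocks = list(s.blocks)
        b = blocks[2]
        blocks[2] = ProbeBlockMeasure(b.V1, b.M + 1.0, b.V2_hat, block_index=3)
        perturbed = ProbeSeries(blocks=tuple(blocks), paradigm=s.paradigm)
        assert objective(TRUE, perturbed, FitConfig()) == pytest.approx(0.65)

    def test_eta_weights_as_stated(self):
        assert ETA_WEIGHTS == (1.52, 0.65, 0.65, 0.65, 1.52)
        assert sum(ETA_WEIGHTS) == pytest.approx(4.99)


class TestFit:
    @pytest.mark.parametrize("cond", ["CTS_in", "CTS_out", "CVE_in", "CVE_out"])
    def test_noiseless_parameter_recovery(self, cond):
        s = series_from_model(START, TRUE, cond)
        res = fit(s, FitConfig(mode="postdiction", seed=1))
        for a_hat, a_true in zip(res.alpha.as_tuple(), TRUE.as_tuple()):
            assert abs(a_hat - a_true) / a_true < 0.01
        assert res.sse < 1e-10
        assert res.rse == pytest.approx(math.sqrt(res.sse / 14), abs=1e-15)

    def test_constant_series_zero_rates_optimum(self):
        s = series_from_model(GainState(1, 1, 1), LearningRates(0, 0, 0), "baseline")
        res = fit(s, FitConfig(seed=0))
        assert res.sse == pytest.approx(0.0, abs=1e-12)

    def test_bounds_respected(self):
        s = series_from_model(START, TRUE, "CTS_in")
        res = fit(s, FitConfig(seed=0))
        for a in res.alpha.as_tuple():
            assert 0.0 <= a <= ALPHA_UPPER

    def test_prediction_fit_worse_on_postdiction_data(self):
        s = series_from_model(START, TRUE, "CTS_in", mode="postdiction")
        rse_post = fit(s, FitConfig(mode="postdiction", seed=0)).rse
        rse_pre = fit(s, FitConfig(mode="prediction", seed=0)).rse
        assert rse_pre > rse_post

    def test_objective_at_fit_equals_reported_sse(self):
        s = series_from_model(START, TRUE, "CVE_out")
        cfg = FitConfig(seed=3)
        res = fit(s, cfg)
        assert objective(res.alpha, s, cfg) == pytest.approx(res.sse, rel=1e-12, abs=1e-15)


class TestFitShared:
    def test_shared_recovery(self):
        cts = series_from_model(START, TRUE, "CTS_in")
        cve = series_from_model(START, TRUE, "CVE_in")
        r_cts, r_cve = fit_shared(cts, cve, FitConfig(seed=2))
        assert r_cts.alpha == r_cve.alpha
        for a_hat, a_true in zip(r_cts.alpha.as_tuple(), TRUE.as_tuple()):
            assert abs(a_hat - a_true) / a_true < 0.01

    def test_shared_rse_not_better_than_individual(self):
        other = LearningRates(4e-6, 3e-5, 1.2e-5)
        cts = series_from_model(START, TRUE, "CTS_in")
        cve = series_from_model(START, other, "CVE_in")
        cfg = FitConfig(seed=2)
        r_cts, r_cve = fit_shared(cts, cve, cfg)
        assert r_cts.rse >= fit(cts, cfg).rse - 1e-9
        assert r_cve.rse >= fit(cve, cfg).rse - 1e-9

    def test_identical_series_match_single_fit(self):
        s = series_from_model(START, TRUE, "CTS_in")
        cfg = FitConfig(seed=4)
        r1, r2 = fit_shared(s, s, cfg)
        single = fit(s, cfg)
        assert r1.alpha.as_tuple() == pytest.approx(single.alpha.as_tuple(), rel=1e-6)


class TestErrorMetrics:
    def test_unity_initial_gains_zero_baseline_error(self):
        for mode in ("prediction", "postdiction"):
            s = series_from_model(GainState(1, 1, 1), TRUE, "CTS_in", mode=mode)
            res = fit(s, FitConfig(mode=mode, seed=0))
            assert res.metrics["baseline_error"] == pytest.approx(0.0, abs=1e-9)

    def test_baseline_postdiction_error_hand_computed(self):
        """Trial-1 gains from block (13, 12.4, 0.8): baseline E_post = 0.4 deg."""
        s = series_from_model(
            GainState(1.0, 12.4 / 13.0, 12.2 / 12.4), LearningRates(0, 0, 0), "CTS_in"
        )
        res = fit(s, FitConfig(seed=0))
        assert res.metrics["baseline_error"] == pytest.approx(0.4, abs=1e-6)

    def test_full_decline_is_100_pct(self):
        s = series_from_model(START, TRUE, "CTS_in")
        res = fit(s, FitConfig(seed=0))
        traj_err = res.trajectory.error
        expected = 100 * (1 - abs(traj_err[-1]) / abs(traj_err[0]))
        assert res.metrics["pct_decline"] == pytest.approx(expected)
        assert 0 < res.metrics["pct_decline"] <= 100


class TestCompareModels:
    def _fits(self, rses, mode="postdiction"):
        s = series_from_model(START, TRUE, "CTS_in")
        res = fit(s, FitConfig(seed=0))
        out = []
        for r in rses:
            clone = dataclasses.replace(res)
            clone.rse = r
            out.append(clone)
        return out

    def test_identical_fits_t_zero(self):
        a = self._fits([0.5, 0.6, 0.7])
        res = compare_models(a, a)
        assert res["t"] == 0.0

    def test_known_paired_t(self):
        a = self._fits([0.8, 1.0, 0.9])
        b = self._fits([0.5, 0.5, 0.5])
        res = compare_models(a, b)
        assert res["mean_diff"] == pytest.approx(0.4)
        assert res["t"] == pytest.approx(0.4 / (0.1 / math.sqrt(3)), abs=1e-3)
        assert res["df"] == 2

    def test_size_mismatch(self):
        with pytest.raises(ValueError):
            compare_models(self._fits([0.5]), self._fits([0.5, 0.6]))
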