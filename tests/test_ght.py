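"""Geary-Hinkley localized caller: statistics, p-values, calibration."""

import numpy as np
import pytest
from scipy.stats import norm

from aluscancnv.ght import (
    LocalizedCallConfig,
    adjusted_ratio,
    call_localized,
    call_window,
    ght_t,
    ght_t_gc,
    two_sided_p,
)
from aluscancnv.simulate import SimulationTruth, simulate_pair, synthetic_windows


class TestAdjustedRatio:
    @pytest.mark.parametrize(
        "Rt, Rc, Nt, Nc, expected",
        [
            (20, 10, 2_000_000, 1_000_000, 1.0),
            (15, 10, 1_000_000, 1_000_000, 1.5),
            (10, 10, 500_000, 500_000, 1.0),
        ],
    )
    def test_total_read_scaling(self, Rt, Rc, Nt, Nc, expected):
        assert adjusted_ratio(Rt, Rc, Nt, Nc) == pytest.approx(expected)

    def test_zero_control_depth_excluded(self):
        with pytest.raises(ValueError):
            adjusted_ratio(5, 0, 100, 100)


class TestGHTStatistic:
    def test_ratio_one_equal_lambdas_gives_zero(self):
        assert ght_t(1.0, 10, 10) == pytest.approx(0.0)

    def test_derived_value(self):
        # independent arithmetic: (100*1.2 - 100)/sqrt(100*1.44 + 100) = 20/sqrt(244)
        assert ght_t(1.2, 100, 100) == pytest.approx(20 / np.sqrt(244))
        assert ght_t(1.2, 100, 100) == pytest.approx(1.28037, abs=1e-5)

    def test_monotone_increasing_in_r(self):
        r = np.linspace(0.2, 5.0, 200)
        t = ght_t(r, 80, 120)
        assert (np.diff(t) > 0).all()

    def test_non_positive_lambda_rejected(self):
        with pytest.raises(ValueError):
            ght_t(1.0, 0, 10)

    def test_gc_group_statistic_uses_group_lambdas(self):
        lam_t = {0: 50.0, 1: 100.0}
        lam_c = {0: 50.0, 1: 100.0}
        # window in group 0 must use the group-0 means only
        assert ght_t_gc(1.2, 0, lam_t, lam_c) == pytest.approx(ght_t(1.2, 50, 50))
        assert ght_t_gc(1.2, 1, lam_t, lam_c) == pytest.approx(ght_t(1.2, 100, 100))

    def test_shared_lambdas_reduce_to_global_form(self):
        lam = {g: 77.0 for g in range(20)}
        for g in (0, 7, 19):
            assert ght_t_gc(0.9, g, lam, lam) == pytest.approx(ght_t(0.9, 77, 77))

    def test_missing_group_raises(self):
        with pytest.raises(KeyError):
            ght_t_gc(1.0, 5, {0: 1.0}, {0: 1.0})


class TestTwoSidedP:
    def test_t_zero_gives_p_one(self):
        assert two_sided_p(0.0, 1.2) == pytest.approx(1.0)

    def test_upper_tail_value(self):
        # Phi(1.6449) ~ 0.95, so p ~ 0.10; high-precision CDF check
        assert two_sided_p(1.6449, 1.5) == pytest.approx(2 * norm.sf(1.6449), abs=1e-12)
        assert two_sided_p(1.6449, 1.5) == pytest.approx(0.1000, abs=2e-4)

    def test_ratio_one_forces_p_one(self):
        assert two_sided_p(3.0, 1.0) == 1.0

    def test_tail_symmetry(self):
        for t in (0.3, 1.1, 2.7):
            assert two_sided_p(t, 1.5) == pytest.approx(two_sided_p(-t, 0.5))


class TestCallWindow:
    def test_gain_call_chain(self):
        # r = 1.4, t = 40/sqrt(296) = 2.32495, p = 2(1-Phi(t)) = 0.020095
        out = call_window(140, 100, 1000.0, 1000.0, 100, 100)
        assert out["r"] == pytest.approx(1.4)
        assert out["t"] == pytest.approx(40 / np.sqrt(296))
        assert out["p"] == pytest.approx(0.0201, abs=1e-4)
        assert out["state"] == "gain"

    def test_ratio_one_neutral(self):
        out = call_window(100, 100, 1000.0, 1000.0, 60, 140)
        assert out["state"] == "neutral"

    def test_large_p_neutral(self):
        out = call_window(105, 100, 1000.0, 1000.0, 100, 100)
        assert out["p"] >= 0.05 and out["state"] == "neutral"

    def test_loss_call(self):
        out = call_window(60, 100, 1000.0, 1000.0, 100, 100)
        assert out["r"] < 1 and out["state"] == "loss"


class TestCallLocalized:
    def test_identical_profiles_all_neutral(self):
        win = synthetic_windows(500, seed=0)
        truth = SimulationTruth(seed=0, coverage_fraction=1.0)
        test, _ = simulate_pair(win, truth)
        res = call_localized(test, test)
        assert (res.calls["state"] == "neutral").all()
        assert (res.calls["r"] == 1.0).all()

    def test_null_call_fraction_near_alpha(self):
        win = synthetic_windows(20000, seed=11, with_gc=False)
        truth = SimulationTruth(seed=11, coverage_fraction=1.0)
        test, control = simulate_pair(win, truth, shared_coverage=True)
        res = call_localized(test, control)
        frac = (res.calls["state"] != "neutral").mean()
        se = np.sqrt(0.05 * 0.95 / len(res.calls))
        assert abs(frac - 0.05) < 3 * se

    def test_injected_gain_power(self):
        win = synthetic_windows(5000, seed=12, with_gc=False)
        truth = SimulationTruth(
            cnv_regions=[(1000, 1100, 2.0)], seed=12, coverage_fraction=1.0
        )
        test, control = simulate_pair(win, truth)
        res = call_localized(test, control)
        region = res.calls.iloc[1000:1100]
        assert (region["state"] == "gain").mean() > 0.99

    def test_monotone_in_test_depth(self):
        states = [
            call_window(R, 100, 1000.0, 1000.0, 100, 100)["state"]
            for R in range(40, 200, 5)
        ]
        order = {"loss": 0, "neutral": 1, "gain": 2}
        ranks = [order[s] for s in states]
        assert ranks == sorted(ranks)

    def test_unpaired_template_null_calibration(self):
        # pooled control with ~10x the test depth: the statistic must stay
        # standard normal (it self-centers at lambda_t/lambda_c)
        from aluscancnv.template import build_template
        from aluscancnv.windows import DepthProfile

        win = synthetic_windows(20000, seed=21, with_gc=False)
        rng = np.random.default_rng(21)
        refs = [
            DepthProfile(f"ref{i}", win, rng.poisson(100.0, len(win)))
            for i in range(10)
        ]
        tpl = build_template(refs)
        test = DepthProfile("t", win, rng.poisson(100.0, len(win)))
        res = call_localized(test, tpl)
        frac = (res.calls["state"] != "neutral").mean()
        se = np.sqrt(0.05 * 0.95 / len(res.calls))
        assert abs(frac - 0.05) < 3 * se
        t = res.calls["t"].to_numpy()
        assert abs(t.mean()) < 0.03
        assert abs(t.std(ddof=1) - 1.0) < 0.03

    def test_excluded_windows_reported_with_reason(self):
        win = synthetic_windows(2000, seed=13, with_gc=False)
        truth = SimulationTruth(seed=13, coverage_fraction=0.5)
        test, control = simulate_pair(win, truth, shared_coverage=False)
        res = call_localized(test, control)
        assert len(res.calls) + len(res.excluded) == len(win)
        assert set(res.excluded["reason"]).issubset(
            {"zero_depth_both", "zero_depth_test", "zero_depth_control"}
        )
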