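import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from exposim import (
    ErrorParams,
    ValidationPair,
    estimate_error_params,
    leave_out_split,
    make_monitor_network,
    make_validation_pairs,
    standard_metrics,
)


def _pair(site_id, monitor, model, site_type="background", ivar=0.0):
    rec = pd.DataFrame(
        {"day": np.arange(len(monitor)), "monitor": monitor, "model": model}
    )
    return ValidationPair(site_id, site_type, rec, ivar)


class TestEstimateErrorParams:
    def test_identity(self):
        rng = np.random.default_rng(0)
        pairs = [
            _pair(f"s{i}", v, v.copy())
            for i, v in enumerate(rng.normal(30, 5, size=(5, 50)))
        ]
        est = estimate_error_params(pairs, "background")
        assert est.rho_T == pytest.approx(1.0)
        assert est.rho_S == pytest.approx(1.0)
        assert est.lambda_T == pytest.approx(1.0)
        assert est.lambda_S == pytest.approx(1.0)

    def test_correction_noop_when_ivar_zero(self, tiny_network):
        pairs = make_validation_pairs(
            tiny_network, ErrorParams(rho_T=0.8, lambda_T=1.4), instrument_sd=0.0, seed=1
        )
        a = estimate_error_params(pairs, "background", correct_instrument=True)
        b = estimate_error_params(pairs, "background", correct_instrument=False)
        assert a.rho_T == pytest.approx(b.rho_T)
        assert a.lambda_T == pytest.approx(b.lambda_T)
        assert a.rho_S == pytest.approx(b.rho_S)
        assert a.lambda_S == pytest.approx(b.lambda_S)

    def test_correction_removes_attenuation(self):
        # monitor = true + noise, model = true: corrected rho_T ~ 1, naive < 1
        rng = np.random.default_rng(2)
        true = rng.normal(30, 6, size=(6, 3000))
        ivar = 4.0
        pairs = [
            _pair(f"s{i}", t + rng.normal(0, 2.0, t.shape), t.copy(), ivar=ivar)
            for i, t in enumerate(true)
        ]
        corrected = estimate_error_params(pairs, "background")
        naive = estimate_error_params(pairs, "background", correct_instrument=False)
        assert naive.rho_T < 0.97
        assert corrected.rho_T == pytest.approx(1.0, abs=0.02)
        assert corrected.lambda_T == pytest.approx(1.0, abs=0.05)

    def test_lambda_invariant_to_common_shift(self):
        rng = np.random.default_rng(3)
        mon = rng.normal(30, 5, size=(5, 200))
        mod = mon + rng.normal(0, 2, mon.shape)
        a = estimate_error_params(
            [_pair(f"s{i}", mon[i], mod[i]) for i in range(5)], "background"
        )
        b = estimate_error_params(
            [_pair(f"s{i}", mon[i] + 7.0, mod[i] + 7.0) for i in range(5)], "background"
        )
        assert a.lambda_T == pytest.approx(b.lambda_T)
        assert a.lambda_S == pytest.approx(b.lambda_S)

    def test_rho_invariant_to_affine_rescale(self):
        rng = np.random.default_rng(4)
        mon = rng.normal(30, 5, size=(5, 200))
        mod = mon + rng.normal(0, 2, mon.shape)
        a = estimate_error_params(
            [_pair(f"s{i}", mon[i], mod[i]) for i in range(5)], "background"
        )
        b = estimate_error_params(
            [_pair(f"s{i}", mon[i], 3.0 * mod[i] + 1.0) for i in range(5)], "background"
        )
        assert a.rho_T == pytest.approx(b.rho_T)
        assert a.rho_S == pytest.approx(b.rho_S)

    def test_excessive_instrument_variance_errors(self):
        rng = np.random.default_rng(5)
        mon = rng.normal(30, 1, size=(4, 100))
        pairs = [_pair(f"s{i}", mon[i], mon[i], ivar=100.0) for i in range(4)]
        with pytest.raises(ValueError, match="instrument variance"):
            estimate_error_params(pairs, "background")

    def test_too_few_sites(self):
        pairs = [_pair("a", np.ones(5) * 20, np.ones(5) * 21)]
        with pytest.raises(ValueError, match=">= 3 sites"):
            estimate_error_params(pairs, "background")

    def test_per_site_pooling_close_to_pooled(self, tiny_network):
        pairs = make_validation_pairs(
            tiny_network, ErrorParams(rho_T=0.8, lambda_T=1.5), instrument_sd=0.0, seed=6
        )
        pooled = estimate_error_params(pairs, "background", pooling="pooled")
        per_site = estimate_error_params(pairs, "background", pooling="per_site")
        assert per_site.rho_T == pytest.approx(pooled.rho_T, abs=0.05)
        assert per_site.lambda_T == pytest.approx(pooled.lambda_T, rel=0.10)

    def test_proportional_scale_recovers_log_plant(self):
        from exposim.errors import inject_components

        rng = np.random.default_rng(7)
        n_sites, n_days = 20, 2000
        log_true = 3.4 + np.repeat(
            rng.normal(0, 0.3, n_sites), n_days
        ).reshape(n_sites, n_days) + rng.normal(0, 0.2, (n_sites, n_days))
        planted = ErrorParams(rho_T=0.8, rho_S=0.9, lambda_T=1.5, lambda_S=1.2,
                              error_scale="proportional")
        means = log_true.mean(axis=1)
        devs = log_true - means[:, None]
        log_model = inject_components(means, devs, planted, rng)
        pairs = [
            _pair(f"s{i}", np.exp(log_true[i]), np.exp(log_model[i]))
            for i in range(n_sites)
        ]
        est = estimate_error_params(pairs, "background", scale="proportional")
        assert est.rho_T == pytest.approx(0.8, abs=0.03)
        assert est.lambda_T == pytest.approx(1.5, rel=0.06)
        assert est.rho_S == pytest.approx(0.9, abs=0.1)


class TestStandardMetrics:
    def test_perfect_model(self):
        rng = np.random.default_rng(8)
        v = rng.uniform(5, 50, 40)
        stats = standard_metrics([_pair("a", v, v.copy())])
        row = stats.per_site.iloc[0]
        assert row["MB"] == 0.0
        assert row["NMB"] == 0.0
        assert row["NMGE"] == 0.0
        assert row["RMSE"] == 0.0
        assert row["FAC2"] == 1.0

    def test_hand_example(self):
        o = np.array([10.0, 10.0, 10.0, 10.0])
        m = np.array([5.0, 10.0, 20.0, 45.0])
        row = standard_metrics([_pair("a", o, m)]).per_site.iloc[0]
        assert row["FAC2"] == pytest.approx(3 / 4)
        assert row["MB"] == pytest.approx(10.0)
        assert row["NMB"] == pytest.approx(1.0)
        assert row["NMGE"] == pytest.approx(50 / 40)
        assert row["RMSE"] == pytest.approx(math.sqrt((25 + 0 + 100 + 1225) / 4))

    def test_brute_force_oracle_random_fixture(self):
        rng = np.random.default_rng(9)
        pairs = []
        for i in range(10):
            o = rng.uniform(1, 60, 30)
            m = o * rng.uniform(0.3, 3.0, 30)
            pairs.append(_pair(f"s{i}", o, m, site_type="roadside" if i % 2 else "background"))
        stats = standard_metrics(pairs)
        for p in pairs:
            row = stats.per_site.set_index("site_id").loc[p.site_id]
            o = list(p.records["monitor"])
            m = list(p.records["model"])
            n = len(o)
            mb = sum(m[k] - o[k] for k in range(n)) / n
            rmse = math.sqrt(sum((m[k] - o[k]) ** 2 for k in range(n)) / n)
            nmb = sum(m[k] - o[k] for k in range(n)) / sum(o)
            nmge = sum(abs(m[k] - o[k]) for k in range(n)) / sum(o)
            fac2 = sum(1 for k in range(n) if 0.5 <= m[k] / o[k] <= 2.0) / n
            assert row["MB"] == pytest.approx(mb)
            assert row["RMSE"] == pytest.approx(rmse)
            assert row["NMB"] == pytest.approx(nmb)
            assert row["NMGE"] == pytest.approx(nmge)
            assert row["FAC2"] == pytest.approx(fac2)
        # site-type averages: unweighted means over sites
        bg = stats.per_site[stats.per_site.site_type == "background"]
        avg = stats.by_type.set_index("site_type").loc["background"]
        assert avg["RMSE"] == pytest.approx(bg["RMSE"].mean())

    def test_nonpositive_monitor_days_excluded(self):
        o = np.array([0.0, -1.0, 10.0, 20.0])
        m = np.array([5.0, 5.0, 10.0, 25.0])
        row = standard_metrics([_pair("a", o, m)]).per_site.iloc[0]
        assert row["n_excluded"] == 2
        assert row["NMB"] == pytest.approx(5 / 30)
        assert row["FAC2"] == 1.0
        # MB and RMSE still use all days
        assert row["MB"] == pytest.approx((5 + 6 + 0 + 5) / 4)

    def test_all_nonpositive_flagged(self):
        with pytest.warns(RuntimeWarning, match="normalized"):
            stats = standard_metrics([_pair("a", np.zeros(3), np.ones(3))])
        assert np.isnan(stats.per_site.iloc[0]["NMB"])

    @settings(max_examples=30, deadline=None)
    @given(
        o=arrays(float, 12, elements=st.floats(0.5, 100.0)),
        m=arrays(float, 12, elements=st.floats(0.1, 150.0)),
    )
    def test_metric_inequalities(self, o, m):
        row = standard_metrics([_pair("a", o, m)]).per_site.iloc[0]
        assert row["RMSE"] >= abs(row["MB"]) - 1e-12
        assert row["NMGE"] >= abs(row["NMB"]) - 1e-12
        assert 0.0 <= row["FAC2"] <= 1.0


class TestLeaveOutSplit:
    def test_47_sites_tenth(self):
        net = make_monitor_network(n_background=45, n_roadside=2, n_days=5, seed=0)
        groups = leave_out_split(net, 0.1, seed=1)
        assert len(groups) == 10
        sizes = sorted(len(g) for g in groups)
        assert set(sizes) <= {4, 5}
        flat = [s for g in groups for s in g]
        assert sorted(flat) == sorted(net.site_ids)
        assert len(set(flat)) == 47

    def test_even_split(self):
        net = make_monitor_network(n_background=5, n_roadside=5, n_days=5, seed=2)
        groups = leave_out_split(net, 0.5, seed=3)
        assert [len(g) for g in groups] == [5, 5]

    def test_deterministic(self, tiny_network):
        a = leave_out_split(tiny_network, 0.25, seed=4)
        b = leave_out_split(tiny_network, 0.25, seed=4)
        assert a == b

    def test_bad_fraction(self, tiny_network):
        with pytest.raises(ValueError):
            leave_out_split(tiny_network, 0.0, seed=0)
        with pytest.raises(ValueError):
            leave_out_split(tiny_network, 1.0, seed=0)
        with pytest.raises(ValueError, match="empty"):
            leave_out_split(tiny_network, 0.01, seed=0)
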