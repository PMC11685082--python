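"""Sampling distributions, the Gaussian copula, DSA and PSA machinery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sclccea.uncertainty import (ParamSpec, build_distribution, correlated_sample,
                                 dsa, psa)


def spec(name="p", base=10.0, low=5.0, high=15.0, dist="gamma"):
    return ParamSpec(name, base, low, high, dist)


class TestBuildDistribution:
    def test_beta_mean_matches_base(self):
        d = build_distribution(spec("u", 0.84, 0.63, 0.90, "beta"))
        x = d.rvs(size=10_000, random_state=np.random.default_rng(0))
        assert abs(x.mean() - 0.84) < 0.01
        assert np.all((x >= 0.63) & (x <= 0.90))

    def test_beta_handles_negative_disutility_range(self):
        d = build_distribution(spec("du", -0.19, -0.2375, -0.1425, "beta"))
        x = d.rvs(size=5_000, random_state=np.random.default_rng(1))
        assert abs(x.mean() - (-0.19)) < 0.005
        assert np.all(x < 0)

    def test_gamma_positive_support(self):
        d = build_distribution(spec())
        x = d.rvs(size=5_000, random_state=np.random.default_rng(2))
        assert np.all(x > 0)
        assert abs(x.mean() - 10.0) < 0.2

    def test_degenerate_range_point_mass(self):
        d = build_distribution(spec(base=3.0, low=3.0, high=3.0))
        assert np.all(d.rvs(size=10) == 3.0)
        assert np.all(d.ppf(np.array([0.1, 0.9])) == 3.0)

    def test_infeasible_moments_fall_back_to_uniform(self):
        # base equal to the upper bound: no valid beta mean
        with pytest.warns(UserWarning, match="uniform"):
            d = build_distribution(spec("x", 1.0, 0.0, 1.0, "beta"))
        x = d.rvs(size=1000, random_state=np.random.default_rng(3))
        assert np.all((x >= 0) & (x <= 1))

    def test_order_violation_rejected(self):
        with pytest.raises(ValueError, match="low <= base <= high"):
            spec(base=1.0, low=5.0, high=15.0)


class TestCorrelatedSample:
    def params(self):
        return [ParamSpec("a", 0.5, 0.3, 0.7, "beta"),
                ParamSpec("b", 0.5, 0.3, 0.7, "beta"),
                ParamSpec("c", 100.0, 50.0, 150.0, "gamma")]

    def test_identity_correlation_independent(self):
        df = correlated_sample(self.params(), [], n=10_000, seed=1)
        rho = stats.spearmanr(df["a"], df["b"]).statistic
        assert abs(rho) < 0.05

    def test_positive_rank_correlation(self):
        df = correlated_sample(self.params(), [("a", "b", 0.9)], n=10_000, seed=2)
        rho = stats.spearmanr(df["a"], df["b"]).statistic
        assert 0.85 <= rho <= 0.95

    def test_negative_rank_correlation(self):
        df = correlated_sample(self.params(), [("a", "c", -0.9)], n=10_000, seed=3)
        rho = stats.spearmanr(df["a"], df["c"]).statistic
        assert -0.95 <= rho <= -0.85

    def test_simplex_groups_renormalized(self):
        params = [ParamSpec(f"m{i}", 0.25, 0.15, 0.35, "beta") for i in range(4)]
        df = correlated_sample(params, [], n=500, seed=4,
                               simplex_groups=[[f"m{i}" for i in range(4)]])
        sums = df[[f"m{i}" for i in range(4)]].sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-12)

    def test_seeded_reproducibility(self):
        a = correlated_sample(self.params(), [("a", "b", 0.9)], n=200, seed=9)
        b = correlated_sample(self.params(), [("a", "b", 0.9)], n=200, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestDSA:
    def test_zero_width_parameter(self):
        p = ParamSpec("x", 2.0, 2.0, 2.0, "gamma")
        out = dsa([p], lambda ov: 5.0 * ov.get("x", 2.0))
        assert out.loc[0, "icer_width"] == 0.0

    def test_linear_model_bar_width(self):
        c = 7.0
        p = ParamSpec("x", 2.0, 1.0, 4.0, "gamma")
        out = dsa([p], lambda ov: c * ov.get("x", 2.0))
        assert out.loc[0, "icer_width"] == pytest.approx(c * 3.0)

    def test_two_parameter_ordering_matches_brute_force(self):
        ps = [ParamSpec("x", 2.0, 1.0, 3.0, "gamma"),
              ParamSpec("y", 5.0, 1.0, 13.0, "gamma")]

        def model(ov):
            return 10.0 * ov.get("x", 2.0) + 2.0 * ov.get("y", 5.0)

        out = dsa(ps, model)
        widths = {"x": 10.0 * 2.0, "y": 2.0 * 12.0}  # brute force
        assert out.iloc[0]["parameter"] == max(widths, key=widths.get)

    def test_model_failure_recorded(self):
        def model(ov):
            raise RuntimeError("boom")

        out = dsa([spec()], model)
        assert bool(out.loc[0, "failed"])


class TestPSA:
    def toy_draws(self, n, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({"dc": rng.normal(4000.0, 500.0, n),
                             "dq": rng.normal(0.2, 0.05, n)})

    @staticmethod
    def toy_model(row):
        return {"ref": (0.0, 0.0), "new": (row["dc"], row["dq"])}

    def test_single_draw_step_function(self):
        res = psa(self.toy_draws(1), self.toy_model, ["ref", "new"], "ref")
        assert set(np.unique(res.ceac_pairwise["new"])) <= {0.0, 1.0}

    def test_identical_draws_give_zero_one(self):
        draws = pd.DataFrame({"dc": [4000.0] * 5, "dq": [0.2] * 5})
        res = psa(draws, self.toy_model, ["ref", "new"], "ref")
        assert set(np.unique(res.ceac_pairwise["new"])) <= {0.0, 1.0}

    def test_normal_oracle(self):
        """CEAC matches the closed-form normal probability
        P(w dQ - dC > 0) with dC, dQ independent normals."""
        n = 5000
        res = psa(self.toy_draws(n, seed=5), self.toy_model, ["ref", "new"], "ref",
                  wtp_grid=np.array([10_000.0, 20_000.0, 30_000.0]))
        for w in (10_000.0, 20_000.0, 30_000.0):
            mu = w * 0.2 - 4000.0
            sd = np.hypot(w * 0.05, 500.0)
            expected = stats.norm.cdf(mu / sd)
            got = float(res.ceac_pairwise.loc[res.ceac_pairwise["wtp"] == w, "new"].iloc[0])
            assert got == pytest.approx(expected, abs=0.025)

    def test_winner_rule_sums_to_one(self):
        res = psa(self.toy_draws(500), self.toy_model, ["ref", "new"], "ref")
        sums = res.ceac_winner.drop(columns="wtp").sum(axis=1)
        assert np.allclose(sums, 1.0)

    def test_pairwise_monotone_when_dq_positive(self):
        draws = self.toy_draws(2000, seed=6)
        draws["dq"] = np.abs(draws["dq"]) + 0.01
        res = psa(draws, self.toy_model, ["ref", "new"], "ref")
        assert np.all(np.diff(res.ceac_pairwise["new"]) >= -1e-12)

    def test_empty_draws_rejected(self):
        with pytest.raises(ValueError, match="at least one draw"):
            psa(pd.DataFrame(), self.toy_model, ["ref", "new"], "ref")
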