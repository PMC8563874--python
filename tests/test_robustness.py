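"""Latin hypercube sampling and the Δp-RIP3 statistic."""

import numpy as np
import pytest
from scipy import stats

from ripnet import build_network
from ripnet.parameters import smodel_lhs_ranges, smodel_nominal_parameters
from ripnet.robustness import (
    ParameterRanges,
    delta_p_rip3,
    estimate_negative_probability,
    lhs_sample,
    ssa_negative_check,
)


class TestLhs:
    def test_one_sample_per_log_bin(self):
        """n=4 on [1, 16]: exactly one draw in each octave."""
        ranges = ParameterRanges({"k": (1.0, 16.0)})
        vals = sorted(ps["k"] for ps in lhs_sample(ranges, 4, seed=0))
        edges = [1.0, 2.0, 4.0, 8.0, 16.0]
        counts = np.histogram(vals, bins=edges)[0]
        assert list(counts) == [1, 1, 1, 1]

    def test_stratification_exact_for_every_parameter(self):
        ranges = ParameterRanges({"a": (1e-3, 1e3), "b": (0.1, 10.0)})
        n = 64
        sets = lhs_sample(ranges, n, seed=5)
        for name, (lo, hi) in ranges.bounds.items():
            logs = np.log([ps[name] for ps in sets])
            edges = np.linspace(np.log(lo), np.log(hi), n + 1)
            counts = np.histogram(logs, bins=edges)[0]
            assert np.all(counts == 1)

    def test_marginal_log_uniformity(self):
        ranges = ParameterRanges({"k": (1e-2, 1e2)})
        vals = np.log([ps["k"] for ps in lhs_sample(ranges, 10_000, seed=2)])
        u = (vals - np.log(1e-2)) / (np.log(1e2) - np.log(1e-2))
        assert stats.kstest(u, "uniform").pvalue > 0.01

    def test_same_seed_identical_batch(self):
        ranges = ParameterRanges({"a": (0.1, 10.0), "b": (1.0, 100.0)})
        x = lhs_sample(ranges, 50, seed=9)
        y = lhs_sample(ranges, 50, seed=9)
        assert x == y

    def test_invalid_ranges_rejected(self):
        with pytest.raises(ValueError):
            ParameterRanges({"k": (0.0, 1.0)})
        with pytest.raises(ValueError):
            ParameterRanges({"k": (2.0, 1.0)})


class TestDelta:
    def test_identical_scales_give_exact_zero(self):
        net = build_network("SModel2")
        params = smodel_nominal_parameters("SModel2")
        assert delta_p_rip3(net, params, scale_low=1.0) == 0.0

    def test_full_model2_negative_regulation_at_calibrated_parameters(self):
        from ripnet.parameters import default_parameters

        net = build_network("Model2")
        assert delta_p_rip3(net, default_parameters("Model2"), t_end=420.0) < 0

    def test_continuity_in_the_compared_scale(self):
        """|Δ| shrinks as the two compared RIP1 levels approach each other."""
        net = build_network("SModel2")
        params = smodel_nominal_parameters("SModel2")
        deltas = [abs(delta_p_rip3(net, params, scale_low=s)) for s in (0.5, 0.9, 0.99)]
        assert deltas[0] > deltas[1] > deltas[2]

    def test_no_rip3_activation_means_probability_zero(self):
        """With seeding and amplification removed, Δ < 0 is impossible."""
        ranges = smodel_lhs_ranges("SModel2")
        eps = 1e-25
        ranges["k_seed"] = (eps, eps * 10)
        ranges["k_amp"] = (eps, eps * 10)
        s = estimate_negative_probability(
            "SModel2", ParameterRanges(ranges), n=100, seed=4
        )
        assert s.n_negative == 0

    def test_disjoint_seeds_agree_within_binomial_ci(self):
        """Two independent samplings give compatible probabilities."""
        a = estimate_negative_probability("SModel2", n=600, seed=21)
        b = estimate_negative_probability("SModel2", n=600, seed=22)
        p_pool = (a.n_negative + b.n_negative) / (a.n_sampled + b.n_sampled)
        se = np.sqrt(2 * p_pool * (1 - p_pool) / 600)
        assert abs(a.probability - b.probability) < 2.576 * se + 1e-12

    def test_batch_counts_sum_to_total(self):
        s = estimate_negative_probability("SModel2", n=300, seed=8, batch_size=100)
        assert sum(s.batch_counts) == s.n_negative
        assert 0.0 <= s.probability <= 1.0


class TestSsaCheck:
    def test_sign_agreement_on_a_negative_regulation_set(self):
        """ODE and ensemble-mean SSA agree on the direction of regulation."""
        params = smodel_nominal_parameters("SModel2")
        # strengthen caspase-8 recruitment: a parameter regime with
        # clearly negative ODE delta
        params = params.copy()
        params["k_c8_rec"] = 1e-5
        params["k_cleave"] = 1e-4
        net = build_network("SModel2")
        ode = delta_p_rip3(net, params)
        res = ssa_negative_check("SModel2", params, n_runs=8, seed=3)
        assert res["ode_delta"] == ode
        assert res["agree"]

    def test_rip3_absent_gives_zero_delta_both_ways(self):
        params = smodel_nominal_parameters("SModel2").copy()
        params["RIP3_0"] = 1e-30
        net = build_network("SModel2")
        assert delta_p_rip3(net, params) == 0.0
        res = ssa_negative_check("SModel2", params, n_runs=3, seed=1)
        assert res["ssa_mean_delta"] == 0.0

    def test_too_few_runs_rejected(self):
        with pytest.raises(ValueError):
            ssa_negative_check("SModel2", smodel_nominal_parameters("SModel2"), n_runs=1, seed=0)
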