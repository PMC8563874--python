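"""Deterministic and stochastic simulation contracts."""

import numpy as np
import pytest

from ripnet import (
    PerturbationSpec,
    apply_perturbation,
    build_network,
    default_parameters,
    readout,
    simulate_ode,
    simulate_ssa,
)
from ripnet.network import KineticParameterSet
from ripnet.simulate import initial_state_with_params


def _turnover_off(params):
    p = params.copy()
    for k in ("k_syn_rip1", "k_deg_rip1", "k_syn_proc8", "k_deg_proc8"):
        p[k] = 1e-30
    return p


class TestOde:
    def test_no_stimulus_leaves_complexes_empty(self, model2, model2_params, minute_grid):
        net, p = apply_perturbation(model2, PerturbationSpec(tnf_dose=0.0), model2_params)
        traj = simulate_ode(net, _turnover_off(p), minute_grid)
        for sp in ("TNFR1a", "C1_RIP1", "C1_TRADD", "Nec", "pRIP3", "C2", "pMLKL"):
            assert np.all(traj.series(sp) == 0.0), sp

    def test_rip1_knockout_abolishes_rip3_phosphorylation(self, model2, model2_params, minute_grid):
        net, p = apply_perturbation(
            model2, PerturbationSpec(expression_scale={"RIP1": 0}), model2_params
        )
        traj = simulate_ode(net, p, minute_grid)
        assert readout(traj, "p-RIP3", "peak") < 1e-6

    def test_identical_inputs_identical_outputs(self, model2, model2_params, minute_grid):
        a = simulate_ode(model2, model2_params, minute_grid)
        b = simulate_ode(model2, model2_params, minute_grid)
        assert np.array_equal(a.amounts, b.amounts)

    def test_non_negativity(self, model2, model2_params, minute_grid):
        for scale in (1.0, 0.1, 0.01):
            net, p = apply_perturbation(
                model2, PerturbationSpec(expression_scale={"RIP1": scale}), model2_params
            )
            traj = simulate_ode(net, p, minute_grid)
            assert traj.amounts.min() >= 0.0

    @pytest.mark.parametrize("variant", ["Model1", "Model2", "Model3", "Model4"])
    def test_moiety_conservation_with_turnover_off(self, variant, minute_grid):
        net = build_network(variant)
        p = _turnover_off(default_parameters(variant))
        traj = simulate_ode(net, p, minute_grid)
        for protein in ("RIP3", "RIP1", "FADD"):
            members = net.moiety_members(protein)
            total = sum(w * traj.series(n) for n, w in members.items())
            assert np.all(np.abs(total / total[0] - 1.0) < 1e-3), (variant, protein)

    def test_bad_grid_rejected(self, model2, model2_params):
        with pytest.raises(ValueError):
            simulate_ode(model2, model2_params, [10.0, 20.0])
        with pytest.raises(ValueError):
            simulate_ode(model2, model2_params, [0.0, 5.0, 5.0])

    def test_missing_parameter_reported(self, model2, model2_params, minute_grid):
        p = model2_params.copy()
        del p["k_amp"]
        with pytest.raises(KeyError):
            simulate_ode(model2, p, minute_grid)


class TestReadout:
    def test_peak_dominates_point_queries(self, model2, model2_params, minute_grid):
        traj = simulate_ode(model2, model2_params, minute_grid)
        peak = readout(traj, "p-RIP3", "peak")
        for t in (0, 60, 240, 420):
            assert peak >= readout(traj, "p-RIP3", t)

    def test_time_zero_equals_initial_derived_value(self, model2, model2_params, minute_grid):
        traj = simulate_ode(model2, model2_params, minute_grid)
        assert readout(traj, "p-RIP3", 0.0) == 0.0
        y0 = initial_state_with_params(model2, model2_params)
        assert readout(traj, "p-MLKL", 0.0) == y0[model2.index["pMLKL"]]

    def test_unknown_readout_and_out_of_window(self, model2, model2_params, minute_grid):
        traj = simulate_ode(model2, model2_params, minute_grid)
        with pytest.raises(KeyError):
            readout(traj, "nonsense", "peak")
        with pytest.raises(ValueError):
            readout(traj, "p-RIP3", 1e5)

    def test_necrosome_proc8_decreases_with_rip1(self, model2, model2_params, minute_grid):
        vals = []
        for scale in (1.0, 0.5, 0.2):
            net, p = apply_perturbation(
                model2, PerturbationSpec(expression_scale={"RIP1": scale}), model2_params
            )
            vals.append(readout(simulate_ode(net, p, minute_grid), "proC8-RIP3-complex", "peak"))
        assert vals[0] > vals[1] > vals[2]


class TestSsa:
    def test_same_seed_identical_path(self, toy_binding_network, toy_params):
        a = simulate_ssa(toy_binding_network, toy_params, 30.0, seed=11)
        b = simulate_ssa(toy_binding_network, toy_params, 30.0, seed=11)
        assert np.array_equal(a.amounts, b.amounts)
        c = simulate_ssa(toy_binding_network, toy_params, 30.0, seed=12)
        assert not np.array_equal(a.amounts, c.amounts)

    def test_all_zero_initial_state_stays_zero(self, toy_binding_network, toy_params):
        net = toy_binding_network.with_initial({"A": 0, "B": 0, "C": 0})
        traj = simulate_ssa(net, toy_params, 30.0, seed=1)
        assert np.all(traj.amounts == 0)

    def test_non_integer_initial_amounts_rejected(self, toy_binding_network, toy_params):
        net = toy_binding_network.with_initial({"A": 10.5})
        with pytest.raises(ValueError, match="integer"):
            simulate_ssa(net, toy_params, 10.0, seed=1)

    def test_ensemble_mean_matches_ode_within_3se(self, toy_binding_network, toy_params):
        """Large-copy SSA converges to the deterministic solution."""
        t_end = 30.0
        grid = np.linspace(0.0, t_end, 31)
        ode = simulate_ode(toy_binding_network, toy_params, grid)
        c_ode = ode.series("C")[-1]
        n_runs = 200
        finals = [
            simulate_ssa(toy_binding_network, toy_params, t_end, seed=1000 + i,
                         n_record=31).series("C")[-1]
            for i in range(n_runs)
        ]
        mean = np.mean(finals)
        se = np.std(finals, ddof=1) / np.sqrt(n_runs)
        assert abs(mean - c_ode) < 3 * max(se, 1e-9)
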