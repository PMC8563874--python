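"""Structural properties of the model variants and perturbation semantics."""

import numpy as np
import pytest

from ripnet import (
    KineticParameterSet,
    PerturbationSpec,
    apply_perturbation,
    build_network,
    default_parameters,
    network_from_yaml,
    network_to_yaml,
)
from ripnet.network import C8_RIP3_INTERINHIBITION, CASPASE_CATALYTIC, RIP1_WILDTYPE_MPC
from ripnet.parameters import smodel_nominal_parameters
from ripnet.smodels import SMODEL_PARAM_COUNTS


class TestVariantStructure:
    def test_model3_contains_models_1_and_2(self):
        ids3 = build_network("Model3").reaction_ids()
        assert build_network("Model1").reaction_ids() <= ids3
        assert build_network("Model2").reaction_ids() <= ids3

    def test_model4_is_model2_plus_tradd_activation(self):
        ids2 = build_network("Model2").reaction_ids()
        ids4 = build_network("Model4").reaction_ids()
        assert ids2 <= ids4
        extra = ids4 - ids2
        # the non-cleaving TRADD-route pair plus its scaffold chain
        assert {"V45", "V46"} <= extra
        # the TRADD-activated caspase-8 of Model 4 neither cleaves RIP1/RIP3
        # nor is suppressed by RIP3
        net4 = build_network("Model4")
        for rxn in net4.reactions:
            reactants = dict(rxn.reactants)
            if "C8aT" in reactants:
                assert not ({"RIP1a", "RIP3", "pRIP3"} & set(dict(rxn.products)))

    def test_no_interinhibition_variant_never_consumes_rip3_via_c8(self):
        net = build_network("Model2_noC8RIP3inhibition")
        assert not (set(C8_RIP3_INTERINHIBITION) & net.reaction_ids())
        for rxn in net.reactions:
            reactants = dict(rxn.reactants)
            if "C8a" in reactants or "C2" in reactants:
                assert "RIP3c" not in dict(rxn.products)

    @pytest.mark.parametrize("variant,count", sorted(SMODEL_PARAM_COUNTS.items()))
    def test_smodel_free_parameter_counts(self, variant, count):
        nominal = smodel_nominal_parameters(variant)
        assert len(nominal) == count
        net = build_network(variant)
        sampled_inits = {k[:-2] for k in nominal if k.endswith("_0")}
        assert set(net.rate_constant_names) | {f"{s}_0" for s in sampled_inits} == set(nominal)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="unknown model variant"):
            build_network("Model9")

    def test_models_1_to_3_drawn_from_v1_v44(self):
        for v in ("Model1", "Model2", "Model3"):
            nums = {int(i[1:]) for i in build_network(v).reaction_ids()}
            assert max(nums) <= 44

    def test_mass_action_orders_at_most_two(self):
        for v in ("Model1", "Model2", "Model3", "Model4"):
            assert all(r.order <= 2 for r in build_network(v).reactions)


class TestPerturbations:
    def test_knockout_zeroes_initial_amount_and_synthesis(self, model2, model2_params):
        net, p = apply_perturbation(
            model2, PerturbationSpec(expression_scale={"RIP1": 0}), model2_params
        )
        assert net.initial_state()[net.index["RIP1"]] == 0
        assert p["k_syn_rip1"] < 1e-20
        # original inputs untouched
        assert model2.initial_state()[model2.index["RIP1"]] == RIP1_WILDTYPE_MPC
        assert model2_params["k_syn_rip1"] > 1e-3

    def test_half_expression_arithmetic(self, model2, model2_params):
        net, _ = apply_perturbation(
            model2, PerturbationSpec(expression_scale={"RIP1": 0.5}), model2_params
        )
        assert net.initial_state()[net.index["RIP1"]] == pytest.approx(25_500)

    def test_zvad_blocks_catalysis_but_not_binding(self):
        net4 = build_network("Model4")
        params = default_parameters("Model4")
        _, p = apply_perturbation(net4, PerturbationSpec(catalytic_block={"zVAD"}), params)
        blocked = {r.rate_constant_name for r in net4.reactions if r.id in CASPASE_CATALYTIC}
        for name in blocked:
            assert p[name] < 1e-20
        for r in net4.reactions:
            if r.kind == "binding":
                assert p[r.rate_constant_name] == params[r.rate_constant_name]

    def test_unknown_protein_and_negative_scale_rejected(self, model2, model2_params):
        with pytest.raises(ValueError, match="unknown protein"):
            apply_perturbation(model2, PerturbationSpec(expression_scale={"XYZ": 1}), model2_params)
        with pytest.raises(ValueError, match="negative"):
            PerturbationSpec(expression_scale={"RIP1": -0.5})


class TestParameterSetAndSerialization:
    def test_rate_constants_must_be_positive(self):
        with pytest.raises(ValueError, match="must be > 0"):
            KineticParameterSet({"k": 0.0})

    def test_yaml_round_trip(self, model2, model2_params):
        text = network_to_yaml(model2, model2_params)
        net2, params2 = network_from_yaml(text)
        assert net2.species_names == model2.species_names
        assert net2.reaction_ids() == model2.reaction_ids()
        assert params2 == model2_params
        assert np.allclose(net2.initial_state(), model2.initial_state())

    def test_missing_rate_constant_detected(self, model2, model2_params):
        p = model2_params.copy()
        del p["k_seed"]
        with pytest.raises(KeyError, match="k_seed"):
            model2.rate_vector(p)
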