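"""Reduced (simplified) model variants for random-parameterization analysis.

Each full model carries > 50 parameters; the reduced variants keep the
mechanism-defining core with 14 (SModel1), 14 (SModel2) and 16 (SModel3)
sampled parameters (rate constants plus the RIP3 and pro-caspase-8 pools,
which enter the sampling as ``RIP3_0`` / ``ProC8_0``).

Shared necroptotic core: stimulus-driven RIP1 activation, RIP1-seeded
RIP3 phosphorylation with RIP3->RIP3 amplification, lumped Ppm1b
dephosphorylation, and caspase-8-mediated cleavage of phospho-RIP3 with
reciprocal suppression of caspase-8 by phospho-RIP3.  The variants differ
only in how caspase-8 reaches the necrosome:

* SModel1 -- recruitment by active TRADD, which active RIP1 sequesters
  (receptor-competition surrogate);
* SModel2 -- recruitment by active RIP1 itself;
* SModel3 -- both routes feeding one caspase-8 pool.

Copy numbers are scaled down (RIP1 pool 5,000) so the reduced models are
also cheap to simulate stochastically.
"""

from __future__ import annotations

from .network import ReactionNetwork, Species, Reaction

__all__ = ["build_smodel", "SMODEL_PARAM_COUNTS"]

SMODEL_PARAM_COUNTS = {"SModel1": 14, "SModel2": 14, "SModel3": 16}

#: reduced-model RIP1 reference pool (the scan variable; not sampled)
SMODEL_RIP1_POOL = 5_000.0
SMODEL_SIGNAL = 1_000.0


def _rxn(rid, kind, reactants, products, k):
    return Reaction(rid, kind, tuple(reactants), tuple(products), k)


def _core_species():
    return [
        Species("RIP1", SMODEL_RIP1_POOL),
        Species("RIP1a", 0.0),
        Species("RIP3", 3_000.0),
        Species("pRIP3", 0.0, frozenset({"phosphorylated"})),
        Species("ProC8", 2_000.0),
        Species("C8X", 0.0),
        Species("RIP3c", 0.0, frozenset({"cleaved"})),
    ]


def _core_reactions(prefix):
    return [
        _rxn(f"{prefix}4", "phosphorylation", [("RIP1a", 1), ("RIP3", 1)],
             [("RIP1a", 1), ("pRIP3", 1)], "k_seed"),
        _rxn(f"{prefix}5", "phosphorylation", [("pRIP3", 1), ("RIP3", 1)],
             [("pRIP3", 2)], "k_amp"),
        _rxn(f"{prefix}6", "dephosphorylation", [("pRIP3", 1)], [("RIP3", 1)], "k_deph"),
        _rxn(f"{prefix}7", "cleavage", [("C8X", 1), ("pRIP3", 1)],
             [("C8X", 1), ("RIP3c", 1)], "k_cleave"),
    ]


def build_smodel(variant: str) -> ReactionNetwork:
    if variant == "SModel2":
        species = [Species("SIG", SMODEL_SIGNAL), Species("pMLKL", 0.0,
                   frozenset({"phosphorylated"}))] + _core_species()
        rxns = [
            _rxn("S1", "degradation", [("SIG", 1)], [], "k_sig_decay"),
            _rxn("S2", "translocation", [("SIG", 1), ("RIP1", 1)],
                 [("SIG", 1), ("RIP1a", 1)], "k_input"),
            _rxn("S3", "degradation", [("RIP1a", 1)], [("RIP1", 1)], "k_a_decay"),
            *_core_reactions("S"),
            _rxn("S8", "binding", [("RIP1a", 1), ("ProC8", 1)], [("C8X", 1)], "k_c8_rec"),
            _rxn("S9", "unbinding", [("C8X", 1)], [("RIP1a", 1), ("ProC8", 1)], "k_c8_off"),
            _rxn("S10", "degradation", [("pRIP3", 1), ("C8X", 1)],
                 [("pRIP3", 1), ("RIP1a", 1)], "k_c8_supp"),
            _rxn("S11", "cleavage", [("C8X", 1), ("RIP3", 1)],
                 [("C8X", 1), ("RIP3c", 1)], "k_cleave_u"),
            _rxn("S12", "phosphorylation", [("pRIP3", 1)],
                 [("pRIP3", 1), ("pMLKL", 1)], "k_mlkl"),
        ]
        return ReactionNetwork(variant, species, rxns)

    if variant == "SModel1":
        species = _core_species() + [Species("TRADDa", 0.0), Species("TaR", 0.0)]
        rxns = [
            _rxn("S2", "translocation", [("RIP1", 1)], [("RIP1a", 1)], "k_input"),
            _rxn("S3", "degradation", [("RIP1a", 1)], [("RIP1", 1)], "k_a_decay"),
            *_core_reactions("S"),
            _rxn("T1", "synthesis", [], [("TRADDa", 1)], "k_t_in"),
            _rxn("T2", "degradation", [("TRADDa", 1)], [], "k_t_decay"),
            _rxn("T3", "binding", [("TRADDa", 1), ("RIP1a", 1)], [("TaR", 1)], "k_seq"),
            _rxn("T4", "binding", [("TRADDa", 1), ("ProC8", 1)], [("C8X", 1)], "k_c8_rec_t"),
            _rxn("T5", "unbinding", [("C8X", 1)], [("TRADDa", 1), ("ProC8", 1)], "k_c8_off"),
            _rxn("T6", "degradation", [("pRIP3", 1), ("C8X", 1)],
                 [("pRIP3", 1), ("TRADDa", 1)], "k_c8_supp"),
        ]
        return ReactionNetwork(variant, species, rxns)

    if variant == "SModel3":
        species = [Species("SIG", SMODEL_SIGNAL)] + _core_species() + [
            Species("TRADDa", 0.0), Species("TaR", 0.0)]
        rxns = [
            _rxn("S1", "degradation", [("SIG", 1)], [], "k_sig_decay"),
            _rxn("S2", "translocation", [("SIG", 1), ("RIP1", 1)],
                 [("SIG", 1), ("RIP1a", 1)], "k_input"),
            _rxn("S3", "degradation", [("RIP1a", 1)], [("RIP1", 1)], "k_a_decay"),
            *_core_reactions("S"),
            _rxn("S8", "binding", [("RIP1a", 1), ("ProC8", 1)], [("C8X", 1)], "k_c8_rec"),
            _rxn("S9", "unbinding", [("C8X", 1)], [("RIP1a", 1), ("ProC8", 1)], "k_c8_off"),
            _rxn("S10", "degradation", [("pRIP3", 1), ("C8X", 1)],
                 [("pRIP3", 1), ("RIP1a", 1)], "k_c8_supp"),
            _rxn("T1", "synthesis", [], [("TRADDa", 1)], "k_t_in"),
            _rxn("T2", "degradation", [("TRADDa", 1)], [], "k_t_decay"),
            _rxn("T3", "binding", [("TRADDa", 1), ("RIP1a", 1)], [("TaR", 1)], "k_seq"),
            _rxn("T4", "binding", [("TRADDa", 1), ("ProC8", 1)], [("C8X", 1)], "k_c8_rec_t"),
        ]
        return ReactionNetwork(variant, species, rxns)

    raise ValueError(f"unknown S-model variant {variant!r}")
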