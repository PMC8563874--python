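"""Species/reaction representation of the TNF-induced cell-death network.

The network couples TNF/TNFR1 ligation to two death branches: a
RIP1-FADD-caspase-8 apoptotic branch and a RIP1-RIP3-MLKL necroptotic
branch, with caspase-8 restraining necroptosis by cleaving RIP1/RIP3.
Four mechanistic variants differ in how pro-caspase-8 is activated:

* ``Model1`` -- activation through TRADD only,
* ``Model2`` -- activation through RIP1 only,
* ``Model3`` -- both routes (superset of Models 1 and 2),
* ``Model4`` -- Model 2 plus a TRADD-dependent route whose product
  neither cleaves RIP1/RIP3 nor is suppressed by RIP3.

Reactions carry catalog ids ``V1``..``V46``; Models 1-3 draw from
``V1``-``V44`` and ``V45``/``V46`` are the Model-4-specific pair.
All rate laws are mass action; amounts are copy numbers (molecules per
cell, mpc) and rate constants are in s^-1 (first order), mpc^-1 s^-1
(second order) or mpc s^-1 (zeroth order synthesis).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "Species",
    "Reaction",
    "ReactionNetwork",
    "KineticParameterSet",
    "PerturbationSpec",
    "VARIANTS",
    "build_network",
    "apply_perturbation",
    "network_to_yaml",
    "network_from_yaml",
]

REACTION_KINDS = frozenset(
    {
        "binding",
        "unbinding",
        "synthesis",
        "degradation",
        "phosphorylation",
        "dephosphorylation",
        "cleavage",
        "translocation",
    }
)

#: wildtype RIP1 abundance in mpc (absolute quantification baseline)
RIP1_WILDTYPE_MPC = 51_000.0


@dataclass(frozen=True)
class Species:
    """A molecular species: a free protein, a modified form or a complex."""

    name: str
    initial_amount: float = 0.0
    modifications: frozenset = frozenset()
    compartment: str = "cell"

    def __post_init__(self):
        if self.initial_amount < 0:
            raise ValueError(f"initial amount of {self.name} must be >= 0")
        bad = set(self.modifications) - {"phosphorylated", "cleaved"}
        if bad:
            raise ValueError(f"unknown modification tags {bad} on {self.name}")


@dataclass(frozen=True)
class Reaction:
    """One elementary mass-action reaction.

    ``reactants``/``products`` map species name -> integer stoichiometry.
    The propensity is fully determined by ``kind`` + reactants: zeroth
    order for synthesis, otherwise the mass-action product over reactants.
    """

    id: str
    kind: str
    reactants: tuple  # ((name, stoich), ...)
    products: tuple
    rate_constant_name: str

    def __post_init__(self):
        if self.kind not in REACTION_KINDS:
            raise ValueError(f"unknown reaction kind {self.kind!r} in {self.id}")
        order = sum(s for _, s in self.reactants)
        if order > 2:
            raise ValueError(f"{self.id}: mass-action order {order} > 2")
        if self.kind == "synthesis" and order != 0:
            raise ValueError(f"{self.id}: synthesis must be zeroth order")

    @property
    def order(self) -> int:
        return sum(s for _, s in self.reactants)


class KineticParameterSet(dict):
    """Named positive rate constants; a thin dict with validation."""

    def __init__(self, values=()):
        super().__init__(values)
        for name, v in self.items():
            if not v > 0:
                raise ValueError(f"rate constant {name} must be > 0, got {v}")

    def copy(self) -> "KineticParameterSet":
        return KineticParameterSet(dict.copy(self))


@dataclass
class PerturbationSpec:
    """Genetic/pharmacological scenario applied to a network.

    ``expression_scale`` rescales a protein's initial amount and (where
    present) its synthesis rate: 1 = wildtype, 0 = knockout.
    ``catalytic_block`` names blocked activities; ``"zVAD"`` zeroes every
    caspase-8 catalytic rate constant while leaving binding untouched.
    ``tnf_dose`` overrides the TNF ligand amount (mpc-equivalent).
    """

    expression_scale: dict = field(default_factory=dict)
    catalytic_block: set = field(default_factory=set)
    tnf_dose: float | None = None

    def __post_init__(self):
        for prot, s in self.expression_scale.items():
            if s < 0:
                raise ValueError(f"negative expression scale for {prot}")
        if self.tnf_dose is not None and self.tnf_dose < 0:
            raise ValueError("tnf_dose must be >= 0")


class ReactionNetwork:
    """A model variant: species list + reaction list + index machinery."""

    def __init__(self, variant: str, species: list[Species], reactions: list[Reaction]):
        names = [s.name for s in species]
        if len(set(names)) != len(names):
            raise ValueError("species names must be unique")
        self.variant = variant
        self.species = list(species)
        self.reactions = list(reactions)
        self.index = {n: i for i, n in enumerate(names)}
        known = set(names)
        for r in self.reactions:
            for n, _ in r.reactants + r.products:
                if n not in known:
                    raise ValueError(f"{r.id}: unknown species {n}")
        self._build_arrays()

    # -- structural helpers -------------------------------------------------
    def _build_arrays(self):
        ns, nr = len(self.species), len(self.reactions)
        S = np.zeros((ns, nr))
        idxA = np.full(nr, -1, dtype=np.int64)
        idxB = np.full(nr, -1, dtype=np.int64)
        for j, r in enumerate(self.reactions):
            slots = []
            for n, st in r.reactants:
                i = self.index[n]
                S[i, j] -= st
                slots.extend([i] * st)
            for n, st in r.products:
                S[self.index[n], j] += st
            if len(slots) >= 1:
                idxA[j] = slots[0]
            if len(slots) == 2:
                idxB[j] = slots[1]
        self.stoich = S
        self.reactant_idx = (idxA, idxB)

    @property
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    @property
    def rate_constant_names(self) -> list[str]:
        return [r.rate_constant_name for r in self.reactions]

    def initial_state(self) -> np.ndarray:
        return np.array([s.initial_amount for s in self.species], dtype=float)

    def reaction_ids(self) -> set[str]:
        return {r.id for r in self.reactions}

    def rate_vector(self, params: KineticParameterSet) -> np.ndarray:
        missing = [n for n in self.rate_constant_names if n not in params]
        if missing:
            raise KeyError(f"missing rate constants: {sorted(set(missing))}")
        return np.array([params[n] for n in self.rate_constant_names])

    def with_initial(self, overrides: dict) -> "ReactionNetwork":
        """Copy of the network with some initial amounts replaced."""
        sp = []
        for s in self.species:
            if s.name in overrides:
                sp.append(
                    Species(s.name, float(overrides[s.name]), s.modifications, s.compartment)
                )
            else:
                sp.append(s)
        return ReactionNetwork(self.variant, sp, self.reactions)

    def without_reactions(self, ids) -> "ReactionNetwork":
        ids = set(ids)
        return ReactionNetwork(
            self.variant, self.species, [r for r in self.reactions if r.id not in ids]
        )

    def moiety_members(self, protein: str) -> dict:
        """Species containing the protein moiety -> copies per complex."""
        table = _MOIETY.get(protein, {})
        return {n: w for n, w in table.items() if n in self.index}


# ---------------------------------------------------------------------------
# Species catalog (full models). Initial amounts live in parameters.py and
# are injected by build_network; zero here.
# ---------------------------------------------------------------------------

_PHOS = frozenset({"phosphorylated"})
_CLEAVED = frozenset({"cleaved"})

_FULL_SPECIES = [
    # (name, modifications)
    ("TNF", frozenset()),
    ("TNFR1", frozenset()),
    ("TNFR1a", frozenset()),          # TNF:TNFR1 ligated receptor
    ("TRADD", frozenset()),
    ("RIP1", frozenset()),
    ("C1_TRADD", frozenset()),        # TNFR1a:TRADD (complex I, TRADD arm)
    ("C1_RIP1", frozenset()),         # TNFR1a:RIP1 (complex I, RIP1 arm)
    ("TRADDa", frozenset()),          # released, death-signaling TRADD
    ("RIP1a", frozenset()),           # released, death-signaling RIP1
    ("TaR", frozenset()),             # TRADDa:RIP1 mutual complex (sequestration)
    ("FADD", frozenset()),
    ("ProC8", frozenset()),
    ("RIP3", frozenset()),
    ("Nec", frozenset()),             # RIP1a:RIP3 necrosome seed (high affinity)
    ("NecR", frozenset()),            # Nec + bulk RIP1 protomer (low affinity)
    ("NecRF", frozenset()),           # NecR:FADD scaffold
    ("C2", frozenset()),              # NecRF:ProC8 -- necrosome-resident pro-C8
    ("pRIP3", _PHOS),
    ("Ppm1b", frozenset()),
    ("pRIP3_Ppm1b", _PHOS),
    ("MLKL", frozenset()),
    ("pMLKL", _PHOS),
    ("C8a", frozenset()),             # active caspase-8 (cleaves RIP1/RIP3)
    ("C8aT", frozenset()),            # TRADD-route active caspase-8 (Model 4)
    ("RIP1c", _CLEAVED),              # cleaved RIP1 (inactive sink)
    ("RIP3c", _CLEAVED),              # cleaved RIP3 (inactive sink)
]

#: protein moiety -> {species: copies of the protein it contains}
_MOIETY = {
    "RIP1": {"RIP1": 1, "RIP1a": 1, "C1_RIP1": 1, "Nec": 1, "NecR": 2,
             "NecRF": 2, "C2": 2, "TaR": 1, "TFR": 1, "RIP1c": 1},
    "RIP3": {"RIP3": 1, "pRIP3": 1, "Nec": 1, "NecR": 1, "NecRF": 1, "C2": 1,
             "pRIP3_Ppm1b": 1, "RIP3c": 1},
    "FADD": {"FADD": 1, "NecRF": 1, "C2": 1, "TRADD_FADD": 1, "T2": 1,
             "TFR": 1},
    "TRADD": {"TRADD": 1, "TRADDa": 1, "C1_TRADD": 1, "TaR": 1,
              "TRADD_FADD": 1, "T2": 1, "TFR": 1},
    "MLKL": {"MLKL": 1, "pMLKL": 1},
    "Ppm1b": {"Ppm1b": 1, "pRIP3_Ppm1b": 1},
}

_TRADD_ROUTE_SPECIES = [
    ("TRADD_FADD", frozenset()),      # TRADDa:FADD scaffold
    ("T2", frozenset()),              # TRADDa:FADD:ProC8
    ("TFR", frozenset()),             # TRADD_FADD:RIP1 competition complex
]


def _rxn(rid, kind, reactants, products, k):
    return Reaction(rid, kind, tuple(reactants), tuple(products), k)


# ---------------------------------------------------------------------------
# Reaction catalog.  Group "black" is shared by all variants, "blue" is the
# RIP1-dependent caspase-8 route (Mechanism 2), "orange" the TRADD-dependent
# route (Mechanism 1); V45/V46 are the Model-4 non-cleaving TRADD route.
# ---------------------------------------------------------------------------

_BLACK = [
    _rxn("V1", "binding", [("TNF", 1), ("TNFR1", 1)], [("TNFR1a", 1)], "k_tnf_on"),
    _rxn("V2", "unbinding", [("TNFR1a", 1)], [("TNF", 1), ("TNFR1", 1)], "k_tnf_off"),
    _rxn("V3", "binding", [("TNFR1a", 1), ("TRADD", 1)], [("C1_TRADD", 1)], "k_tradd_on"),
    _rxn("V4", "unbinding", [("C1_TRADD", 1)], [("TNFR1a", 1), ("TRADD", 1)], "k_tradd_off"),
    _rxn("V5", "binding", [("TNFR1a", 1), ("RIP1", 1)], [("C1_RIP1", 1)], "k_rip1_on"),
    _rxn("V6", "unbinding", [("C1_RIP1", 1)], [("TNFR1a", 1), ("RIP1", 1)], "k_rip1_off"),
    _rxn("V7", "translocation", [("C1_TRADD", 1)], [("TNFR1a", 1), ("TRADDa", 1)], "k_tradd_rel"),
    _rxn("V8", "translocation", [("C1_RIP1", 1)], [("TNFR1a", 1), ("RIP1a", 1)], "k_rip1_rel"),
    _rxn("V9", "binding", [("TRADDa", 1), ("RIP1", 1)], [("TaR", 1)], "k_seq_on"),
    # disassembly deactivates the TRADD arm: sequestration is a true sink
    _rxn("V10", "unbinding", [("TaR", 1)], [("TRADD", 1), ("RIP1", 1)], "k_seq_off"),
    _rxn("V11", "degradation", [("TRADDa", 1)], [("TRADD", 1)], "k_tradda_deact"),
    _rxn("V12", "degradation", [("RIP1a", 1)], [("RIP1", 1)], "k_rip1a_deact"),
    _rxn("V15", "binding", [("RIP1a", 1), ("RIP3", 1)], [("Nec", 1)], "k_nec_on"),
    # seed disassembly deactivates its RIP1 (kinase turn-off on release), so
    # the standing seed pool tracks the receptor activation flux
    _rxn("V16", "unbinding", [("Nec", 1)], [("RIP1", 1), ("RIP3", 1)], "k_nec_off"),
    _rxn("V17", "phosphorylation", [("Nec", 1), ("RIP3", 1)], [("Nec", 1), ("pRIP3", 1)], "k_seed"),
    _rxn("V18", "phosphorylation", [("pRIP3", 1), ("RIP3", 1)], [("pRIP3", 2)], "k_amp"),
    _rxn("V19", "binding", [("pRIP3", 1), ("Ppm1b", 1)], [("pRIP3_Ppm1b", 1)], "k_ppm_on"),
    _rxn("V20", "unbinding", [("pRIP3_Ppm1b", 1)], [("pRIP3", 1), ("Ppm1b", 1)], "k_ppm_off"),
    _rxn("V21", "dephosphorylation", [("pRIP3_Ppm1b", 1)], [("RIP3", 1), ("Ppm1b", 1)], "k_deph"),
    _rxn("V22", "phosphorylation", [("pRIP3", 1), ("MLKL", 1)], [("pRIP3", 1), ("pMLKL", 1)], "k_mlkl_p"),
    _rxn("V23", "dephosphorylation", [("pMLKL", 1)], [("MLKL", 1)], "k_mlkl_dp"),
    _rxn("V24", "cleavage", [("C8a", 1), ("RIP1a", 1)], [("C8a", 1), ("RIP1c", 1)], "k_cl_rip1"),
    _rxn("V25", "cleavage", [("C8a", 1), ("pRIP3", 1)], [("C8a", 1), ("RIP3c", 1)], "k_cl_prip3"),
    _rxn("V26", "degradation", [("pRIP3", 1), ("C8a", 1)], [("pRIP3", 1)], "k_c8a_supp"),
    _rxn("V27", "degradation", [("C8a", 1)], [], "k_c8a_deg"),
    _rxn("V28", "synthesis", [], [("RIP1", 1)], "k_syn_rip1"),
    _rxn("V29", "degradation", [("RIP1", 1)], [], "k_deg_rip1"),
    _rxn("V30", "synthesis", [], [("ProC8", 1)], "k_syn_proc8"),
    _rxn("V31", "degradation", [("ProC8", 1)], [], "k_deg_proc8"),
]

_BLUE = [
    # bulk-RIP1 protomers extend the necrosome seed and scaffold FADD/pro-C8;
    # this arm is stoichiometric in free RIP1, hence linear in expression level
    _rxn("V32", "binding", [("Nec", 1), ("RIP1", 1)], [("NecR", 1)], "k_necr_on"),
    _rxn("V33", "unbinding", [("NecR", 1)], [("Nec", 1), ("RIP1", 1)], "k_necr_off"),
    _rxn("V34", "binding", [("NecR", 1), ("FADD", 1)], [("NecRF", 1)], "k_nf_on"),
    _rxn("V35", "unbinding", [("NecRF", 1)], [("NecR", 1), ("FADD", 1)], "k_nf_off"),
    _rxn("V36", "binding", [("NecRF", 1), ("ProC8", 1)], [("C2", 1)], "k_c8_on"),
    _rxn("V37", "unbinding", [("C2", 1)], [("NecRF", 1), ("ProC8", 1)], "k_c8_off"),
    _rxn("V38", "cleavage", [("C2", 1), ("pRIP3", 1)], [("C2", 1), ("RIP3c", 1)], "k_cl_prip3_c2"),
    _rxn("V39", "cleavage", [("C2", 1)], [("C8a", 1), ("NecRF", 1)], "k_c8_act_rip1"),
]

_ORANGE = [
    # bulk RIP1 competes at the TRADD:FADD scaffold (death-domain competition)
    _rxn("V13", "binding", [("TRADD_FADD", 1), ("RIP1", 1)], [("TFR", 1)], "k_tfr_on"),
    _rxn("V14", "unbinding", [("TFR", 1)], [("TRADD", 1), ("FADD", 1), ("RIP1", 1)], "k_tfr_off"),
    _rxn("V40", "binding", [("TRADDa", 1), ("FADD", 1)], [("TRADD_FADD", 1)], "k_tf_on"),
    _rxn("V41", "unbinding", [("TRADD_FADD", 1)], [("TRADDa", 1), ("FADD", 1)], "k_tf_off"),
    _rxn("V42", "binding", [("TRADD_FADD", 1), ("ProC8", 1)], [("T2", 1)], "k_t2_on"),
    _rxn("V43", "unbinding", [("T2", 1)], [("TRADD_FADD", 1), ("ProC8", 1)], "k_t2_off"),
    # activation requires two scaffold-bound zymogens (dimerization)
    _rxn("V44", "cleavage", [("T2", 2)], [("C8a", 2), ("TRADD_FADD", 2)], "k_c8_act_tradd"),
]

_MODEL4_EXTRA = [
    # TRADD-activated caspase-8 that neither cleaves RIP1/RIP3 nor is
    # suppressed by RIP3
    _rxn("V45", "cleavage", [("T2", 2)], [("C8aT", 2), ("TRADD_FADD", 2)], "k_c8t_act"),
    _rxn("V46", "degradation", [("C8aT", 1)], [], "k_c8t_deg"),
]

_CATALOG = {r.id: r for r in _BLACK + _BLUE + _ORANGE + _MODEL4_EXTRA}

#: reactions in which caspase-8 acts catalytically (blocked by zVAD)
CASPASE_CATALYTIC = ("V24", "V25", "V38", "V39", "V44", "V45")

#: the pro-C8 <-> RIP3 inter-inhibition reaction set (caspase-8 cleaving
#: phospho-RIP3 and phospho-RIP3 suppressing active caspase-8)
C8_RIP3_INTERINHIBITION = ("V25", "V26", "V38")

_IDS = {
    "Model1": [r.id for r in _BLACK + _ORANGE],
    "Model2": [r.id for r in _BLACK + _BLUE],
    "Model3": [r.id for r in _BLACK + _BLUE + _ORANGE],
    # Model 4 = Model 2 + TRADD scaffold chain + non-cleaving activation
    "Model4": [r.id for r in _BLACK + _BLUE] + ["V40", "V41", "V42", "V43", "V45", "V46"],
}
_IDS["Model2_noC8RIP3inhibition"] = [
    i for i in _IDS["Model2"] if i not in set(C8_RIP3_INTERINHIBITION)
]

FULL_VARIANTS = tuple(_IDS)
SMODEL_VARIANTS = ("SModel1", "SModel2", "SModel3")
VARIANTS = FULL_VARIANTS + SMODEL_VARIANTS


def _needs_tradd_route(ids):
    tr = {"V40", "V41", "V42", "V43", "V44", "V45", "V46"}
    return bool(tr & set(ids))


def build_network(variant: str, initial_amounts: dict | None = None) -> ReactionNetwork:
    """Construct a model variant as an explicit species/reaction system.

    ``initial_amounts`` overrides the default initial copy numbers
    (defaults come from :mod:`ripnet.parameters`).
    """
    if variant in SMODEL_VARIANTS:
        from . import smodels

        return smodels.build_smodel(variant)
    if variant not in _IDS:
        raise ValueError(
            f"unknown model variant {variant!r}; expected one of {sorted(VARIANTS)}"
        )
    from . import parameters

    ids = _IDS[variant]
    sp_catalog = list(_FULL_SPECIES)
    if _needs_tradd_route(ids):
        sp_catalog += _TRADD_ROUTE_SPECIES
    amounts = dict(parameters.default_initial_amounts(variant))
    if initial_amounts:
        amounts.update(initial_amounts)
    species = [Species(n, amounts.get(n, 0.0), mods) for n, mods in sp_catalog]
    used = set()
    for i in ids:
        for n, _ in _CATALOG[i].reactants + _CATALOG[i].products:
            used.add(n)
    species = [s for s in species if s.name in used]
    return ReactionNetwork(variant, species, [_CATALOG[i] for i in ids])


def apply_perturbation(
    network: ReactionNetwork,
    perturbation: PerturbationSpec,
    params: KineticParameterSet,
) -> tuple[ReactionNetwork, KineticParameterSet]:
    """Realize a KO/KD/zVAD/dose scenario; inputs are left unmodified.

    Expression scaling multiplies the protein's initial amount and, where a
    synthesis reaction for it exists, its synthesis rate.  ``zVAD`` zeroes
    caspase-8 catalytic rate constants (numerically: a negligible floor,
    since rate constants are strictly positive) without touching binding.
    """
    net = network
    p = params.copy()
    overrides = {}
    syn_rate_for = {"RIP1": "k_syn_rip1", "ProC8": "k_syn_proc8"}
    for prot, scale in perturbation.expression_scale.items():
        if prot not in net.index:
            raise ValueError(f"unknown protein {prot!r} in expression_scale")
        if scale < 0:
            raise ValueError("expression scale must be >= 0")
        base = next(s.initial_amount for s in net.species if s.name == prot)
        overrides[prot] = base * scale
        kname = syn_rate_for.get(prot)
        if kname and kname in p:
            p[kname] = max(p[kname] * scale, _K_FLOOR)
    if overrides:
        net = net.with_initial(overrides)
    for block in perturbation.catalytic_block:
        if block != "zVAD":
            raise ValueError(f"unknown catalytic block {block!r}")
        for rid in CASPASE_CATALYTIC:
            for r in net.reactions:
                if r.id == rid:
                    p[r.rate_constant_name] = _K_FLOOR
    if perturbation.tnf_dose is not None:
        if "TNF" in net.index:
            net = net.with_initial({"TNF": perturbation.tnf_dose})
    return net, p


#: numerical stand-in for a zeroed rate constant (strict positivity invariant)
_K_FLOOR = 1e-30


# ---------------------------------------------------------------------------
# Serialization (structured-text round trip)
# ---------------------------------------------------------------------------

def network_to_yaml(network: ReactionNetwork, params: KineticParameterSet | None = None) -> str:
    doc = {
        "variant": network.variant,
        "species": [
            {"name": s.name, "initial_mpc": float(s.initial_amount),
             "modifications": sorted(s.modifications)}
            for s in network.species
        ],
        "reactions": [
            {"id": r.id, "kind": r.kind,
             "reactants": [[n, st] for n, st in r.reactants],
             "products": [[n, st] for n, st in r.products],
             "rate_constant": r.rate_constant_name}
            for r in network.reactions
        ],
    }
    if params is not None:
        doc["parameters"] = {k: float(v) for k, v in params.items()}
    return yaml.safe_dump(doc, sort_keys=False)


def network_from_yaml(text: str):
    doc = yaml.safe_load(text)
    species = [
        Species(d["name"], d["initial_mpc"], frozenset(d.get("modifications", [])))
        for d in doc["species"]
    ]
    reactions = [
        Reaction(
            d["id"], d["kind"],
            tuple((n, s) for n, s in d["reactants"]),
            tuple((n, s) for n, s in d["products"]),
            d["rate_constant"],
        )
        for d in doc["reactions"]
    ]
    net = ReactionNetwork(doc["variant"], species, reactions)
    params = KineticParameterSet(doc["parameters"]) if "parameters" in doc else None
    return net, params
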