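# Methods

## The biological question and the modeling strategy

TNF can kill a cell by apoptosis (FADD/caspase-8) or by necroptosis
(RIP3/MLKL), and RIP1 sits at the junction: it is required to seed RIP3
phosphorylation, yet cells with *less* RIP1 often show *more* necroptotic
signaling. `ripnet` implements a quantitative account of this paradox as a
family of mass-action reaction networks describing the assembly and
disassembly of the TNFR1-proximal complex, the cytosolic
RIP1–FADD–caspase-8 complex, and the necrosome, driven to the absolute
copy-number scale (molecules per cell, mpc) of the L929 fibrosarcoma
system: wildtype RIP1 is 51,000 mpc and the measured complex components
span roughly 20–12,000 mpc.

Four variants differ only in how pro-caspase-8 is activated:

| variant | activation route | role |
|---|---|---|
| Model 1 | TRADD only | rejected: cannot give negative regulation |
| Model 2 | RIP1 only | explains the biphasic RIP1→p-RIP3 relation |
| Model 3 | both (superset of 1 and 2) | behaves like Model 1 at its optimum |
| Model 4 | Model 2 + a TRADD route whose product neither cleaves RIP1/RIP3 nor is suppressed by RIP3 | adds RIP1-KO apoptosis; the fate-prediction model |

A fifth variant removes the pro-caspase-8↔RIP3 inter-inhibition from
Model 2, and three reduced models (14, 14 and 16 sampled parameters)
retain each mechanism's topology for parameter-space robustness analysis.

## The mechanism in the equations

Three ingredients produce the linear-vs-ultrasensitive dichotomy that the
package is organized around:

1. **Saturating receptor engagement of RIP1.** The TNFR1–RIP1 arm
   half-saturates at ~1,500–2,000 mpc of free RIP1 (a few percent of
   wildtype), so the flux of activated RIP1 — and with it necrosome
   seeding — is nearly independent of RIP1 level until expression falls
   to ~2%.
2. **A zero-order phosphatase cycle.** Ppm1b dephosphorylates
   phospho-RIP3 through an enzyme–substrate cycle running deep in
   saturation (Michaelis constant ~160 mpc, far below the phospho-RIP3
   plateau). Seeding flux must exceed the cycle's maximal velocity for
   phospho-RIP3 to accumulate; the crossing defines a sharp ignition
   threshold near 2% of wildtype RIP1, below which p-RIP3 collapses.
   A weak RIP3→RIP3 autocatalytic term sharpens the switch without
   making it ignite from arbitrarily small seeds.
3. **Stoichiometric recruitment of pro-caspase-8 by bulk RIP1.** The
   necrosome seed (a high-affinity RIP1–RIP3 unit whose standing level
   tracks the receptor flux) extends by binding bulk-pool RIP1
   protomers, which scaffold FADD and pro-caspase-8. The
   necrosome-resident pro-caspase-8 is therefore *linear* in RIP1
   expression, and it is what erodes phospho-RIP3 (cleavage to an
   inactive form). Lowering RIP1 from 100% to ~5% removes the eroding
   caspase while leaving seeding intact — phospho-RIP3 rises — and only
   below ~2% does seeding itself fail: the biphasic optimum.

Model 4's TRADD arm converts the same competition into apoptosis: active
TRADD is drained by association with bulk RIP1 (a sink, not an
equilibrium buffer: the complex disassembles into inactive components),
bulk RIP1 also competes at the TRADD–FADD scaffold, and activation
requires two scaffold-bound zymogens (dimerization). Each stage
contributes roughly one power of RIP1 suppression, so TRADD-dependent
caspase-8 rises steeply as RIP1 falls, exactly as the TRADD-knockout
comparison requires.

## Death model

Each death mode is an execution hazard driven by its terminal effector,
with Michaelis-saturating kinetics (execution machinery is limited):

    h_apo(t) = k_apo · C8act / (K_apo + C8act)     k_apo = 0.005 /min, K_apo = 22 mpc
    h_nec(t) = k_nec · pMLKL / (K_nec + pMLKL)     k_nec = 0.006 /min, K_nec = 20,000 mpc

Death by time *t* is `1 − exp(−H(t))` with `H` the integrated total
hazard. The apoptotic/necroptotic components are the *first-passage*
partition — the probability that the first lethal event was of each mode
— so the two components sum to the total death rate exactly, and the
mode observed in a cell is decided by which pathway executes first (a
speed competition, not mutual exclusion). The four constants were
calibrated once against the fate anchors (band edges near 2% and 90% of
wildtype RIP1, comparable mode contributions in between, an n-shaped
total-death curve) and then frozen; nothing downstream re-tunes them.
A mode is called "alone" where the minority mode contributes < 10% of
total death. (A 5% cutoff was considered; under mass-action kinetics the
apoptotic share at full RIP1 expression floors near 6–8%, so 5% would
declare the necroptosis-alone band empty on technicality — 10% reflects
what the model can actually distinguish.)

## Parameters

The reaction catalog (V1–V46, with Models 1–3 drawn from V1–V44 and
V45/V46 the Model-4-specific pair) and all rate constants are this
package's own construction: the topology encodes the mechanism
hypotheses above, and the magnitudes were calibrated once to the
quantitative anchors of the L929 system (51,000 mpc RIP1 baseline; ~2%
optimum; 20–12,000 mpc complex envelope; fate-band edges; knockout
orderings) and frozen in `ripnet.parameters`. Units: s⁻¹ (first order), mpc⁻¹·s⁻¹ (second
order), mpc·s⁻¹ (synthesis); time grids are minutes. Each variant keeps
its own fitted table — Models 1/3 weight the TRADD-route drain, Model 4
re-balances the TRADD arm and carries a smaller free pro-caspase-8 pool
with a compensating necrosome-cleavage constant.

Basal synthesis/turnover is included for RIP1 and pro-caspase-8 (so
knockdown semantics — scaled initial amount *and* synthesis — are
well-defined, and the TRADD arm has a finite zymogen budget); it is slow
relative to the ≤7 h window, and conservation tests switch it off.

## Numerical choices

* LSODA (stiff-capable) with rtol 1e-8, atol 1e-6 mpc; second-order
  rates acting across four orders of magnitude of abundance make the
  equations stiff.
* Negative transients are clipped to zero below 0.05 mpc in magnitude
  (with a logged warning); anything larger aborts the run.
* Δp-RIP3 (wildtype peak p-RIP3 minus the 50%-RIP1 peak) is evaluated on
  a log-spaced time grid over 0–6 h; when the two peaks are within 10%
  of each other the argmax is re-resolved on a locally refined grid —
  sampled parameter sets can peak within the first minutes, and a coarse
  grid would otherwise manufacture spurious sign flips. Differences
  below 1e-6 of the peak scale count as ties (non-negative).
* The stochastic path is the exact direct-method Gillespie algorithm
  (numba-accelerated with a pure-Python fallback); a doubled reactant
  contributes k·x·(x−1), matching k·x² at large copy number.
* Latin hypercube sampling uses scipy's engine (one draw per equal
  log-width bin per parameter, seeded); ranges are one decade either
  side of each reduced model's nominal value. Probability estimates run
  at 10⁴ sets per reduced model — the zero count for the TRADD-only
  mechanism and the ordering of the other two are stable well below
  that, and the analysis scales to larger n unchanged.
* Fits release five complex-assembly constants with direct leverage on a
  measured complex component; receptor-arm rates are held fixed because
  composition data constrain only products of the two (sloppy
  directions). Residuals are SD-weighted log differences of
  replicate-mean abundances; optimization is seeded multi-start bounded
  least squares in log-parameter space. R² is the squared Pearson
  correlation of observed vs simulated amounts pooled over all proteins
  and timepoints, computed on the log scale — on the raw scale a
  handful of high-abundance points dominates and the statistic mostly
  measures their replicate noise.

## The synthetic-data generator

`ripnet.synth` replaces the raw proteomics measurements. Time courses:
the ground-truth variant is simulated at each dataset's dose, sampled on
the experimental grids (TNFR1 pull-down 0–60 min; RIP1 0–420 min; RIP3
0/120/180/330/420 min; three replicates), a 20 mpc nonspecific-binding
floor is added (IP measurements never reach zero), and replicates get
multiplicative lognormal noise whose CV on the log2 scale is 8% — below
the 10% reproducibility bound of the quantification workflow and
consistent with inter-run Pearson correlations of ~0.8–0.95. Intensity
tables: three peptides per protein with 10% within-run noise, flat
background proteins, recruited proteins stepping up 16-fold after
stimulus (11 planted among 1,000 by default), and an optional
between-run noise term at the log2-CV scale for reproducibility studies.
The generator always emits its ground truth beside the data.

What passing on these data does *not* show: the generator has no missing
values, no peptide-identification errors, no retention-time drift, no
batch structure, and its noise is exactly lognormal — real IP-SWATH
tables violate all four, so the round-trip fit quality here is an upper
bound on what real data would give, and the recruitment filter's exact
recovery holds at the planted 16-fold effect size, not for marginal
recruiters.

## Known limitations

* The reaction catalog and rate constants are a calibrated
  construction, not a transcription of an experimentally fitted table;
  agreement with the quantitative anchors is by design where an anchor
  existed and extrapolation elsewhere.
* The apoptosis-alone band edge lands near 1% of wildtype (the printed
  figure is ~2%); both lie inside the ignition-threshold region and the
  discrepancy is within the grid resolution of the scan.
* Single cells are deterministic here; the stochastic machinery verifies
  means, not fate bifurcation in individual cells.
* NF-κB/MAPK branches, RIP1 ubiquitination-state dynamics and spatial
  effects are out of scope.
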