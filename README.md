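# ripnet

Quantitative modeling of TNF-induced cell-death signaling: how the
expression level of RIP1 decides whether a cell dies by apoptosis, by
necroptosis, or survives.

TNF ligation assembles a chain of complexes — the receptor-proximal
complex (TNFR1·TRADD / TNFR1·RIP1), the cytosolic
RIP1–FADD–pro-caspase-8 complex, and the necrosome, in which RIP3 is
phosphorylated and in turn phosphorylates MLKL to execute necroptosis,
while caspase-8 restrains the process by cleaving RIP1 and RIP3.
`ripnet` implements this system as explicit mass-action reaction
networks in absolute copy-number units (molecules per cell, mpc;
wildtype RIP1 = 51,000 mpc), in four mechanistic variants that differ in
how pro-caspase-8 is activated (through TRADD, through RIP1, through
both, or through RIP1 plus a TRADD route whose product does not cleave
RIP1/RIP3). On top of the simulators it provides:

* **robustness analysis** — Latin-hypercube sampling of reduced models
  (14/14/16 parameters) scored by Δp-RIP3, the difference in peak
  phospho-RIP3 between wildtype and 50%-RIP1 cells; Δp-RIP3 < 0 means
  RIP1 *suppresses* necroptotic signaling,
* **fitting** — seeded multi-start least squares of complex-composition
  time courses in log space, scored by pooled R²,
* **fate analysis** — RIP1-level scans, a saturating-hazard death model
  with a first-passage apoptosis/necroptosis partition, and the
  two-dimensional death-rate phase diagram,
* **quantification math** — the TOP3 protein-amount estimate, spike-in
  calibration to mpc, the strict differential-recruitment filter
  (|log2 FC| > 2 and −log10 P > 2) and reproducibility statistics,
* **synthetic data** — generators for abundance time courses and
  peptide intensity tables with known ground truth, so the entire
  pipeline runs without any download.

See `docs/methods.md` for the model, its assumptions and the
calibration; the mechanism in one sentence: *pro-caspase-8 joins the
necrosome stoichiometrically with bulk RIP1 (linear in expression),
while RIP3 phosphorylation needs only a receptor-saturating trace of
RIP1 and a seeding flux above a zero-order phosphatase threshold
(ultrasensitive near ~2% of wildtype) — so lowering RIP1 first removes
the caspase brake and only below ~2% the spark.*

## Worked example

```python
import numpy as np
from ripnet import (build_network, default_parameters, simulate_ode,
                    apply_perturbation, PerturbationSpec, readout)

net = build_network("Model2")                      # RIP1-route variant
params = default_parameters("Model2")
t = np.linspace(0, 420, 141)                       # minutes

for scale in (1.0, 0.5, 0.02, 0.005):
    pert = PerturbationSpec(expression_scale={"RIP1": scale})
    n2, p2 = apply_perturbation(net, pert, params)
    peak = readout(simulate_ode(n2, p2, t), "p-RIP3", "peak")
    print(f"RIP1 at {100 * scale:5.1f}%: peak p-RIP3 = {peak:7.0f} mpc")
```

prints

```
RIP1 at 100.0%: peak p-RIP3 =   22602 mpc
RIP1 at  50.0%: peak p-RIP3 =   23219 mpc
RIP1 at   2.0%: peak p-RIP3 =   26523 mpc
RIP1 at   0.5%: peak p-RIP3 =    2485 mpc
```

— the biphasic signature: halving RIP1 *raises* phospho-RIP3 (the
linear caspase-8 brake weakens), the maximum sits near 2% of wildtype,
and below it RIP3 phosphorylation collapses (no more seeding).

The numbered drivers under `analysis/` run the full analysis end to end
(`01` synthetic data → `02` recruitment statistics → `03` fits →
`04` robustness sampling → `05` RIP1 scans → `06` phase diagram),
each printing what it found and writing tables under `results/`. For
example `python analysis/06_phase_diagram.py` reports

```
apoptosis-alone band: RIP1 < 0.008 of wildtype
necroptosis-alone band: RIP1 > 0.853
mixed band mean apoptotic share: 0.50
death at 4 h: endpoints 0.65/0.53, interior max 0.88 (n-shaped: True)
death at 6 h: endpoints 0.79/0.60, interior max 0.96 (n-shaped: True)
```

i.e. pure apoptosis below ~1% of wildtype RIP1, pure necroptosis above
~85%, an even split in between, and a death-rate curve that is low at
both RIP1 extremes and maximal at intermediate expression.

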