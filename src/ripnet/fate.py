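"""Cell-fate predictions: RIP1-level scans, death rates and phase diagrams.

Death model
-----------
Each death mode is an execution hazard driven by its terminal effector:
active caspase-8 (apoptosis) and phospho-MLKL (necroptosis).  Execution
machinery saturates, so hazards are Michaelis-shaped in the effector:

    h_apo(t) = k_apo * C8act(t) / (K_apo + C8act(t))
    h_nec(t) = k_nec * pMLKL(t) / (K_nec + pMLKL(t))

The death rate by time t is 1 - exp(-H(t)) with H the integrated total
hazard, and the apoptotic/necroptotic components are the first-passage
split: the fraction of cells whose first lethal event was of each mode
(the two pathways race within one cell; whichever executes first sets
the observed death type).  The components sum to the total death rate
exactly.  The four constants were calibrated once against the fate anchors
(mixed-death band edges near 2% and 90% of wildtype RIP1, comparable
mode contributions in between) and frozen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .network import (
    ReactionNetwork,
    KineticParameterSet,
    PerturbationSpec,
    apply_perturbation,
    build_network,
)
from .parameters import default_parameters
from .simulate import Trajectory, simulate_ode, readout

__all__ = [
    "DeathModel",
    "DEFAULT_DEATH_MODEL",
    "ScanResult",
    "PhaseDiagram",
    "rip1_scan",
    "linearity_and_threshold",
    "death_rate",
    "scenario_compare",
    "phase_diagram",
]


@dataclass(frozen=True)
class DeathModel:
    """Saturating execution hazards (rates per minute, half-points in mpc)."""

    k_apo: float = 5.0e-3
    K_apo: float = 22.0
    k_nec: float = 6.0e-3
    K_nec: float = 20_000.0

    def hazards(self, traj: Trajectory):
        c8 = traj.readout_series("active-C8")
        ml = traj.readout_series("p-MLKL")
        h_apo = self.k_apo * c8 / (self.K_apo + c8)
        h_nec = self.k_nec * ml / (self.K_nec + ml)
        return h_apo, h_nec


DEFAULT_DEATH_MODEL = DeathModel()

#: a mode is "alone" where the minority mode contributes < 10% of death
ALONE_CUTOFF = 0.10


def death_rate(traj: Trajectory, t_hours: float, model: DeathModel = DEFAULT_DEATH_MODEL):
    """Death rate at ``t_hours`` with its apoptotic/necroptotic components.

    Returns ``(total, apoptotic, necroptotic)``; the components sum to the
    total (first-passage partition of the competing hazards).
    """
    t_min = float(t_hours) * 60.0
    if t_min > traj.times[-1] + 1e-9 or t_min < traj.times[0]:
        raise ValueError(f"t = {t_hours} h outside the simulated window")
    h_apo, h_nec = DeathModel.hazards(model, traj)
    H = cumulative_trapezoid(h_apo + h_nec, traj.times, initial=0.0)
    surv = np.exp(-H)
    m = traj.times <= t_min + 1e-9
    apo = float(np.trapezoid((h_apo * surv)[m], traj.times[m]))
    nec = float(np.trapezoid((h_nec * surv)[m], traj.times[m]))
    return apo + nec, apo, nec


@dataclass
class ScanResult:
    """Readouts along a RIP1 expression-fraction grid."""

    variant: str
    grid: np.ndarray                      # RIP1 fractions, increasing
    times_h: tuple                        # evaluation times (hours)
    peak_p_rip3: np.ndarray
    p_rip3_at: dict                       # hour -> array over grid
    proc8_necrosome: np.ndarray           # peak pro-C8 in the necrosome
    active_c8: np.ndarray                 # peak active caspase-8
    death: dict                           # hour -> array of total death rate
    argmax_fraction: float = field(init=False)

    def __post_init__(self):
        self.argmax_fraction = float(self.grid[int(np.argmax(self.peak_p_rip3))])


def rip1_scan(
    variant: str,
    params: KineticParameterSet | None = None,
    grid=None,
    times_h=(2.0, 4.0, 6.0),
    t_end_h: float = 7.0,
    death_model: DeathModel = DEFAULT_DEATH_MODEL,
) -> ScanResult:
    """Simulate a series of RIP1 expression levels and collect fate readouts."""
    if grid is None:
        grid = np.concatenate([[0.0], np.geomspace(1e-3, 1.0, 50)])
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0) or grid.min() < 0 or grid.max() > 1.2:
        raise ValueError("grid must be strictly increasing within [0, 1.2]")
    if params is None:
        params = default_parameters(variant)
    base = build_network(variant)
    t = np.linspace(0.0, t_end_h * 60.0, int(t_end_h * 30) + 1)
    pk, c2, c8 = [], [], []
    p_at = {h: [] for h in times_h}
    death = {h: [] for h in times_h}
    for r in grid:
        net, p = apply_perturbation(base, PerturbationSpec(expression_scale={"RIP1": r}), params)
        traj = simulate_ode(net, p, t)
        pk.append(readout(traj, "p-RIP3", "peak"))
        # the TRADD-only mechanism has no necrosome-resident pro-C8 species
        try:
            c2.append(readout(traj, "proC8-necrosome", "peak"))
        except KeyError:
            c2.append(np.nan)
        c8.append(readout(traj, "active-C8", "peak"))
        for h in times_h:
            p_at[h].append(readout(traj, "p-RIP3", h * 60.0))
            death[h].append(death_rate(traj, h, death_model)[0])
    return ScanResult(
        variant, grid, tuple(times_h), np.array(pk),
        {h: np.array(v) for h, v in p_at.items()},
        np.array(c2), np.array(c8),
        {h: np.array(v) for h, v in death.items()},
    )


def linearity_and_threshold(scan: ScanResult) -> dict:
    """Linearity of pro-C8 recruitment and the p-RIP3 ultrasensitive threshold.

    * ``linearity_r2`` -- coefficient of determination of a least-squares
      line through (RIP1 fraction, peak pro-C8 in necrosome).
    * ``threshold_fraction`` -- RIP1 fraction at which peak p-RIP3 first
      falls to 50% of its plateau (the mean over the top decade of the
      grid is the plateau), scanning downward; None if never crossed.
    """
    if len(scan.grid) < 4:
        raise ValueError("need at least 4 grid points")
    x, y = scan.grid, scan.proc8_necrosome
    if np.isnan(y).all():
        raise ValueError(f"no necrosome pro-C8 readout for {scan.variant}")
    coef = np.polyfit(x, y, 1)
    resid = y - np.polyval(coef, x)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    top = scan.grid >= scan.grid.max() / 10.0
    plateau = float(scan.peak_p_rip3[top].mean())
    threshold = None
    below = scan.peak_p_rip3 < 0.5 * plateau
    if below.any():
        idx = np.nonzero(~below)[0]
        if len(idx) and idx[0] > 0:
            threshold = float(scan.grid[idx[0] - 1])
        elif len(idx) == 0:
            threshold = float(scan.grid[-1])
        else:
            # interpolate between the last sub-threshold point and the
            # first supra-threshold point
            i = idx[0]
            threshold = float(scan.grid[max(i - 1, 0)])
    return {"linearity_r2": r2, "threshold_fraction": threshold, "plateau": plateau}


def scenario_compare(
    scenarios: dict,
    variant: str,
    params: KineticParameterSet | None = None,
    readout_name: str = "p-RIP3",
    t="peak",
    t_end_h: float = 7.0,
):
    """Readout per named scenario plus the difference to the first (baseline).

    ``scenarios`` maps label -> PerturbationSpec; returns a pandas
    DataFrame indexed by label with ``value`` and ``delta_vs_baseline``.
    """
    import pandas as pd

    if params is None:
        params = default_parameters(variant)
    base = build_network(variant)
    t_grid = np.linspace(0.0, t_end_h * 60.0, int(t_end_h * 30) + 1)
    values = {}
    for label, spec in scenarios.items():
        net, p = apply_perturbation(base, spec, params)
        values[label] = readout(simulate_ode(net, p, t_grid), readout_name, t)
    labels = list(values)
    baseline = values[labels[0]]
    return pd.DataFrame(
        {
            "value": [values[l] for l in labels],
            "delta_vs_baseline": [values[l] - baseline for l in labels],
        },
        index=pd.Index(labels, name="scenario"),
    )


@dataclass
class PhaseDiagram:
    """Death rate and mode partition over RIP1 fraction x time."""

    rip1_grid: np.ndarray
    times_h: np.ndarray
    death: np.ndarray                 # len(grid) x len(times)
    apoptosis_fraction: np.ndarray    # share of death that is apoptotic
    necroptosis_fraction: np.ndarray
    apoptosis_alone_upper: float | None
    necroptosis_alone_lower: float | None
    mid_band_apoptosis_share: float


def phase_diagram(
    variant: str = "Model4",
    params: KineticParameterSet | None = None,
    rip1_grid=None,
    times_h=None,
    death_model: DeathModel = DEFAULT_DEATH_MODEL,
    partition_at_h: float = 6.0,
) -> PhaseDiagram:
    """Two-dimensional death-rate surface with apoptosis/necroptosis bands.

    Band edges use the minority-mode cutoff (< 10% of total death at
    ``partition_at_h``): the apoptosis-alone band is the low-RIP1 region
    where necroptosis stays a minority, the necroptosis-alone band the
    high-RIP1 region where apoptosis does.
    """
    if params is None:
        params = default_parameters(variant)
    if rip1_grid is None:
        rip1_grid = np.concatenate([[0.0], np.geomspace(2e-3, 1.0, 40)])
    rip1_grid = np.asarray(rip1_grid, dtype=float)
    if times_h is None:
        times_h = np.linspace(0.5, 7.0, 14)
    times_h = np.asarray(times_h, dtype=float)
    if len(rip1_grid) == 0 or len(times_h) == 0:
        raise ValueError("empty grids")
    base = build_network(variant)
    t = np.linspace(0.0, float(times_h.max()) * 60.0, int(times_h.max() * 30) + 1)
    death = np.zeros((len(rip1_grid), len(times_h)))
    apo_fr = np.full(len(rip1_grid), np.nan)
    nec_fr = np.full(len(rip1_grid), np.nan)
    for i, r in enumerate(rip1_grid):
        net, p = apply_perturbation(base, PerturbationSpec(expression_scale={"RIP1": r}), params)
        traj = simulate_ode(net, p, t)
        for j, h in enumerate(times_h):
            death[i, j] = death_rate(traj, h, death_model)[0]
        tot, apo, nec = death_rate(traj, partition_at_h, death_model)
        if tot > 0:
            apo_fr[i], nec_fr[i] = apo / tot, nec / tot
    apo_alone = nec_fr < ALONE_CUTOFF
    nec_alone = apo_fr < ALONE_CUTOFF
    upper = None
    if apo_alone.any():
        k = np.nonzero(apo_alone)[0]
        # contiguous low-RIP1 run
        stop = k[0]
        while stop + 1 < len(rip1_grid) and apo_alone[stop + 1]:
            stop += 1
        upper = float(rip1_grid[stop])
    lower = None
    if nec_alone.any():
        k = np.nonzero(nec_alone)[0]
        start = k[-1]
        while start - 1 >= 0 and nec_alone[start - 1]:
            start -= 1
        lower = float(rip1_grid[start])
    mixed = ~apo_alone & ~nec_alone & np.isfinite(apo_fr)
    mid_share = float(np.nanmean(apo_fr[mixed])) if mixed.any() else float("nan")
    return PhaseDiagram(
        rip1_grid, times_h, death, apo_fr, nec_fr, upper, lower, mid_share
    )
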