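"""Deterministic (ODE) and stochastic (Gillespie) simulation of networks.

The deterministic path integrates the mass-action rate equations with
LSODA (stiff-capable; rtol 1e-8, atol 1e-6 mpc).  The stochastic path is
the exact direct-method SSA; for a reaction with a doubled reactant the
propensity is k*x*(x-1), matching the deterministic k*x^2 law at large
copy number.  Time grids are in minutes; rate constants in per-second
units are converted internally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.integrate import odeint

from .network import KineticParameterSet, ReactionNetwork

__all__ = [
    "Trajectory",
    "SimulationError",
    "simulate_ode",
    "simulate_ssa",
    "readout",
    "READOUTS",
]

log = logging.getLogger(__name__)

#: transient negativity beyond this magnitude (mpc) aborts the run
NEG_TOL = 0.05

#: named readouts -> candidate species summed (those present in the variant)
READOUTS = {
    "p-RIP3": ("pRIP3", "pRIP3_Ppm1b"),
    "active-C8": ("C8a", "C8aT", "C8X"),
    "p-MLKL": ("pMLKL",),
    "proC8-necrosome": ("C2",),
    "proC8-RIP3-complex": ("C2",),
    "RIP1-RIP3-complex": ("Nec", "NecR", "NecRF", "C2"),
    "Ppm1b-RIP3-complex": ("pRIP3_Ppm1b",),
}


class SimulationError(RuntimeError):
    pass


@dataclass
class Trajectory:
    """Simulated copy-number time courses for one network + parameter set."""

    times: np.ndarray            # minutes
    amounts: np.ndarray          # species x time (mpc)
    species: list
    variant: str

    def __post_init__(self):
        self._index = {n: i for i, n in enumerate(self.species)}

    def series(self, species_name: str) -> np.ndarray:
        return self.amounts[self._index[species_name]]

    def readout_series(self, name: str) -> np.ndarray:
        if name not in READOUTS:
            raise KeyError(f"unknown readout {name!r}; known: {sorted(READOUTS)}")
        members = [m for m in READOUTS[name] if m in self._index]
        if not members:
            raise KeyError(f"readout {name!r} undefined for variant {self.variant}")
        return sum(self.series(m) for m in members)


def initial_state_with_params(network: ReactionNetwork, params) -> np.ndarray:
    """Initial state; a parameter ``<species>_0`` overrides that amount.

    Reduced models sample initial pools alongside rate constants, so the
    parameter set may carry e.g. ``RIP3_0``.
    """
    y0 = network.initial_state()
    for key, val in params.items():
        if key.endswith("_0") and key[:-2] in network.index:
            y0[network.index[key[:-2]]] = float(val)
    return y0


def _mass_action_funcs(network: ReactionNetwork, params: KineticParameterSet):
    k = network.rate_vector(params) * 60.0  # per-minute rates
    S = network.stoich
    idxA, idxB = network.reactant_idx
    mA, mB = idxA >= 0, idxB >= 0
    jA, jB = np.nonzero(mA)[0], np.nonzero(mB)[0]
    nr, ns = len(k), S.shape[0]

    def rates(x):
        xc = np.maximum(x, 0.0)
        r = k.copy()
        r[mA] *= xc[idxA[mA]]
        r[mB] *= xc[idxB[mB]]
        return r

    def rhs(x, t):
        return S @ rates(x)

    def jac(x, t):
        xc = np.maximum(x, 0.0)
        a = np.ones(nr)
        b = np.ones(nr)
        a[mA] = xc[idxA[mA]]
        b[mB] = xc[idxB[mB]]
        D = np.zeros((nr, ns))
        np.add.at(D, (jA, idxA[mA]), (k * b)[mA])
        np.add.at(D, (jB, idxB[mB]), (k * a)[mB])
        return S @ D

    return rhs, jac, rates


def simulate_ode(
    network: ReactionNetwork,
    params: KineticParameterSet,
    t_grid,
    rtol: float = 1e-8,
    atol: float = 1e-6,
    y0=None,
) -> Trajectory:
    """Integrate the mass-action ODEs on an increasing minute grid.

    The grid normally starts at 0 with the network's initial state; pass
    ``y0`` to continue a trajectory from an arbitrary start time.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or len(t) < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be increasing")
    if y0 is None:
        if t[0] != 0:
            raise ValueError("t_grid must start at 0")
        y0 = initial_state_with_params(network, params)
    rhs, jac, _ = _mass_action_funcs(network, params)
    y, info = odeint(
        rhs, y0, t, Dfun=jac, rtol=rtol, atol=atol, mxstep=20000, full_output=True
    )
    if info["message"] != "Integration successful.":
        tcu = info.get("tcur", [np.nan])
        raise SimulationError(
            f"ODE integration failed for {network.variant} near t = "
            f"{np.max(tcu):.3g} min: {info['message']}"
        )
    ymin = y.min()
    if ymin < -NEG_TOL:
        i, j = np.unravel_index(np.argmin(y), y.shape)
        raise SimulationError(
            f"species {network.species_names[j]} reached {ymin:.3g} mpc at "
            f"t = {t[i]:.3g} min (below -{NEG_TOL})"
        )
    if ymin < 0:
        log.warning(
            "clipping negative transient (min %.3g mpc) in %s", ymin, network.variant
        )
        y = np.maximum(y, 0.0)
    return Trajectory(t, y.T.copy(), network.species_names, network.variant)


def _ssa_python(x, k, S, idxA, idxB, t_rec, rec, t_end, max_events, rng_state):
    rng = np.random.default_rng(rng_state)
    dup = (idxA == idxB) & (idxA >= 0)
    n_record = len(t_rec)
    t_now, i_rec, events = 0.0, 0, 0
    while True:
        a = k.copy()
        valid = idxA >= 0
        a[valid] *= x[idxA[valid]]
        vb = (idxB >= 0) & ~dup
        a[vb] *= x[idxB[vb]]
        a[dup] *= np.maximum(x[idxA[dup]] - 1, 0)
        a0 = a.sum()
        if a0 <= 0:
            break
        t_now += rng.exponential(1.0 / a0)
        if t_now > t_end:
            break
        while i_rec < n_record and t_rec[i_rec] < t_now:
            rec[:, i_rec] = x
            i_rec += 1
        j = int(np.searchsorted(np.cumsum(a), rng.uniform(0, a0)))
        x = x + S[:, j]
        events += 1
        if events >= max_events:
            return -1
    while i_rec < n_record:
        rec[:, i_rec] = x
        i_rec += 1
    return events


def _build_ssa_kernel():
    try:
        from numba import njit
    except Exception:  # pragma: no cover - numba is an optional speedup
        return None

    @njit(cache=True)
    def kernel(x, k, S, idxA, idxB, t_rec, rec, t_end, max_events, seed):
        np.random.seed(seed)
        nr = k.shape[0]
        n_record = t_rec.shape[0]
        a = np.empty(nr)
        t_now = 0.0
        i_rec = 0
        events = 0
        while True:
            a0 = 0.0
            for j in range(nr):
                aj = k[j]
                ia, ib = idxA[j], idxB[j]
                if ia >= 0:
                    if ia == ib:
                        aj *= x[ia] * max(x[ia] - 1, 0)
                    else:
                        aj *= x[ia]
                        if ib >= 0:
                            aj *= x[ib]
                a[j] = aj
                a0 += aj
            if a0 <= 0.0:
                break
            t_now += -np.log(np.random.random()) / a0
            if t_now > t_end:
                break
            while i_rec < n_record and t_rec[i_rec] < t_now:
                for i in range(x.shape[0]):
                    rec[i, i_rec] = x[i]
                i_rec += 1
            u = np.random.random() * a0
            acc = 0.0
            j = nr - 1
            for jj in range(nr):
                acc += a[jj]
                if u <= acc:
                    j = jj
                    break
            for i in range(x.shape[0]):
                x[i] += S[i, j]
            events += 1
            if events >= max_events:
                return -1
        while i_rec < n_record:
            for i in range(x.shape[0]):
                rec[i, i_rec] = x[i]
            i_rec += 1
        return events

    return kernel


_SSA_KERNEL = _build_ssa_kernel()


def simulate_ssa(
    network: ReactionNetwork,
    params: KineticParameterSet,
    t_end: float,
    seed: int,
    n_record: int = 201,
    max_events: int = 50_000_000,
) -> Trajectory:
    """Exact stochastic sample path, recorded on a uniform minute grid."""
    y0 = initial_state_with_params(network, params)
    if not np.allclose(y0, np.round(y0)):
        raise ValueError("SSA requires integer-valued initial amounts")
    k = network.rate_vector(params) * 60.0
    S = network.stoich.astype(np.int64)
    idxA, idxB = network.reactant_idx
    t_rec = np.linspace(0.0, float(t_end), n_record)
    rec = np.zeros((len(y0), n_record))
    x = np.round(y0).astype(np.int64)
    if _SSA_KERNEL is not None:
        events = _SSA_KERNEL(
            x, k, S, idxA, idxB, t_rec, rec, float(t_end), max_events,
            int(seed) % 2**32,
        )
    else:
        events = _ssa_python(x, k, S, idxA, idxB, t_rec, rec, float(t_end), max_events, seed)
    if events < 0:
        raise SimulationError(f"SSA exceeded {max_events} events before t = {t_end} min")
    return Trajectory(t_rec, rec, network.species_names, network.variant)


def readout(traj: Trajectory, name: str, t="peak") -> float:
    """Named readout at a time point (minutes, linear interpolation) or its peak."""
    series = traj.readout_series(name)
    if isinstance(t, str):
        if t != "peak":
            raise ValueError(f"time must be a number or 'peak', got {t!r}")
        return float(series.max())
    t = float(t)
    if t < traj.times[0] or t > traj.times[-1]:
        raise ValueError(f"t = {t} min outside simulated window")
    return float(np.interp(t, traj.times, series))
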