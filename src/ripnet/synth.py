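"""Synthetic-data generation for every pipeline input.

Two generators stand in for the raw measurements:

* :func:`generate_timecourses` -- model-derived absolute-abundance time
  courses (molecules per cell) on the experimental IP sampling grids,
  with multiplicative lognormal replicate noise whose coefficient of
  variation on the log2 scale matches the reported reproducibility of
  the quantification workflow (default 8%, below the 10% bound).
* :func:`generate_ip_table` -- peptide-level intensity tables with known
  recruited/background ground truth for the differential-recruitment
  statistics.

Every generator emits its ground truth alongside the data; downstream
tests compare against the emitted record, never a re-derivation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fitting import DATASETS, AbundanceTimeCourse, simulate_observables
from .parameters import default_parameters

__all__ = ["GeneratorConfig", "generate_timecourses", "generate_ip_table"]


@dataclass
class GeneratorConfig:
    """Ground truth and noise structure for the synthetic datasets."""

    seed: int
    variant: str = "Model2"
    params: dict | None = None
    datasets: tuple = ("TNFR1", "RIP1", "RIP3")
    n_replicates: int = 3
    cv_log2: float = 0.08           # CV of log2 abundance across replicates
    background_mpc: float = 20.0    # nonspecific IP background floor
    # IP intensity-table structure
    n_background: int = 1000
    n_recruited: int = 11
    recruited_fold_change: float = 16.0
    n_peptides: int = 3
    peptide_cv: float = 0.10        # within-run peptide-level noise (linear CV)
    run_cv_log2: float = 0.0        # between-run protein-level CV of log2 abundance
    timepoints: tuple = (0, 5, 15, 30, 45, 60)

    def __post_init__(self):
        if self.cv_log2 < 0 or self.peptide_cv < 0:
            raise ValueError("noise CV must be >= 0")
        if self.n_recruited < 0 or self.n_background < 0:
            raise ValueError("protein counts must be >= 0")
        unknown = set(self.datasets) - set(DATASETS)
        if unknown:
            raise ValueError(f"unknown datasets {sorted(unknown)}")


def generate_timecourses(cfg: GeneratorConfig):
    """Simulate the ground-truth model and add replicate noise.

    Returns ``(AbundanceTimeCourse, truth)`` where ``truth`` is the
    noise-free table (dataset, protein, time_min, mpc).
    """
    rng = np.random.default_rng(cfg.seed)
    params = default_parameters(cfg.variant)
    if cfg.params:
        params = params.copy()
        params.update(cfg.params)
    truth = simulate_observables(
        cfg.variant, params, datasets=list(cfg.datasets),
        background_mpc=cfg.background_mpc,
    )
    rows = []
    for _, row in truth.iterrows():
        log2_mu = np.log2(row["mpc"])
        sd = cfg.cv_log2 * abs(log2_mu)
        for rep in range(1, cfg.n_replicates + 1):
            noisy = 2.0 ** (log2_mu + (rng.normal(0.0, sd) if sd > 0 else 0.0))
            rows.append((row["dataset"], row["protein"], row["time_min"], rep, noisy))
    data = pd.DataFrame(rows, columns=["dataset", "protein", "time_min", "replicate", "mpc"])
    return (
        AbundanceTimeCourse(data, {"variant": cfg.variant, "seed": cfg.seed,
                                   "cv_log2": cfg.cv_log2}),
        truth,
    )


def generate_ip_table(cfg: GeneratorConfig):
    """Peptide intensity table with planted recruited proteins.

    Background proteins are flat in time; recruited proteins step up by
    the configured fold change at every post-stimulus timepoint.
    Returns ``(table, labels)``: a wide intensity DataFrame indexed by
    (protein, peptide) with one column per run (``t{min}_r{rep}``), and
    a Series mapping protein -> True for planted recruited proteins.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    n_total = cfg.n_background + cfg.n_recruited
    proteins = [f"P{i:04d}" for i in range(n_total)]
    recruited = {p: i < cfg.n_recruited for i, p in enumerate(proteins)}
    base = 10.0 ** rng.uniform(3.0, 6.0, size=n_total)          # run-to-run scale
    pep_weight = rng.lognormal(0.0, 0.5, size=(n_total, cfg.n_peptides))
    cols = {}
    for t in cfg.timepoints:
        for rep in range(1, cfg.n_replicates + 1):
            vals = base * (
                cfg.recruited_fold_change
                ** (np.array([recruited[p] for p in proteins]) * (t > 0))
            )
            if cfg.run_cv_log2 > 0:
                # between-run variability at the reported log2-CV scale
                sd = cfg.run_cv_log2 * np.abs(np.log2(vals))
                vals = 2.0 ** (np.log2(vals) + rng.normal(0.0, 1.0, n_total) * sd)
            noise = rng.lognormal(0.0, cfg.peptide_cv, size=(n_total, cfg.n_peptides))
            cols[f"t{int(t)}_r{rep}"] = (vals[:, None] * pep_weight * noise).ravel()
    index = pd.MultiIndex.from_tuples(
        [(p, f"{p}_pep{j+1}") for p in proteins for j in range(cfg.n_peptides)],
        names=["protein", "peptide"],
    )
    table = pd.DataFrame(cols, index=index)
    labels = pd.Series({p: bool(v) for p, v in recruited.items()}, name="recruited")
    return table, labels
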