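"""Downstream quantification math of the IP-MS workflow.

Covers the label-free TOP3 protein-amount estimate (mean of the three
most intense peptides), calibration of relative abundances to absolute
molecules per cell via a spiked-in reference protein of known amount,
the strict double-threshold differential-recruitment filter
(|log2 fold change| > 2 and -log10 P > 2 versus the pre-stimulus
baseline), and the inter-run reproducibility statistics (pairwise
Pearson correlations and per-protein CVs of log2 abundance).

Statistical choices: the per-timepoint P-value is a two-sample Welch t
test on log2 abundances across replicates; no multiple-testing
correction is applied (the filter is deliberately the raw double
threshold).  Zero intensities are imputed with half the smallest
positive value in the table before log transformation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SpikeInReference",
    "top3_amount",
    "protein_abundance_table",
    "calibrate_mpc",
    "differential_recruitment",
    "reproducibility_stats",
    "FC_THRESHOLD_LOG2",
    "P_THRESHOLD_NEGLOG10",
]

FC_THRESHOLD_LOG2 = 2.0
P_THRESHOLD_NEGLOG10 = 2.0


@dataclass(frozen=True)
class SpikeInReference:
    """Heavy-labeled reference protein of known absolute amount."""

    protein: str
    amount: float                    # absolute spiked amount (molecules)
    intensities: dict                # run id -> measured intensity

    def __post_init__(self):
        if not self.amount > 0:
            raise ValueError("spiked amount must be > 0")


def top3_amount(peptide_intensities) -> tuple[float, bool]:
    """TOP3 estimate: mean of the three most intense peptides.

    Returns ``(amount, low_evidence)``; ``low_evidence`` flags proteins
    quantified from fewer than three peptides (or with no nonzero
    signal, in which case the amount is NaN).
    """
    x = np.asarray(list(peptide_intensities), dtype=float)
    if x.size == 0:
        raise ValueError("need at least one peptide intensity")
    if (x < 0).any():
        raise ValueError("intensities must be >= 0")
    if not (x > 0).any():
        return float("nan"), True
    top = np.sort(x)[::-1][:3]
    return float(top.mean()), len(x) < 3


def protein_abundance_table(table: pd.DataFrame) -> pd.DataFrame:
    """Per-run TOP3 abundance for every protein in a wide intensity table.

    ``table`` is indexed by (protein, peptide) with one column per run.
    """
    def _top3(col):
        return col.groupby(level="protein").apply(lambda v: top3_amount(v)[0])

    return table.apply(_top3)


def calibrate_mpc(
    abundances: pd.DataFrame,
    spike: SpikeInReference,
    cells_per_sample: float,
) -> pd.DataFrame:
    """Convert relative TOP3 abundances to molecules per cell.

    The per-run response factor is (spiked amount / spike intensity in
    that run); runs in which the spike was not measured are dropped with
    a warning.  mpc = relative * factor / cells.
    """
    import logging

    if cells_per_sample <= 0:
        raise ValueError("cells_per_sample must be > 0")
    out = {}
    for run in abundances.columns:
        spike_int = spike.intensities.get(run, 0.0)
        if not spike_int > 0:
            logging.getLogger(__name__).warning(
                "run %s excluded: spike %s not measured", run, spike.protein
            )
            continue
        out[run] = abundances[run] * (spike.amount / spike_int) / cells_per_sample
    return pd.DataFrame(out)


def _impute(df: pd.DataFrame) -> pd.DataFrame:
    positive = df.values[df.values > 0]
    if positive.size == 0:
        raise ValueError("table has no positive intensities")
    return df.where(df > 0, positive.min() / 2.0)


def _run_meta(columns):
    meta = []
    for c in columns:
        t, r = c.split("_")
        meta.append((float(t[1:]), int(r[1:])))
    return pd.DataFrame(meta, index=columns, columns=["time_min", "replicate"])


def differential_recruitment(table: pd.DataFrame, baseline_time: float = 0.0) -> pd.DataFrame:
    """Per-protein, per-timepoint differential test against the baseline.

    Expects run columns named ``t{minutes}_r{replicate}``.  Returns a
    tidy frame with log2 fold change, -log10 P (Welch t on log2
    abundance), the strict double-threshold significance flag, and the
    direction ("up" = recruited).  A protein is *recruited* if it is
    significantly up at >= 1 post-stimulus timepoint.
    """
    abund = protein_abundance_table(table)
    meta = _run_meta(abund.columns)
    if (meta.groupby("time_min").size() < 2).any():
        raise ValueError("need >= 2 replicates per timepoint")
    log2a = np.log2(_impute(abund))
    base_cols = meta.index[meta["time_min"] == baseline_time]
    if len(base_cols) == 0:
        raise ValueError(f"no baseline runs at t = {baseline_time}")
    rows = []
    for t in sorted(set(meta["time_min"]) - {baseline_time}):
        cols = meta.index[meta["time_min"] == t]
        a = log2a[cols]
        b = log2a[base_cols]
        lfc = a.mean(axis=1) - b.mean(axis=1)
        tstat = stats.ttest_ind(a, b, axis=1, equal_var=False)
        neglogp = -np.log10(np.maximum(tstat.pvalue, 1e-300))
        # strict inequalities, guarded against float noise at the boundary
        sig = (lfc.abs() > FC_THRESHOLD_LOG2 + 1e-9) & (
            neglogp > P_THRESHOLD_NEGLOG10 + 1e-9
        )
        for prot, l, p_, s in zip(a.index, lfc, neglogp, sig):
            rows.append((prot, t, float(l), float(p_), bool(s),
                         "up" if l > 0 else "down"))
    res = pd.DataFrame(
        rows, columns=["protein", "time_min", "log2_fc", "neglog10_p",
                       "significant", "direction"],
    )
    rec = (
        res[(res["significant"]) & (res["direction"] == "up")]
        .groupby("protein").size()
    )
    res["recruited"] = res["protein"].map(rec.ge(1)).astype("boolean").fillna(False).astype(bool)
    return res


def reproducibility_stats(table: pd.DataFrame) -> dict:
    """Inter-run Pearson matrix and per-protein CV of log2 abundance.

    Pearson correlations are computed on log2 TOP3 abundances between
    every pair of runs; the CV is sd/mean of log2 abundance across
    replicates of the same timepoint, reported per protein x timepoint.
    """
    abund = protein_abundance_table(table)
    if abund.shape[1] < 2:
        raise ValueError("need >= 2 runs")
    log2a = np.log2(_impute(abund))
    pearson = log2a.corr(method="pearson")
    meta = _run_meta(abund.columns)
    cv_rows = []
    for t, cols in meta.groupby("time_min").groups.items():
        sub = log2a[list(cols)]
        mean, sd = sub.mean(axis=1), sub.std(axis=1, ddof=1)
        cv = sd / mean.abs()
        for prot, v in cv.items():
            cv_rows.append((prot, float(t), float(v)))
    cv = pd.DataFrame(cv_rows, columns=["protein", "time_min", "cv_log2"])
    return {"pearson": pearson, "cv_log2": cv}
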