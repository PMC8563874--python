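"""Generate the synthetic datasets every later step consumes.

Writes, under results/data/:
  * abundance_timecourses.tsv -- molecules-per-cell time courses for the
    TNFR1/RIP1/RIP3 pull-down datasets (3 replicates, log2-CV 8% noise)
  * abundance_truth.tsv       -- the noise-free ground truth
  * ip_intensity_table.tsv    -- peptide-level IP intensities with 11
    planted recruited proteins among 1,000 background proteins
  * ip_truth_labels.tsv       -- the planted recruitment labels
"""

import argparse
import pathlib

from ripnet.synth import GeneratorConfig, generate_timecourses, generate_ip_table


def main(seed: int = 42, outdir: str = "results/data") -> None:
    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = GeneratorConfig(seed=seed)
    data, truth = generate_timecourses(cfg)
    data.to_tsv(out / "abundance_timecourses.tsv")
    truth.to_csv(out / "abundance_truth.tsv", sep="\t", index=False)
    table, labels = generate_ip_table(cfg)
    table.to_csv(out / "ip_intensity_table.tsv", sep="\t")
    labels.to_csv(out / "ip_truth_labels.tsv", sep="\t")
    lo, hi = truth["mpc"].min(), truth["mpc"].max()
    print(f"abundance table: {len(data.records)} records, truth spans "
          f"{lo:.0f}-{hi:.0f} mpc across {truth['dataset'].nunique()} datasets")
    print(f"IP table: {table.index.get_level_values('protein').nunique()} proteins, "
          f"{int(labels.sum())} planted recruited")


if __name__ == "__main__":
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--out", default="results/data")
    a = ap.parse_args()
    main(a.seed, a.out)
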