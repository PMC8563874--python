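"""TOP3 estimation, spike-in calibration and the differential filter."""

import numpy as np
import pandas as pd
import pytest

from ripnet.quant import (
    SpikeInReference,
    calibrate_mpc,
    differential_recruitment,
    protein_abundance_table,
    reproducibility_stats,
    top3_amount,
)
from ripnet.synth import GeneratorConfig, generate_ip_table


class TestTop3:
    def test_definition_and_order_invariance(self):
        assert top3_amount([10, 20, 30, 40]) == (30.0, False)
        assert top3_amount([40, 10, 30, 20]) == (30.0, False)

    def test_fewer_than_three_peptides_flagged(self):
        amount, low = top3_amount([7.0])
        assert amount == 7.0 and low is True

    def test_all_zero_flagged_missing(self):
        amount, low = top3_amount([0.0, 0.0])
        assert np.isnan(amount) and low is True

    def test_validation(self):
        with pytest.raises(ValueError):
            top3_amount([])
        with pytest.raises(ValueError):
            top3_amount([-1.0, 2.0])


def _tiny_table():
    idx = pd.MultiIndex.from_tuples(
        [("A", "A_p1"), ("A", "A_p2"), ("B", "B_p1")], names=["protein", "peptide"]
    )
    return pd.DataFrame({"t0_r1": [100.0, 200.0, 50.0], "t0_r2": [110.0, 190.0, 55.0]},
                        index=idx)


class TestCalibration:
    def test_linearity_in_input_intensity(self):
        abund = protein_abundance_table(_tiny_table())
        spike = SpikeInReference("S", 1e9, {"t0_r1": 1e5, "t0_r2": 1e5})
        mpc = calibrate_mpc(abund, spike, cells_per_sample=1e4)
        mpc2 = calibrate_mpc(2.0 * abund, spike, cells_per_sample=1e4)
        pd.testing.assert_frame_equal(mpc2, 2.0 * mpc)

    def test_spike_recovers_its_own_amount(self):
        idx = pd.MultiIndex.from_tuples([("S", "S_p1")], names=["protein", "peptide"])
        table = pd.DataFrame({"t0_r1": [5e4]}, index=idx)
        abund = protein_abundance_table(table)
        spike = SpikeInReference("S", 2e10, {"t0_r1": 5e4})
        mpc = calibrate_mpc(abund, spike, cells_per_sample=1e4)
        assert mpc.loc["S", "t0_r1"] == pytest.approx(2e10 / 1e4)

    def test_dilution_series_log_log_slope_is_one(self):
        """Four-decade dilution series calibrates with unit slope."""
        amounts = np.logspace(0, 4, 9)  # relative input spanning 4 decades
        idx = pd.MultiIndex.from_tuples(
            [(f"P{i}", f"P{i}_p1") for i in range(len(amounts))],
            names=["protein", "peptide"],
        )
        table = pd.DataFrame({"t0_r1": amounts * 3.7e3}, index=idx)
        abund = protein_abundance_table(table)
        spike = SpikeInReference("P0", 1e8, {"t0_r1": float(table.iloc[0, 0])})
        mpc = calibrate_mpc(abund, spike, cells_per_sample=1e4)
        slope = np.polyfit(np.log10(amounts), np.log10(mpc["t0_r1"].to_numpy()), 1)[0]
        assert slope == pytest.approx(1.0, abs=0.05)

    def test_zero_spike_run_excluded_with_warning(self, caplog):
        abund = protein_abundance_table(_tiny_table())
        spike = SpikeInReference("S", 1e9, {"t0_r1": 1e5})
        mpc = calibrate_mpc(abund, spike, cells_per_sample=1e4)
        assert list(mpc.columns) == ["t0_r1"]


class TestDifferentialFilter:
    def test_flat_protein_not_significant(self):
        idx = pd.MultiIndex.from_tuples([("A", "A_p1")], names=["protein", "peptide"])
        cols = {f"t{t}_r{r}": [100.0] for t in (0, 30) for r in (1, 2, 3)}
        res = differential_recruitment(pd.DataFrame(cols, index=idx))
        assert (res["log2_fc"] == 0).all()
        assert not res["significant"].any()

    def test_exact_threshold_fold_change_is_not_significant(self):
        """|log2 FC| = 2.0 exactly fails the strict inequality."""
        idx = pd.MultiIndex.from_tuples([("A", "A_p1")], names=["protein", "peptide"])
        cols = {f"t0_r{r}": [100.0] for r in (1, 2, 3)}
        cols.update({f"t30_r{r}": [400.0] for r in (1, 2, 3)})
        res = differential_recruitment(pd.DataFrame(cols, index=idx))
        assert res["log2_fc"].iloc[0] == pytest.approx(2.0, abs=1e-9)
        assert not res["significant"].any()

    def test_planted_recruited_proteins_recovered_exactly(self):
        table, labels = generate_ip_table(GeneratorConfig(seed=12))
        res = differential_recruitment(table)
        found = set(res.loc[res["recruited"], "protein"])
        planted = set(labels[labels].index)
        assert found == planted
        assert len(planted) == 11

    def test_raising_the_threshold_shrinks_the_significant_set(self):
        table, _ = generate_ip_table(GeneratorConfig(seed=12, n_background=100))
        res = differential_recruitment(table)
        loose = set(res.loc[res["significant"], "protein"])
        strict = set(
            res.loc[(res["log2_fc"].abs() > 3.0) & (res["neglog10_p"] > 2.0), "protein"]
        )
        assert strict <= loose


class TestReproducibility:
    def test_duplicated_run_has_unit_correlation(self):
        idx = pd.MultiIndex.from_tuples(
            [(f"P{i}", f"P{i}_p1") for i in range(30)], names=["protein", "peptide"]
        )
        vals = np.logspace(2, 6, 30)
        table = pd.DataFrame({"t0_r1": vals, "t0_r2": vals}, index=idx)
        st = reproducibility_stats(table)
        assert st["pearson"].loc["t0_r1", "t0_r2"] == pytest.approx(1.0)

    def test_cv_recovers_generator_setting(self):
        table, _ = generate_ip_table(
            GeneratorConfig(seed=3, run_cv_log2=0.08, n_background=300)
        )
        st = reproducibility_stats(table)
        median_cv = st["cv_log2"]["cv_log2"].median()
        assert 0.06 <= median_cv <= 0.10

    def test_pearson_in_reported_band_at_study_noise_level(self):
        table, _ = generate_ip_table(
            GeneratorConfig(seed=3, run_cv_log2=0.08, n_background=300)
        )
        pearson = reproducibility_stats(table)["pearson"].values
        off = pearson[np.triu_indices_from(pearson, 1)]
        assert 0.78 <= np.median(off) <= 0.97
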