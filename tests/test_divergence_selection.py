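"""Divergence metrics, correlation correction and the selection scan."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from regdecomp import divergence_selection as dv
from regdecomp import synthetic_data as sd
from regdecomp.counts_io import SampleSheet

from conftest import STUDY_KW


def _sheet(n_rep=3, stage="testis"):
    rows = []
    for species in ("mel", "sim"):
        for genotype in ("WT", "KO"):
            for r in range(1, n_rep + 1):
                rows.append(
                    {
                        "species": species,
                        "genotype": genotype,
                        "stage": stage,
                        "replicate": r,
                    }
                )
    idx = [
        f"{r['species']}_{r['genotype']}_{stage}_{r['replicate']}" for r in rows
    ]
    return SampleSheet(pd.DataFrame(rows, index=idx))


class TestGlobalDivergence:
    def test_identical_profiles_give_zero(self):
        sheet = _sheet(n_rep=2)
        values = pd.DataFrame(
            {s: [1.0, 2.0, 3.0, 4.0, 5.0] for s in sheet.sample_ids},
            index=[f"g{i}" for i in range(5)],
        )
        res = dv.global_divergence(values, sheet)
        assert np.allclose(res["divergence"], 0.0)
        # 2 mel x 2 sim per genotype class, two classes
        assert len(res) == 8

    def test_reversed_ranks_give_two(self):
        sheet = _sheet(n_rep=2)
        base = np.arange(1.0, 6.0)
        values = pd.DataFrame(
            {
                s: base if s.startswith("mel") else base[::-1]
                for s in sheet.sample_ids
            },
            index=[f"g{i}" for i in range(5)],
        )
        res = dv.global_divergence(values, sheet)
        assert np.allclose(res["divergence"], 2.0)

    def test_bounds_respected_on_noise(self):
        sheet = _sheet()
        rng = np.random.default_rng(0)
        values = pd.DataFrame(
            rng.lognormal(2, 1, size=(200, len(sheet.sample_ids))),
            index=[f"g{i}" for i in range(200)],
            columns=sheet.sample_ids,
        )
        res = dv.global_divergence(values, sheet)
        assert res["divergence"].between(0, 2).all()

    def test_divergence_increases_with_context_shift(self):
        meds = []
        for scale in (0.2, 1.5):
            rng = np.random.default_rng(5)
            shift = rng.normal(0, scale, 400)
            # variable baselines give the cross-species rank correlation a
            # signal for the shift to erode
            cfg = sd.SimConfig(n_genes=400, context_shift=shift, seed=19)
            exp = sd.simulate_experiment(cfg)
            res = dv.global_divergence(
                exp.counts.counts.astype(float), exp.sheet
            )
            meds.append(res["divergence"].median())
        assert meds[1] > meds[0]

    def test_too_few_genes_rejected(self):
        sheet = _sheet(n_rep=2)
        values = pd.DataFrame(
            {s: [1.0, 2.0] for s in sheet.sample_ids}, index=["g1", "g2"]
        )
        with pytest.raises(ValueError, match="4 genes"):
            dv.global_divergence(values, sheet)


class TestGeneDivergence:
    @staticmethod
    def _values(mel_wt, sim_wt, mel_ko, sim_ko):
        sheet = _sheet(n_rep=2)
        cols = {}
        for s in sheet.sample_ids:
            if s.startswith("mel_WT"):
                v = mel_wt
            elif s.startswith("sim_WT"):
                v = sim_wt
            elif s.startswith("mel_KO"):
                v = mel_ko
            else:
                v = sim_ko
            cols[s] = v
        return pd.DataFrame(cols, index=[f"g{i}" for i in range(len(mel_wt))]), sheet

    def test_identical_means_give_zero(self):
        values, sheet = self._values([10.0], [10.0], [5.0], [5.0])
        res = dv.gene_divergence(values, sheet)
        assert res["d_WT"].iloc[0] == 0.0
        assert res["d_KO"].iloc[0] == 0.0
        assert res["D"].iloc[0] == 0.0

    def test_normalized_difference_worked_example(self):
        # |d_KO| = 2, |d_WT| = 1 -> D = (2 - 1) / 1.5
        c = dv.PSEUDOCOUNT
        values, sheet = self._values(
            [2.0 * 10 + c], [10.0], [4.0 * 10 + 3 * c], [10.0]
        )
        res = dv.gene_divergence(values, sheet)
        assert res["d_WT"].iloc[0] == pytest.approx(1.0)
        assert res["d_KO"].iloc[0] == pytest.approx(2.0)
        assert res["D"].iloc[0] == pytest.approx(2 / 3)

    def test_equal_nonzero_divergences_give_zero_difference(self):
        values, sheet = self._values([40.0], [10.0], [40.0], [10.0])
        res = dv.gene_divergence(values, sheet)
        assert res["d_WT"].iloc[0] == res["d_KO"].iloc[0] != 0
        assert res["D"].iloc[0] == 0.0

    @given(
        st.lists(st.floats(0.0, 1e4), min_size=4, max_size=4),
    )
    def test_normalized_difference_bounded(self, means):
        values, sheet = self._values(*[[m] for m in means])
        res = dv.gene_divergence(values, sheet)
        assert -2.0 <= res["D"].iloc[0] <= 2.0


class TestKS:
    def test_identical_samples(self):
        x = np.linspace(-1, 1, 50)
        stat, p = dv.divergence_difference_ks(x, x)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_shifted_distributions_detected(self):
        rng = np.random.default_rng(2)
        stat, p = dv.divergence_difference_ks(
            rng.normal(0, 1, 500), rng.normal(1, 1, 500)
        )
        assert p < 1e-10
        assert 0 <= stat <= 1

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            dv.divergence_difference_ks([1.0, 2.0], [1.0, 2.0, 3.0, 4.0, 5.0])


class TestEffectCorrelations:
    def test_perfect_anticorrelation(self):
        x = np.linspace(-2, 2, 20)
        rec = pd.DataFrame(
            {"mir_effect": x, "context_effect": -x},
            index=[f"g{i}" for i in range(20)],
        )
        gdiv = pd.DataFrame(
            {"d_WT": np.linspace(0, 1, 20)}, index=rec.index
        )
        res = dv.effect_correlations(rec, gdiv)
        assert res.loc["mir_vs_context", "r"] == pytest.approx(-1.0)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(7)
        rec = pd.DataFrame(
            {
                "mir_effect": rng.normal(size=50),
                "context_effect": rng.normal(size=50),
            },
            index=[f"g{i}" for i in range(50)],
        )
        gdiv = pd.DataFrame({"d_WT": rng.normal(size=50)}, index=rec.index)
        r1 = dv.effect_correlations(rec, gdiv)
        rec2 = rec.assign(mir_effect=3.0 * rec["mir_effect"] + 1.0)
        r2 = dv.effect_correlations(rec2, gdiv)
        np.testing.assert_allclose(r1["r"], r2["r"], atol=1e-12)

    def test_zero_variance_rejected(self):
        rec = pd.DataFrame(
            {"mir_effect": [1.0, 1.0, 1.0], "context_effect": [1, 2, 3]},
            index=list("abc"),
        )
        gdiv = pd.DataFrame({"d_WT": [0.1, 0.2, 0.3]}, index=rec.index)
        with pytest.raises(ValueError, match="zero variance"):
            dv.effect_correlations(rec, gdiv)


class TestCrossReplicate:
    def test_noiseless_limit_matches_truth(self):
        rng = np.random.default_rng(3)
        n = 400
        a = rng.normal(0, 1, n)
        c = rng.normal(0, 1, n)
        arch = np.column_stack([a, np.zeros(n), c])
        cfg = sd.SimConfig(
            n_genes=n,
            n_replicates=4,
            baseline_log2_mean_range=(13.0, 13.0),
            dispersion=1e-6,
            effect_arch=arch,
            seed=29,
        )
        exp = sd.simulate_experiment(cfg)
        res = dv.cross_replicate_correlation(exp.counts, exp.sheet)
        true_r = np.corrcoef(arch[:, 1] - a, c - arch[:, 1])[0, 1]
        assert res.naive_r == pytest.approx(true_r, abs=0.02)
        assert res.corrected_r == pytest.approx(true_r, abs=0.02)

    def test_deterministic_given_inputs(self, mixed_experiment):
        r1 = dv.cross_replicate_correlation(
            mixed_experiment.counts, mixed_experiment.sheet
        )
        r2 = dv.cross_replicate_correlation(
            mixed_experiment.counts, mixed_experiment.sheet
        )
        assert r1 == r2
        assert r1.n_splits == 3  # balanced 1|2 splits of 3 replicates

    def test_requires_replacement_replicates(self, mixed_experiment):
        sheet = mixed_experiment.sheet.table
        no_repl = sheet[sheet["genotype"] != "replacement"]
        with pytest.raises(ValueError, match="replacement"):
            dv.cross_replicate_correlation(
                mixed_experiment.counts, SampleSheet(no_repl)
            )


class TestCategoryDivergenceTest:
    def test_symmetric_values_not_significant(self):
        gdiv = pd.DataFrame(
            {"d_WT": [-1.0, -0.5, 0.0, 0.5, 1.0]},
            index=[f"g{i}" for i in range(5)],
        )
        t, p = dv.category_divergence_test(gdiv, gdiv.index)
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_one_sample_t_worked_example(self):
        gdiv = pd.DataFrame(
            {"d_WT": [0.9, 1.0, 1.1]}, index=list("abc")
        )
        t, p = dv.category_divergence_test(gdiv, gdiv.index)
        assert t == pytest.approx(17.3205080757, abs=1e-6)
        assert p == pytest.approx(3.3167587224e-3, abs=1e-9)

    def test_scale_invariance_of_t(self):
        gdiv = pd.DataFrame(
            {"d_WT": [0.2, 0.5, 0.9, 1.4]}, index=list("abcd")
        )
        t1, _ = dv.category_divergence_test(gdiv, gdiv.index)
        t2, _ = dv.category_divergence_test(gdiv * 7.5, gdiv.index)
        assert t1 == pytest.approx(t2)


class TestSelectionScan:
    @staticmethod
    def _frame(values, categories):
        idx = [f"g{i}" for i in range(len(values))]
        return (
            pd.DataFrame({"d_WT": values}, index=idx),
            pd.DataFrame({"category": categories}, index=idx),
        )

    def test_extreme_outlier_in_category_iii_selected(self):
        gdiv, rec = self._frame(
            [10.0] + [0.01 * i for i in range(99)], ["III"] + ["V"] * 99
        )
        res = dv.selection_scan(gdiv, rec, dv.ScanConfig(n_boot=500, seed=1))
        assert list(res.candidates) == ["g0"]

    def test_outlier_outside_category_iii_not_selected(self):
        gdiv, rec = self._frame(
            [10.0] + [0.01 * i for i in range(99)], ["I"] + ["V"] * 99
        )
        res = dv.selection_scan(gdiv, rec, dv.ScanConfig(n_boot=500, seed=1))
        assert len(res.candidates) == 0
        assert "g0" in res.significant

    def test_candidates_subset_of_category_iii(self):
        rng = np.random.default_rng(4)
        gdiv, rec = self._frame(
            rng.normal(0, 1, 500), rng.choice(["III", "I", "V"], 500)
        )
        res = dv.selection_scan(gdiv, rec, dv.ScanConfig(n_boot=300, seed=2))
        assert set(rec.loc[res.candidates, "category"]) <= {"III"}
        empirical_q = np.quantile(gdiv["d_WT"], 0.95)
        assert (gdiv.loc[res.candidates, "d_WT"] >= empirical_q).all()

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(9)
        gdiv, rec = self._frame(rng.normal(0, 1, 300), ["III"] * 300)
        r1 = dv.selection_scan(gdiv, rec, dv.ScanConfig(n_boot=200, seed=5))
        r2 = dv.selection_scan(gdiv, rec, dv.ScanConfig(n_boot=200, seed=5))
        assert list(r1.candidates) == list(r2.candidates)
        np.testing.assert_array_equal(r1.quantiles, r2.quantiles)

    def test_small_bootstrap_warns(self):
        with pytest.warns(UserWarning, match="bootstrap"):
            dv.ScanConfig(n_boot=50)
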