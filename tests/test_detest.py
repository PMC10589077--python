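import numpy as np
import pandas as pd
import pytest

import crossplast as cp
from crossplast.containers import ValidationError
from crossplast.detest import Contrast, bh_adjust, estimate_dispersions


def _cm(counts: pd.DataFrame, conditions, blocks=None) -> cp.CountMatrix:
    meta = pd.DataFrame({"condition": conditions}, index=counts.columns)
    if blocks is not None:
        meta["block"] = blocks
    return cp.CountMatrix(counts=counts, sample_meta=meta)


class TestTmmFactors:
    def test_identical_columns_give_unit_factors(self):
        col = pd.Series(np.arange(1, 41))
        cm = _cm(pd.DataFrame({"s1": col, "s2": col, "s3": col}), ["a", "a", "b"])
        assert np.allclose(cp.tmm_factors(cm), 1.0)

    def test_pure_depth_difference_absorbed_by_library_size(self):
        col = pd.Series(np.arange(1, 41))
        cm = _cm(pd.DataFrame({"s1": col, "s2": 2 * col}), ["a", "b"])
        assert np.allclose(cp.tmm_factors(cm), 1.0)

    def test_geometric_mean_is_one(self, small_dataset):
        f = cp.tmm_factors(small_dataset.counts_a)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-12)

    def test_composition_bias_is_corrected(self):
        # sample 2 spends half its reads on one gene: its other genes look
        # spuriously down without TMM; the factor must fall below 1
        rng = np.random.default_rng(0)
        base = rng.poisson(100, size=200).astype(float) + 1
        s2 = base.copy()
        s2[0] = base.sum()  # dominant gene doubles the library
        cm = _cm(pd.DataFrame({"s1": base, "s2": s2}), ["a", "b"])
        f = cp.tmm_factors(cm)
        assert f["s2"] < f["s1"]


class TestEstimateDispersions:
    @staticmethod
    def _simulate(phi0: float, seed: int = 3) -> cp.SimDataset:
        cfg = cp.SimConfig(
            n_genes_a=2000,
            n_genes_b=100,
            frac_de_a=0.0,
            frac_de_b_per_timepoint=0.0,
            dispersion_params=(phi0, 0.0),
            frac_low_abundance=0.0,
            samples_a=[("ctl", "b1")] * 3 + [("trt", "b1")] * 3,
            seed=seed,
        )
        return cp.simulate_dataset(cfg)

    def test_poisson_data_yields_near_zero_dispersion(self):
        ds = self._simulate(phi0=0.0)
        est = estimate_dispersions(ds.counts_a, Contrast("ctl", "trt"))
        assert est.median() <= 0.05

    def test_moderate_dispersion_recovered(self):
        ds = self._simulate(phi0=0.4)
        est = estimate_dispersions(ds.counts_a, Contrast("ctl", "trt"))
        assert 0.2 <= est.median() <= 0.6

    def test_infinite_prior_collapses_to_common(self):
        ds = self._simulate(phi0=0.2)
        est = estimate_dispersions(ds.counts_a, Contrast("ctl", "trt"), prior_df=1e12)
        assert est.max() - est.min() < 1e-6


class TestFitAndTest:
    def test_flat_gene_has_no_signal(self):
        counts = pd.DataFrame(
            {f"s{i}": [50, 30] for i in range(6)}, index=["flat", "other"]
        )
        cm = _cm(counts, ["a"] * 3 + ["b"] * 3)
        nf = pd.Series(1.0, index=cm.sample_ids)
        res = cp.fit_and_test(
            cm, Contrast("a", "b"), dispersions=pd.Series(0.1, index=cm.gene_ids),
            norm_factors=nf,
        )
        assert res.loc["flat", "p_value"] >= 0.99
        assert abs(res.loc["flat", "logFC"]) < 0.05

    def test_relabeling_conditions_flips_logfc_and_keeps_p(self, small_dataset):
        cm = small_dataset.counts_a
        disp = estimate_dispersions(cm, Contrast("omnivore", "carnivore", block="block"))
        fwd = cp.fit_and_test(cm, Contrast("omnivore", "carnivore", block="block"), dispersions=disp)
        rev = cp.fit_and_test(cm, Contrast("carnivore", "omnivore", block="block"), dispersions=disp)
        t = fwd["tested"] & rev["tested"]
        # p symmetry holds for every gene; coefficient symmetry only where
        # the MLE is interior (separable all-zero-in-one-group genes have an
        # unbounded condition coefficient capped by the ridge)
        assert np.allclose(fwd.loc[t, "p_value"], rev.loc[t, "p_value"], atol=1e-6)
        interior = t & (fwd["logFC"].abs() < 15) & (rev["logFC"].abs() < 15)
        assert interior.sum() > 0.9 * t.sum()
        # tolerance reflects the IRLS stopping rule, not an algebraic identity
        assert np.allclose(fwd.loc[interior, "logFC"], -rev.loc[interior, "logFC"], atol=1e-6)

    def test_all_zero_genes_are_untested(self):
        counts = pd.DataFrame(
            {f"s{i}": [0, 30 + i] for i in range(6)}, index=["dead", "live"]
        )
        cm = _cm(counts, ["a"] * 3 + ["b"] * 3)
        res = cp.fit_and_test(
            cm, Contrast("a", "b"), dispersions=pd.Series(0.1, index=cm.gene_ids),
            norm_factors=pd.Series(1.0, index=cm.sample_ids),
        )
        assert not res.loc["dead", "tested"]
        assert np.isnan(res.loc["dead", "p_value"])
        assert res.loc["live", "tested"]

    def test_matches_independent_glm_fits(self):
        # cross-check the vectorized IRLS/LRT against statsmodels' NB GLM
        import statsmodels.api as sm

        rng = np.random.default_rng(11)
        n = 8
        X = np.column_stack([np.ones(n), np.repeat([0.0, 1.0], 4)])
        counts = pd.DataFrame(
            rng.negative_binomial(5, 0.05, size=(6, n)),
            index=[f"g{i}" for i in range(6)],
            columns=[f"s{i}" for i in range(n)],
        )
        cm = _cm(counts, ["a"] * 4 + ["b"] * 4)
        phi = pd.Series(0.2, index=cm.gene_ids)
        nf = pd.Series(1.0, index=cm.sample_ids)
        res = cp.fit_and_test(cm, Contrast("a", "b"), dispersions=phi, norm_factors=nf)
        offset = np.log(counts.sum(axis=0).to_numpy(float))
        for g in cm.gene_ids:
            y = counts.loc[g].to_numpy(float)
            fam = sm.families.NegativeBinomial(alpha=0.2)
            full = sm.GLM(y, X, family=fam, offset=offset).fit()
            red = sm.GLM(y, X[:, :1], family=fam, offset=offset).fit()
            lfc_sm = full.params[1] / np.log(2)
            assert res.loc[g, "logFC"] == pytest.approx(lfc_sm, abs=1e-4)
            from scipy import stats as sps

            p_sm = sps.chi2.sf(red.deviance - full.deviance, df=1)
            assert res.loc[g, "p_value"] == pytest.approx(p_sm, abs=1e-6)

    def test_block_effects_do_not_change_calls_when_modeled(self):
        # multiply one block by a constant: with block in the model, calls agree
        cfg = cp.SimConfig(
            n_genes_a=2000, n_genes_b=100, frac_de_a=0.1, frac_de_b_per_timepoint=0.0,
            frac_low_abundance=0.0, block_sigma=0.0, seed=21,
        )
        ds = cp.simulate_dataset(cfg)
        cm = ds.counts_a
        contrast = Contrast("omnivore", "carnivore", block="block")
        base = cp.fit_and_test(cm, contrast)
        boosted = cp.CountMatrix(
            counts=cm.counts.mul(
                np.where(cm.sample_meta["block"] == "fam2", 3, 1), axis=1
            ),
            sample_meta=cm.sample_meta,
        )
        shifted = cp.fit_and_test(boosted, contrast)
        calls_a = (base["q_value"] < 0.05) & base["tested"]
        calls_b = (shifted["q_value"] < 0.05) & shifted["tested"]
        agreement = (calls_a == calls_b).mean()
        assert agreement >= 0.99

    def test_deg_count_increases_with_effect_size(self):
        # effect sizes chosen below power saturation so the trend is visible
        counts = []
        for lfc in (0.25, 0.5, 1.0):
            cfg = cp.SimConfig(
                n_genes_a=800, n_genes_b=100, frac_de_a=0.2,
                frac_de_b_per_timepoint=0.0, logfc_range=(lfc, lfc),
                dispersion_params=(0.3, 0.0), frac_low_abundance=0.0,
                samples_a=[("ctl", "b1")] * 3 + [("trt", "b1")] * 3, seed=2,
            )
            ds = cp.simulate_dataset(cfg)
            res = cp.fit_and_test(ds.counts_a, Contrast("ctl", "trt"))
            counts.append(int(((res["q_value"] < 0.05) & res["tested"]).sum()))
        assert counts[0] <= counts[1] <= counts[2]
        assert counts[2] > counts[0]


class TestBhAdjust:
    def test_equal_ps_stay_put(self):
        assert np.allclose(bh_adjust(np.full(5, 0.3)), 0.3)

    def test_hand_worked_step_up(self):
        # min over j >= i of p_j * m / j
        q = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(q, 0.04)

    def test_single_p_unchanged(self):
        assert bh_adjust(np.array([0.42]))[0] == pytest.approx(0.42)

    def test_nan_passthrough(self):
        q = bh_adjust(np.array([0.01, np.nan, 0.5]))
        assert np.isnan(q[1])
        assert not np.isnan(q[[0, 2]]).any()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValidationError):
            bh_adjust(np.array([0.5, 1.5]))

    def test_monotone_transform_of_sorted_p(self):
        rng = np.random.default_rng(0)
        p = np.sort(rng.uniform(size=100))
        q = bh_adjust(p)
        assert (np.diff(q) >= -1e-15).all()
        assert (q >= p - 1e-15).all()


def test_contrast_requires_two_samples_per_condition(tiny_counts):
    meta = tiny_counts.sample_meta.copy()
    meta.loc[meta.index[:2], "condition"] = "trt"  # leaves one 'ctl' sample
    cm = cp.CountMatrix(counts=tiny_counts.counts, sample_meta=meta)
    with pytest.raises(ValidationError, match=">= 2 samples"):
        Contrast("ctl", "trt").resolve_samples(cm)
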