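"""GRM, PCA, REML variance components, GLS scan and marginal means."""

import numpy as np
import pandas as pd
import pytest

from admixscan import assoc, synthio
from admixscan.data import MISSING

from conftest import toy_matrix


def _pheno(inds, values, years=(2015,), blocks=None):
    rows = []
    for t_idx, year in enumerate(years):
        for i, ind in enumerate(inds):
            v = values[i] if np.ndim(values) == 1 else values[t_idx][i]
            rows.append((ind, "t", year, 1 if blocks is None else blocks[i], v))
    return pd.DataFrame(rows, columns=["individual", "trait", "year", "block", "value"])


class TestComputeGrm:
    def test_identical_individuals_off_diagonal_equals_diagonal(self):
        rng = np.random.default_rng(0)
        col = rng.integers(0, 3, size=50).astype(np.int8)
        gm = toy_matrix(np.column_stack([col, col]))
        grm = assoc.compute_grm(gm).to_numpy()
        assert grm[0, 1] == pytest.approx(grm[0, 0])

    def test_unrelated_hwe_off_diagonal_structure(self):
        f = synthio.draw_parental_frequencies(5000, 0.01, seed=1)
        gm = synthio.simulate_parental_genotypes(f, 60, seed=2)
        grm = assoc.compute_grm(gm).to_numpy()
        off = grm[np.triu_indices(60, k=1)]
        # sample centering pins the grand sum at ~0, so the off-diagonal mean
        # sits at -mean(diag)/(n-1); the diagonal is ~1 for outbred HWE data
        assert off.mean() == pytest.approx(-grm.diagonal().mean() / 59, abs=1e-3)
        assert grm.diagonal().mean() == pytest.approx(1.0, abs=0.05)
        assert np.allclose(grm, grm.T)

    def test_duplicated_individual_duplicates_row(self):
        rng = np.random.default_rng(3)
        codes = rng.integers(0, 3, size=(40, 5)).astype(np.int8)
        codes = np.column_stack([codes, codes[:, 0]])
        grm = assoc.compute_grm(toy_matrix(codes)).to_numpy()
        assert np.allclose(grm[0], grm[5])

    def test_monomorphic_only_rejected(self):
        with pytest.raises(ValueError):
            assoc.compute_grm(toy_matrix(np.full((5, 4), 2, dtype=np.int8)))


class TestGenotypePca:
    def test_diverged_populations_separate_on_pc1(self):
        cfg = synthio.SimulationConfig(n_loci=600, n_island=30, n_mainland=30,
                                       n_f1=2, fst_target=0.1, seed=4,
                                       years=(2015,), traits=("height",))
        ds = synthio.generate_dataset(cfg, annotate=False)
        pca = assoc.genotype_pca(ds.genotypes)
        pc1 = pca["scores"]["PC1"].to_numpy()
        anc = ds.genotypes.ancestry_array()
        from sklearn.metrics import silhouette_score

        mask = anc != "F1"
        assert silhouette_score(pc1[mask].reshape(-1, 1), anc[mask]) > 0.5

    def test_identical_individuals_zero_scores(self):
        col = np.array([2, 1, 0, 1, 2], dtype=np.int8)
        gm = toy_matrix(np.column_stack([col, col, col]))
        pca = assoc.genotype_pca(gm)
        assert np.allclose(pca["scores"].to_numpy(), 0.0, atol=1e-10)

    def test_deterministic_sign_convention(self):
        rng = np.random.default_rng(5)
        codes = rng.integers(0, 3, size=(100, 20)).astype(np.int8)
        a = assoc.genotype_pca(toy_matrix(codes))["scores"]
        b = assoc.genotype_pca(toy_matrix(codes))["scores"]
        pd.testing.assert_frame_equal(a, b)


class TestEstimateH2:
    def _family_dataset(self, seed, sg, se_):
        cfg = synthio.SimulationConfig(
            n_loci=1500, n_island=150, n_mainland=149, n_f1=1,
            n_families_island=13, n_families_mainland=13,
            missing_rate=0.0, seed=seed, years=(2015,), traits=("height",),
            var_components={"sigma2_g": sg, "sigma2_p": 0.0, "sigma2_b": 0.0,
                            "sigma2_y": 0.0, "sigma2_e": se_})
        return synthio.generate_dataset(cfg, annotate=False)

    def test_zero_heritability_estimated_near_zero(self):
        # single-fit sampling SD is ~0.06 under these conditions; stay within
        # ~3 SD of the true boundary value of 0
        ds = self._family_dataset(seed=6, sg=0.0, se_=1.0)
        vc = assoc.estimate_h2(ds.phenotypes, assoc.compute_grm(ds.genotypes),
                               "height", covariates=())
        assert vc.heritability() <= 0.2

    def test_noiseless_polygenic_limit(self):
        # phenotype == polygenic draw -> h2 -> 1 (per-draw REML noise in the
        # variance ratio keeps single fits below 1; the mean must be close)
        ests = []
        for sd in range(5):
            rng = np.random.default_rng(sd)
            f = synthio.draw_parental_frequencies(1000, 0.01, seed=sd + 30)
            gm = synthio.simulate_family_genotypes(f, 200, 20, seed=sd + 30)
            grm = assoc.compute_grm(gm)
            K = grm.to_numpy()
            w, U = np.linalg.eigh(K)
            g = (U * np.sqrt(np.clip(w, 0, None))) @ rng.standard_normal(200)
            ph = _pheno(gm.individuals, g)
            ests.append(assoc.estimate_h2(ph, grm, "t", covariates=()).heritability())
        assert np.mean(ests) >= 0.9
        assert min(ests) >= 0.75

    def test_fixed_covariates_absorbed(self):
        ds = self._family_dataset(seed=9, sg=0.4, se_=0.6)
        ph = ds.phenotypes.copy()
        # inject a large block effect; declaring it as covariate removes it
        ph["value"] += np.where(ph["block"] > 3, 5.0, 0.0)
        grm = assoc.compute_grm(ds.genotypes)
        vc = assoc.estimate_h2(ph, grm, "height", covariates=("block",))
        assert abs(vc.heritability() - 0.4) < 0.35


class TestFitNullCovariance:
    def _repeated_dataset(self, seed):
        vc = {"sigma2_g": 0.3, "sigma2_p": 0.2, "sigma2_b": 0.1,
              "sigma2_y": 0.1, "sigma2_e": 0.5}
        cfg = synthio.SimulationConfig(
            n_loci=400, n_island=100, n_mainland=99, n_f1=1,
            n_families_island=13, n_families_mainland=13, missing_rate=0.0,
            seed=seed, years=(2014, 2015, 2016, 2017, 2018),
            traits=("height",), var_components=vc)
        return synthio.generate_dataset(cfg, annotate=False), vc

    def test_recovers_generative_components_within_3se(self):
        ds, truth = self._repeated_dataset(seed=10)
        grm = assoc.compute_grm(ds.genotypes)
        comps, V, df = assoc.fit_null_covariance(ds.phenotypes, grm, "height")
        key = {"polygenic": "sigma2_g", "perm_env": "sigma2_p",
               "block": "sigma2_b", "year": "sigma2_y", "residual": "sigma2_e"}
        for name, tkey in key.items():
            se = comps.se[name]
            assert abs(comps.variances[name] - truth[tkey]) <= 3 * max(se, 0.05), name
        assert V.shape == (len(df), len(df))

    def test_reml_trace_monotone(self):
        ds, _ = self._repeated_dataset(seed=11)
        grm = assoc.compute_grm(ds.genotypes)
        comps, _, _ = assoc.fit_null_covariance(ds.phenotypes, grm, "height")
        assert all(b >= a - 1e-9 for a, b in zip(comps.trace, comps.trace[1:]))

    def test_single_record_identifiability_error(self):
        gm = toy_matrix(np.random.default_rng(1).integers(0, 3, (30, 10)).astype(np.int8))
        grm = assoc.compute_grm(gm)
        ph = _pheno(gm.individuals, np.arange(10.0))
        with pytest.raises(ValueError, match="identifiable"):
            assoc.fit_null_covariance(ph, grm)

    def test_zero_variance_phenotype_error(self):
        gm = toy_matrix(np.random.default_rng(2).integers(0, 3, (30, 10)).astype(np.int8))
        grm = assoc.compute_grm(gm)
        ph = _pheno(gm.individuals, np.zeros(10), years=(2015, 2016))
        with pytest.raises(ValueError, match="zero-variance"):
            assoc.fit_null_covariance(ph, grm)


class TestGwasRgls:
    def test_gls_with_identity_covariance_equals_ols(self):
        rng = np.random.default_rng(12)
        codes = rng.integers(0, 3, size=(50, 40)).astype(np.int8)
        gm = toy_matrix(codes)
        y = rng.standard_normal(40)
        ph = _pheno(gm.individuals, y)
        from admixscan._mixed import VarianceComponents

        comps = VarianceComponents(variances={"residual": 1.0}, loglik=0.0)
        df = ph.copy()
        V = np.eye(40)
        res = assoc.gwas_rgls(gm, ph, null_fits={"t": (comps, V, df)})
        # OLS oracle on one SNP
        k = 7
        x = codes[k].astype(float)
        X = np.column_stack([np.ones(40), x])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        row = res[res["locus"] == gm.locus_ids[k]].iloc[0]
        assert row["beta"] == pytest.approx(beta[1], abs=1e-10)

    def test_permuted_phenotype_destroys_signal(self):
        cfg = synthio.SimulationConfig(
            n_loci=300, n_island=60, n_mainland=59, n_f1=1,
            n_families_island=10, n_families_mainland=10, missing_rate=0.0,
            seed=13, years=(2014, 2015, 2016), traits=("height",),
            causal_snps={"height": {5: 2.0}})
        ds = synthio.generate_dataset(cfg, annotate=False)
        grm = assoc.compute_grm(ds.genotypes)
        ph = ds.phenotypes.copy()
        rng = np.random.default_rng(14)
        inds = list(pd.unique(ph["individual"]))
        mapping = dict(zip(inds, rng.permutation(inds)))
        ph["individual"] = ph["individual"].map(mapping)
        res = assoc.gwas_rgls(ds.genotypes, ph, grm=grm)
        assert res["candidate"].sum() <= 1

    def test_monomorphic_snp_skipped(self):
        rng = np.random.default_rng(15)
        codes = rng.integers(0, 3, size=(20, 30)).astype(np.int8)
        codes[0] = 2
        gm = toy_matrix(codes)
        ph = _pheno(gm.individuals, rng.standard_normal(30))
        from admixscan._mixed import VarianceComponents

        comps = VarianceComponents(variances={"residual": 1.0}, loglik=0.0)
        res = assoc.gwas_rgls(gm, ph, null_fits={"t": (comps, np.eye(30), ph)})
        assert gm.locus_ids[0] not in set(res["locus"])

    def test_relatedness_correction_controls_type_i_error(self):
        """Families + polygenic signal: GLS stays calibrated, naive OLS inflates."""
        from scipy import stats as sps

        cfg = synthio.SimulationConfig(
            n_loci=400, n_island=100, n_mainland=99, n_f1=1,
            n_families_island=8, n_families_mainland=8, missing_rate=0.0,
            seed=16, years=(2014, 2015, 2016, 2017), traits=("height",),
            var_components={"sigma2_g": 0.6, "sigma2_p": 0.1, "sigma2_b": 0.0,
                            "sigma2_y": 0.1, "sigma2_e": 0.3})
        ds = synthio.generate_dataset(cfg, annotate=False)
        grm = assoc.compute_grm(ds.genotypes)
        res = assoc.gwas_rgls(ds.genotypes, ds.phenotypes, grm=grm)
        frac_gls = (res["p"] < 0.05).mean()
        assert abs(frac_gls - 0.05) <= 0.04
        # naive OLS on individual means ignoring relatedness
        ph = ds.phenotypes.groupby("individual")["value"].mean()
        dos = ds.genotypes.dosages()
        mean = np.nanmean(dos, axis=1)
        idx = np.where(np.isnan(dos))
        dos[idx] = mean[idx[0]]
        y = ph.loc[ds.genotypes.individuals].to_numpy()
        inflated = 0
        for k in range(dos.shape[0]):
            x = dos[k]
            if x.std() == 0:
                continue
            slope, _, _, p, _ = sps.linregress(x, y)
            inflated += p < 0.05
        assert inflated / dos.shape[0] > frac_gls + 0.04


class TestGenotypeClassChisq:
    def test_paper_style_homozygote_table(self):
        codes = [[2] * 47 + [0] * 2 + [1] + [0] * 67 + [1] * 2]
        gm = toy_matrix(codes, ["island"] * 50 + ["mainland"] * 69)
        res = assoc.genotype_class_chisq(gm, gm.locus_ids[0])
        assert round(res.statistic, 1) == 104.1

    def test_equal_distribution_near_zero(self):
        codes = [[2] * 10 + [0] * 10 + [2] * 10 + [0] * 10]
        gm = toy_matrix(codes, ["island"] * 20 + ["mainland"] * 20)
        assert assoc.genotype_class_chisq(gm, gm.locus_ids[0]).statistic == 0.0

    def test_matches_shared_oracle(self):
        from admixscan.stattests import yates_chi_square

        rng = np.random.default_rng(17)
        codes = rng.choice([0, 2], size=(1, 60)).astype(np.int8)
        gm = toy_matrix(codes, ["island"] * 30 + ["mainland"] * 30)
        res = assoc.genotype_class_chisq(gm, gm.locus_ids[0])
        t = [[int((codes[0, :30] == 2).sum()), int((codes[0, :30] == 0).sum())],
             [int((codes[0, 30:] == 2).sum()), int((codes[0, 30:] == 0).sum())]]
        assert res.statistic == pytest.approx(yates_chi_square(t).statistic)


class TestEmmContrasts:
    def test_balanced_one_way_reduces_to_raw_means(self):
        rng = np.random.default_rng(18)
        inds = [f"x{i}" for i in range(30)]
        geno = pd.Series([2] * 10 + [1] * 10 + [0] * 10, index=inds)
        y = rng.standard_normal(30) + np.repeat([0.0, 1.0, 2.0], 10)
        ph = _pheno(inds, y)
        res = assoc.emm_contrasts(ph, geno, None, trait="t", random_effects=())
        emm = res["emm"].set_index("class")["emm"]
        assert emm["0/0"] == pytest.approx(y[:10].mean())
        assert emm["0/1"] == pytest.approx(y[10:20].mean())
        assert emm["1/1"] == pytest.approx(y[20:].mean())

    def test_planted_additive_effect_monotone_and_significant(self):
        rng = np.random.default_rng(19)
        detected = 0
        for rep in range(20):
            inds = [f"x{i}" for i in range(90)]
            codes = rng.integers(0, 3, size=90)
            blocks = rng.integers(1, 4, size=90)
            y = []
            for year in (2015, 2016, 2017):
                y.append(1.0 * (2 - codes) + rng.standard_normal(90) * 0.8
                         + 0.3 * blocks + 0.2 * year % 2)
            ph = _pheno(inds, y, years=(2015, 2016, 2017), blocks=blocks)
            geno = pd.Series(codes, index=inds)
            res = assoc.emm_contrasts(ph, geno, None, trait="t",
                                      random_effects=("block", "individual"))
            emm = res["emm"].set_index("class")["emm"]
            monotone = emm["0/0"] < emm["0/1"] < emm["1/1"]
            extreme = res["contrasts"].set_index(["class1", "class2"])
            sig = extreme.loc[("0/0", "1/1"), "p_adj"] < 0.05
            detected += monotone and sig
        assert detected >= 18

    def test_identical_phenotypes_share_letter(self):
        inds = [f"x{i}" for i in range(24)]
        geno = pd.Series([2] * 8 + [1] * 8 + [0] * 8, index=inds)
        rng = np.random.default_rng(20)
        y = rng.standard_normal(24)
        ph = _pheno(inds, y)
        res = assoc.emm_contrasts(ph, geno, None, trait="t", random_effects=())
        assert res["emm"]["letter"].nunique() == 1

    def test_missing_genotypes_drop_individuals(self):
        inds = [f"x{i}" for i in range(12)]
        geno = pd.Series([2] * 4 + [0] * 4 + [MISSING] * 4, index=inds)
        ph = _pheno(inds, np.arange(12.0))
        res = assoc.emm_contrasts(ph, geno, None, trait="t", random_effects=())
        assert res["emm"]["n"].sum() == 8
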