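"""Relatedness-aware genotype-phenotype analyses.

Covers the association half of the pipeline: a VanRaden-type genomic
relationship matrix (GRM), genotype PCA, GRM-based REML heritability, a
two-stage repeated-measures GWAS (null covariance fitted once, then
per-SNP generalized least squares), the homozygote genotype-frequency
chi-square, and expected-marginal-means contrasts at a focal locus.

The GWAS design follows the two-stage scheme used for repeated measures:
first a linear mixed model with no SNP effect estimates the phenotypic
covariance (polygenic effect with GRM covariance, permanent-environment,
block and year random effects, residual), then each SNP is tested by GLS
holding that covariance fixed, with Wald p-values and BH correction per
trait.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ._mixed import RandomEffect, VarianceComponents, ai_reml, assemble_covariance, spectral_reml_two
from .data import MISSING, GenotypeMatrix
from .stattests import benjamini_hochberg, yates_chi_square

__all__ = [
    "compute_grm", "genotype_pca", "estimate_h2", "fit_null_covariance",
    "gwas_rgls", "genotype_class_chisq", "emm_contrasts", "VarianceComponents",
]


# ---------------------------------------------------------------------------
# relatedness
# ---------------------------------------------------------------------------

def _imputed_dosage(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """(loci x individuals dosages with per-locus mean imputation, ref freqs)."""
    d = gm.dosages()
    mean = np.nanmean(d, axis=1)
    idx = np.where(np.isnan(d))
    d[idx] = mean[idx[0]]
    p = mean / 2.0
    return d, p


def compute_grm(gm: GenotypeMatrix, *, min_maf: float = 0.0) -> pd.DataFrame:
    """VanRaden centered cross-product GRM.

    ``G = W'W / (2 sum p_k (1 - p_k))`` with ``W`` the per-locus mean-imputed,
    frequency-centered dosage matrix. Monomorphic loci carry no information
    and are excluded from the normalizer and the cross-product.
    """
    if gm.n_individuals < 2:
        raise ValueError("need at least two individuals")
    d, p = _imputed_dosage(gm)
    poly = (p > min_maf) & (p < 1 - min_maf) & (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("no polymorphic loci; GRM undefined")
    W = d[poly] - 2 * p[poly, None]
    denom = 2.0 * float((p[poly] * (1 - p[poly])).sum())
    G = W.T @ W / denom
    return pd.DataFrame(G, index=gm.individuals, columns=gm.individuals)


def genotype_pca(gm: GenotypeMatrix, n_pcs: int = 2, *, scale: bool = True) -> dict:
    """PCA of the mean-imputed dosage matrix (individuals as observations).

    Columns (loci) are centered and, by default, scaled to unit variance;
    constant columns are dropped. PC signs are fixed by forcing the
    largest-magnitude loading of each component positive. Returns a dict with
    ``scores`` (DataFrame, individuals x PCs) and ``explained_variance_ratio``.
    """
    if gm.n_individuals < 3:
        raise ValueError("need at least three individuals for PCA")
    d, _ = _imputed_dosage(gm)
    Xm = d.T  # individuals x loci
    mu = Xm.mean(axis=0)
    sd = Xm.std(axis=0)
    keep = sd > 0
    n_dropped = int((~keep).sum())
    X = Xm[:, keep] - mu[keep]
    if scale:
        X = X / sd[keep]
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    n_pcs = min(n_pcs, S.size)
    scores = U[:, :n_pcs] * S[:n_pcs]
    for k in range(n_pcs):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            scores[:, k] *= -1
    total = float((S**2).sum())
    evr = (S[:n_pcs] ** 2 / total) if total > 0 else np.zeros(n_pcs)
    cols = [f"PC{k + 1}" for k in range(n_pcs)]
    return {
        "scores": pd.DataFrame(scores, index=gm.individuals, columns=cols),
        "explained_variance_ratio": evr,
        "n_constant_dropped": n_dropped,
    }


# ---------------------------------------------------------------------------
# variance components
# ---------------------------------------------------------------------------

def _design(records: pd.Series, levels=None) -> tuple[np.ndarray, list]:
    lv = list(levels) if levels is not None else list(pd.unique(records))
    idx = {l: i for i, l in enumerate(lv)}
    Z = np.zeros((len(records), len(lv)))
    Z[np.arange(len(records)), [idx[v] for v in records]] = 1.0
    return Z, lv


def _psd_grm(grm: pd.DataFrame, individuals: list, ridge: float = 1e-6) -> np.ndarray:
    K = grm.loc[individuals, individuals].to_numpy(dtype=float)
    w = np.linalg.eigvalsh(K)
    if w.min() < -1e-8:
        K = K + ridge * np.eye(len(individuals))
    return K


def estimate_h2(phenotypes: pd.DataFrame, grm: pd.DataFrame, trait: str | None = None,
                covariates: tuple[str, ...] = ("year", "block")) -> VarianceComponents:
    """Narrow-sense heritability by GRM-based REML.

    Fits ``y = Xb + g + e`` with ``cov(g) = s2_g K`` (K the GRM, mapped to
    records through the individual design matrix) and the named phenotype
    columns as fixed-factor covariates. ``h2 = s2_g / (s2_g + s2_e)`` is
    available via :meth:`VarianceComponents.heritability`.
    """
    df = phenotypes if trait is None else phenotypes[phenotypes["trait"] == trait]
    if df.empty:
        raise ValueError(f"no phenotype records for trait {trait!r}")
    df = df.dropna(subset=["value"]).reset_index(drop=True)
    missing = set(df["individual"]) - set(grm.index)
    if missing:
        raise ValueError(f"individuals absent from GRM: {sorted(missing)[:5]}")
    inds = list(pd.unique(df["individual"]))
    Z, _ = _design(df["individual"], inds)
    K = _psd_grm(grm, inds)
    H = Z @ K @ Z.T
    X = _fixed_design(df, covariates)
    return spectral_reml_two(df["value"].to_numpy(dtype=float), X, H)


def _fixed_design(df: pd.DataFrame, covariates: tuple[str, ...]) -> np.ndarray:
    cols = [np.ones(len(df))]
    for cov in covariates:
        levels = list(pd.unique(df[cov]))
        for lv in levels[1:]:  # treatment coding
            cols.append((df[cov] == lv).to_numpy(dtype=float))
    return np.column_stack(cols)


def fit_null_covariance(phenotypes: pd.DataFrame, grm: pd.DataFrame,
                        trait: str | None = None) -> tuple[VarianceComponents, np.ndarray, pd.DataFrame]:
    """Fit the no-SNP repeated-measures mixed model and its record covariance.

    Random effects: polygenic (GRM covariance), permanent environment
    (individual identity), block, year; plus residual. Requires repeated
    records per individual, otherwise the permanent-environment and residual
    variances are confounded. Returns ``(components, V, records)`` where
    ``V`` is the fitted covariance of the (cleaned) record vector.
    """
    df = phenotypes if trait is None else phenotypes[phenotypes["trait"] == trait]
    if df.empty:
        raise ValueError(f"no phenotype records for trait {trait!r}")
    df = df.dropna(subset=["value"]).reset_index(drop=True)
    if df["value"].var() == 0:
        raise ValueError("zero-variance phenotype")
    if df.groupby("individual").size().max() < 2:
        raise ValueError(
            "single record per individual: permanent-environment and residual "
            "variances are not separately identifiable; collapse to estimate_h2"
        )
    inds = list(pd.unique(df["individual"]))
    Z_ind, _ = _design(df["individual"], inds)
    K = _psd_grm(grm, inds)
    Z_block, _ = _design(df["block"])
    Z_year, _ = _design(df["year"])
    effects = [
        RandomEffect("polygenic", Z_ind, K),
        RandomEffect("perm_env", Z_ind),
        RandomEffect("block", Z_block),
        RandomEffect("year", Z_year),
    ]
    y = df["value"].to_numpy(dtype=float)
    X = np.ones((len(df), 1))
    comps = ai_reml(y, X, effects)
    V = assemble_covariance(effects, comps.variances, len(df))
    return comps, V, df


# ---------------------------------------------------------------------------
# per-SNP GLS scan
# ---------------------------------------------------------------------------

def gwas_rgls(gm: GenotypeMatrix, phenotypes: pd.DataFrame,
              null_fits: dict[str, tuple] | None = None,
              grm: pd.DataFrame | None = None,
              *, fdr: float = 0.1) -> pd.DataFrame:
    """Repeated-measures GWAS: per-SNP GLS under a fixed null covariance.

    ``null_fits`` maps trait -> the tuple returned by
    :func:`fit_null_covariance`; traits without an entry are fitted on the
    fly (requires ``grm``). Effects are per extra REFERENCE-allele copy.
    Missing dosages are mean-imputed per SNP; monomorphic SNPs are skipped.
    Returns one row per SNP x trait with beta, SE, Wald p and BH q per trait.
    """
    traits = list(pd.unique(phenotypes["trait"]))
    null_fits = dict(null_fits or {})
    for t in traits:
        if t not in null_fits:
            if grm is None:
                raise ValueError(f"no null fit or GRM provided for trait {t!r}")
            null_fits[t] = fit_null_covariance(phenotypes, grm, t)
    d, p = _imputed_dosage(gm)
    poly = (p > 0) & (p < 1)
    ind_index = {ind: i for i, ind in enumerate(gm.individuals)}
    out = []
    for t in traits:
        from scipy.linalg import solve_triangular

        comps, V, df = null_fits[t]
        L = np.linalg.cholesky(V)
        rec_ind = [ind_index[i] for i in df["individual"]]
        yw = solve_triangular(L, df["value"].to_numpy(dtype=float), lower=True)
        onew = solve_triangular(L, np.ones(len(df)), lower=True)
        for k in np.flatnonzero(poly):
            x = d[k, rec_ind]
            xw = solve_triangular(L, x, lower=True)
            Xw = np.column_stack([onew, xw])
            XtX = Xw.T @ Xw
            try:
                beta = np.linalg.solve(XtX, Xw.T @ yw)
                cov = np.linalg.inv(XtX)
            except np.linalg.LinAlgError:
                continue
            se = float(np.sqrt(cov[1, 1]))
            b = float(beta[1])
            z = b / se if se > 0 else 0.0
            out.append({"locus": gm.locus_ids[k], "trait": t, "beta": b,
                        "se": se, "p": 2 * stats.norm.sf(abs(z))})
    res = pd.DataFrame(out)
    if res.empty:
        raise ValueError("no polymorphic SNPs to test")
    res["q"] = np.nan
    for t in traits:
        sel = res["trait"] == t
        res.loc[sel, "q"] = benjamini_hochberg(res.loc[sel, "p"].to_numpy())
    res["candidate"] = res["q"] < fdr
    res["sign"] = np.sign(res["beta"]).astype(int)
    return res


# ---------------------------------------------------------------------------
# focal-locus follow-ups
# ---------------------------------------------------------------------------

def genotype_class_chisq(gm: GenotypeMatrix, locus: str,
                         groups: tuple[str, str] = ("island", "mainland")):
    """Yates-corrected chi-square on homozygote counts between two ancestries.

    Builds the 2x2 table rows = groups, columns = (hom-ref, hom-alt);
    heterozygotes are excluded.
    """
    li = gm.locus_ids.index(locus)
    table = []
    for g in groups:
        cols = gm.group_columns(g)
        codes = gm.genotypes[li, cols]
        table.append([int((codes == 2).sum()), int((codes == 0).sum())])
    return yates_chi_square(np.asarray(table))


def emm_contrasts(phenotypes: pd.DataFrame, locus_genotypes: pd.Series,
                  pcs: pd.DataFrame | None = None, grm: pd.DataFrame | None = None,
                  trait: str | None = None,
                  random_effects: tuple[str, ...] = ("block", "year", "individual"),
                  *, alpha: float = 0.05, adjust: str = "tukey") -> dict:
    """Expected marginal means of a trait across genotype classes at one locus.

    Fits a linear mixed model with the genotype class as a fixed factor
    (cell-means coding), optional PC1/PC2 fixed covariates (centered, so the
    reference grid sits at their means), and the named random effects; then
    reports model-adjusted class means with SEs, all pairwise contrasts with
    Tukey (or Bonferroni/none) adjustment, and significance letters at
    ``alpha``. With ``random_effects=()`` and no PCs this reduces to ordinary
    least squares, and in a balanced one-way design the adjusted means equal
    raw class means exactly.

    ``locus_genotypes`` maps individual -> genotype code; missing codes drop
    the individual. Classes are labeled by VCF-style genotype strings
    (0/0 = hom-alt ... matching alternate-allele dosage order).
    """
    df = phenotypes if trait is None else phenotypes[phenotypes["trait"] == trait]
    if df.empty:
        raise ValueError(f"no phenotype records for trait {trait!r}")
    df = df.dropna(subset=["value"]).copy()
    geno = locus_genotypes.reindex(pd.unique(df["individual"]))
    geno = geno[(geno.notna()) & (geno != MISSING)]
    df = df[df["individual"].isin(geno.index)].reset_index(drop=True)
    df["geno"] = geno.loc[df["individual"]].to_numpy()
    # label by alternate-allele count: code 2 = hom-ref = 0/0
    label_of = {2: "0/0", 1: "0/1", 0: "1/1"}
    df["class"] = [label_of[int(g)] for g in df["geno"]]
    classes = [c for c in ("0/0", "0/1", "1/1") if c in set(df["class"])]
    if len(classes) < 2:
        raise ValueError("need at least two genotype classes")
    Zc, _ = _design(df["class"], classes)
    X = [Zc]
    if pcs is not None:
        pc_vals = pcs.loc[df["individual"]].to_numpy(dtype=float)
        pc_vals = pc_vals - pc_vals.mean(axis=0)
        X.append(pc_vals)
    X = np.hstack(X)
    y = df["value"].to_numpy(dtype=float)
    effects = []
    for name in random_effects:
        if name == "individual":
            Z, _ = _design(df["individual"])
            effects.append(RandomEffect("individual", Z))
        elif name in ("block", "year"):
            Z, _ = _design(df[name])
            effects.append(RandomEffect(name, Z))
        else:
            raise ValueError(f"unknown random effect {name!r}")
    n = len(df)
    if effects:
        comps = ai_reml(y, X, effects)
        V = assemble_covariance(effects, comps.variances, n)
    else:
        # OLS with the usual unbiased residual variance
        resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        dof = n - np.linalg.matrix_rank(X)
        s2 = float(resid @ resid) / max(dof, 1)
        comps = VarianceComponents(variances={"residual": s2}, loglik=float("nan"),
                                   n_records=n)
        V = s2 * np.eye(n)
    Vinv = np.linalg.inv(V)
    XtViX_inv = np.linalg.inv(X.T @ Vinv @ X)
    beta = XtViX_inv @ (X.T @ Vinv @ y)
    k = len(classes)
    means = beta[:k]
    mean_se = np.sqrt(np.diag(XtViX_inv)[:k])
    dof = n - np.linalg.matrix_rank(X)
    rows, pair_sig = [], {}
    raw = []
    for i in range(k):
        for j in range(i + 1, k):
            cvec = np.zeros(X.shape[1])
            cvec[i], cvec[j] = 1.0, -1.0
            se = float(np.sqrt(cvec @ XtViX_inv @ cvec))
            tval = float((means[i] - means[j]) / se) if se > 0 else 0.0
            raw.append((classes[i], classes[j], means[i] - means[j], se, tval))
    for c1, c2, est, se, tval in raw:
        if adjust == "tukey":
            p = float(stats.studentized_range.sf(abs(tval) * np.sqrt(2), k, max(dof, 2)))
        elif adjust == "bonferroni":
            p = min(1.0, 2 * stats.t.sf(abs(tval), max(dof, 1)) * len(raw))
        elif adjust == "none":
            p = 2 * stats.t.sf(abs(tval), max(dof, 1))
        else:
            raise ValueError(f"unknown adjustment {adjust!r}")
        rows.append({"class1": c1, "class2": c2, "estimate": float(est),
                     "se": se, "t": tval, "p_adj": p})
        pair_sig[frozenset((c1, c2))] = p < alpha
    from .popgen import assign_significance_letters

    letters = assign_significance_letters(classes, pair_sig)
    emm = pd.DataFrame({
        "class": classes, "emm": means, "se": mean_se,
        "n": [int((df["class"] == c).sum()) for c in classes],
        "letter": [letters[c] for c in classes],
    })
    return {"emm": emm, "contrasts": pd.DataFrame(rows),
            "components": comps, "dof": int(dof)}
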