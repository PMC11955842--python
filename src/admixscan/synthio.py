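"""Synthetic ddRAD-style datasets with ground truth.

Generates data with the statistical structure the downstream analyses assume:
two weakly diverged parental populations, an F1 cohort formed by island x
mainland gamete union (optionally thinned by viability selection against
heterozygotes at designated loci), uniform technical missingness,
repeated-measures phenotypes driven by a polygenic GRM effect plus sparse
causal SNPs and block/year/permanent-environment random effects, and a
locus -> annotation-term table with planted enrichment. Every planted signal
is recorded in a ``truth`` record so tests can verify recovery.

Divergence model
----------------
Parental allele frequencies follow the Balding-Nichols model: with ancestral
frequency ``p`` and divergence parameter ``F``, each population draws its
frequency from ``Beta(p (1-F)/F, (1-p)(1-F)/F)``. Because the two-deme Nei
F_ST of such pairs concentrates around ``F / (2 - F)`` rather than ``F``, the
generator maps the requested ``fst_target`` t to ``F = 2t / (1 + t)`` so the
realized two-deme Nei F_ST matches the target.

All randomness flows from a single seed; each stage uses a child stream keyed
on (seed, stage offset) so stages are independently reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import MISSING, GenotypeMatrix, validate_annotations, validate_phenotypes
from .popgen import nei_fst_from_freqs

_STAGE = {"freqs": 1, "island": 2, "mainland": 3, "f1": 4, "missing": 5,
          "phenotypes": 6, "annotations": 7, "blocks": 8}

DEFAULT_TRAITS = ("height", "conelets", "immature_cones", "mature_cones")


@dataclass
class SimulationConfig:
    """Study-shaped generator settings.

    Defaults mirror the common-garden study design this toolkit targets:
    11,379 biallelic SNPs scored in 68 island, 75 mainland and 66 F1 trees,
    genome-wide Nei F_ST of about 0.0129 with ancestral frequencies uniform
    on (0.05, 0.95) (post-MAF-filter data are mostly polymorphic), four
    repeated-measures fitness proxies measured over eleven years in six
    blocks, and 5% uniform missingness. ``s`` is the viability cost of being
    heterozygous at a selected locus (heterozygote survives with probability
    ``1 - s``); selected loci default to diagnostic-like frequencies
    (p_island=0.9, p_mainland=0.1) so selection has something to act on.
    """

    n_loci: int = 11_379
    n_island: int = 68
    n_mainland: int = 75
    n_f1: int = 66
    n_families_island: int | None = None
    n_families_mainland: int | None = None
    fst_target: float = 0.0129
    base_freq_law: tuple = ("uniform", 0.05, 0.95)
    selected_loci: tuple[int, ...] = ()
    selected_locus_freqs: tuple[float, float] | None = (0.9, 0.1)
    s: float = 0.0
    missing_rate: float = 0.05
    causal_snps: dict = field(default_factory=dict)  # trait -> {locus_index: beta}
    var_components: dict = field(default_factory=lambda: {
        "sigma2_g": 0.3, "sigma2_p": 0.1, "sigma2_b": 0.05,
        "sigma2_y": 0.05, "sigma2_e": 0.5,
    })
    n_blocks: int = 6
    years: tuple[int, ...] = tuple(range(2008, 2019))
    traits: tuple[str, ...] = DEFAULT_TRAITS
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fst_target", "missing_rate", "s"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.fst_target >= 1:
            raise ValueError("fst_target must be < 1")
        bad = [i for i in self.selected_loci if not 0 <= i < self.n_loci]
        if bad:
            raise ValueError(f"selected loci out of range: {bad[:5]}")
        if any(v < 0 for v in self.var_components.values()):
            raise ValueError("variance components must be non-negative")


@dataclass
class SyntheticDataset:
    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame
    annotations: pd.DataFrame | None
    truth: dict


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STAGE[stage]])


# ---------------------------------------------------------------------------
# allele frequencies and genotypes
# ---------------------------------------------------------------------------

def draw_parental_frequencies(n_loci: int, fst_target: float,
                              base_freq_law: tuple = ("uniform", 0.05, 0.95),
                              seed: int = 0) -> pd.DataFrame:
    """Balding-Nichols island/mainland frequency pairs at ``n_loci`` loci.

    ``fst_target`` is the realized two-deme Nei F_ST scale (see module notes
    for the t -> F mapping). ``fst_target=0`` degenerates the Beta draw; the
    fall-back sets both populations to the ancestral frequency, with a
    warning. Ancestral frequencies of exactly 0 or 1 are absorbing.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    if not 0 <= fst_target < 1:
        raise ValueError("fst_target must lie in [0, 1)")
    rng = _stage_rng(seed, "freqs")
    law = base_freq_law[0]
    if law == "uniform":
        lo, hi = base_freq_law[1], base_freq_law[2]
        p = rng.uniform(lo, hi, size=n_loci)
    elif law == "beta":
        p = rng.beta(base_freq_law[1], base_freq_law[2], size=n_loci)
    else:
        raise ValueError(f"unknown base frequency law {law!r}")
    if fst_target == 0:
        import warnings

        warnings.warn("fst_target=0 degenerates the Balding-Nichols draw; "
                      "using identical parental frequencies")
        out = np.column_stack([p, p])
    else:
        F = 2 * fst_target / (1 + fst_target)
        a = p * (1 - F) / F
        b = (1 - p) * (1 - F) / F
        out = np.empty((n_loci, 2))
        interior = (p > 0) & (p < 1)
        for col in range(2):
            out[interior, col] = rng.beta(a[interior], b[interior])
            out[~interior, col] = p[~interior]
    locus_ids = [f"scaffold_{i}:{1000 + i}" for i in range(n_loci)]
    return pd.DataFrame({"p_island": out[:, 0], "p_mainland": out[:, 1]},
                        index=locus_ids)


def simulate_parental_genotypes(freqs: pd.DataFrame, n: int, seed: int = 0,
                                population: str = "island") -> GenotypeMatrix:
    """HWE genotypes for one parental population: Binomial(2, p) ref-allele copies."""
    if n < 1:
        raise ValueError("n must be >= 1")
    p = freqs[f"p_{population}"].to_numpy(dtype=float)
    rng = _stage_rng(seed, population)
    codes = rng.binomial(2, p[:, None], size=(p.size, n)).astype(np.int8)
    prefix = {"island": "I", "mainland": "M"}[population]
    inds = [f"{prefix}{k:03d}" for k in range(n)]
    return GenotypeMatrix(genotypes=codes, locus_ids=list(freqs.index),
                          individuals=inds,
                          ancestry={i: population for i in inds})


def simulate_family_genotypes(freqs: pd.DataFrame, n: int, n_families: int,
                              seed: int = 0, population: str = "island") -> GenotypeMatrix:
    """Half-sib family genotypes: maternal trees in HWE, open pollination.

    ``n_families`` maternal genotypes are drawn in HWE; each offspring
    receives one gamete from its (randomly assigned) mother and one pollen
    gamete drawn from the population allele frequency. Offspring of the same
    mother are half-sibs (expected GRM relationship 0.25), giving the
    relatedness contrast that common-garden progeny trials actually have.
    """
    if n < 1 or n_families < 1:
        raise ValueError("n and n_families must be >= 1")
    p = freqs[f"p_{population}"].to_numpy(dtype=float)
    L = p.size
    rng = _stage_rng(seed, population)
    mothers = rng.random((L, n_families, 2)) < p[:, None, None]
    fam = rng.integers(0, n_families, size=n)
    pick = rng.integers(0, 2, size=(L, n))
    maternal = mothers[np.arange(L)[:, None], fam[None, :], pick]
    paternal = rng.random((L, n)) < p[:, None]
    codes = maternal.astype(np.int8) + paternal.astype(np.int8)
    prefix = {"island": "I", "mainland": "M"}[population]
    inds = [f"{prefix}{k:03d}" for k in range(n)]
    return GenotypeMatrix(genotypes=codes, locus_ids=list(freqs.index),
                          individuals=inds,
                          ancestry={i: population for i in inds})


def simulate_f1_cohort(freqs: pd.DataFrame, n_f1: int,
                       selected_loci: tuple[int, ...] = (), s: float = 0.0,
                       seed: int = 0) -> GenotypeMatrix:
    """F1s from island x mainland gamete union, thinned by viability selection.

    Each individual receives one island gamete (reference allele with
    probability ``p_island``) and one mainland gamete per locus. Survival
    probability is the product over selected loci of ``1 - s`` if
    heterozygous there, else 1. Because loci assort independently and the
    viability factorizes across selected loci, the distribution of survivors
    factorizes too; survivors are drawn exactly from the per-locus
    conditional-on-survival gamete-pair law (equivalent to rejection
    sampling, without its exponentially small acceptance rate). Raises when
    the expected viability is zero at some locus (for example ``s = 1``
    where every F1 is heterozygous).
    """
    if n_f1 < 1:
        raise ValueError("n_f1 must be >= 1")
    if not 0 <= s <= 1:
        raise ValueError("s must lie in [0, 1]")
    p_i = freqs["p_island"].to_numpy(dtype=float)
    p_m = freqs["p_mainland"].to_numpy(dtype=float)
    sel = np.asarray(selected_loci, dtype=int)
    h_sel = p_i[sel] * (1 - p_m[sel]) + (1 - p_i[sel]) * p_m[sel]
    viab = 1.0 - s * h_sel
    if (viab <= 0).any():
        raise ValueError("zero expected viability at a selected locus: every "
                         "F1 is heterozygous there and s = 1")
    rng = _stage_rng(seed, "f1")
    gi = (rng.random((p_i.size, n_f1)) < p_i[:, None]).astype(np.int8)
    gmn = (rng.random((p_m.size, n_f1)) < p_m[:, None]).astype(np.int8)
    mat = gi + gmn
    if sel.size and s > 0:
        # survivor law per selected locus: gamete-pair probs reweighted by
        # viability {hom: 1, het: 1-s}, normalized by 1 - s * h
        for locus in sel:
            pi, pm = p_i[locus], p_m[locus]
            w = np.array([
                (1 - pi) * (1 - pm),          # hom-alt (code 0)
                (pi * (1 - pm) + (1 - pi) * pm) * (1 - s),  # het (code 1)
                pi * pm,                       # hom-ref (code 2)
            ])
            w /= w.sum()
            mat[locus] = rng.choice(3, size=n_f1, p=w).astype(np.int8)
    inds = [f"F{k:03d}" for k in range(n_f1)]
    return GenotypeMatrix(genotypes=mat, locus_ids=list(freqs.index),
                          individuals=inds, ancestry={i: "F1" for i in inds})


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def simulate_phenotypes(genotypes: GenotypeMatrix, config: SimulationConfig,
                        seed: int | None = None) -> tuple[pd.DataFrame, dict]:
    """Repeated-measures phenotypes from the generative mixed model.

    ``y_itr = sum_l beta_l d_il + g_i + pe_i + b_block(i) + u_year + eps`` with
    ``g ~ N(0, sigma2_g GRM)``. Returns the long-format table plus a truth
    record with the generative variance components and the implied
    ``h2 = sigma2_g / (sigma2_g + sigma2_p + sigma2_e)`` per trait. A
    configuration with all variances zero and no effects yields constant
    phenotypes, allowed but flagged in the truth record.
    """
    from .assoc import compute_grm

    seed = config.seed if seed is None else seed
    vc = config.var_components
    rng = _stage_rng(seed, "phenotypes")
    block_rng = _stage_rng(seed, "blocks")
    inds = genotypes.individuals
    n = len(inds)
    blocks = block_rng.integers(1, config.n_blocks + 1, size=n)
    dos = genotypes.dosages()
    col_mean = np.nanmean(dos, axis=1)
    ii, jj = np.where(np.isnan(dos))
    dos[ii, jj] = col_mean[ii]
    sg, sp, sb, sy, se_ = (vc["sigma2_g"], vc["sigma2_p"], vc["sigma2_b"],
                           vc["sigma2_y"], vc["sigma2_e"])
    if sg > 0:
        K = compute_grm(genotypes).to_numpy()
        w, U = np.linalg.eigh(K)
        w = np.clip(w, 0, None)
        Kroot = U * np.sqrt(w)
    rows = []
    h2 = {}
    constant = []
    for trait in config.traits:
        g = Kroot @ rng.standard_normal(n) * np.sqrt(sg) if sg > 0 else np.zeros(n)
        pe = rng.standard_normal(n) * np.sqrt(sp)
        be = rng.standard_normal(config.n_blocks) * np.sqrt(sb)
        ye = rng.standard_normal(len(config.years)) * np.sqrt(sy)
        beta = config.causal_snps.get(trait, {})
        fixed = np.zeros(n)
        for locus_idx, b in beta.items():
            fixed += b * dos[int(locus_idx)]
        for t_idx, year in enumerate(config.years):
            eps = rng.standard_normal(n) * np.sqrt(se_)
            vals = fixed + g + pe + be[blocks - 1] + ye[t_idx] + eps
            for i, ind in enumerate(inds):
                rows.append((ind, trait, year, int(blocks[i]), float(vals[i])))
        denom = sg + sp + se_
        h2[trait] = sg / denom if denom > 0 else float("nan")
        constant.append(denom + sb + sy == 0 and not beta)
    df = pd.DataFrame(rows, columns=["individual", "trait", "year", "block", "value"])
    truth = {
        "var_components": dict(vc),
        "h2": h2,
        "causal_snps": {t: {int(k): float(v) for k, v in m.items()}
                        for t, m in config.causal_snps.items()},
        "constant_phenotype": bool(all(constant)) and len(constant) > 0,
    }
    return validate_phenotypes(df), truth


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def generate_annotation_table(loci: list[str], term_universe: list[str],
                              enriched_terms: list[str], candidate_set: list[str],
                              seed: int = 0, *, baseline_rate: float = 0.08,
                              odds_ratio: float = 8.0,
                              categories: dict[str, str] | None = None) -> tuple[pd.DataFrame, dict]:
    """Plant term annotations with elevated odds on candidate loci.

    Every locus receives each term independently at ``baseline_rate``; for
    candidate loci and enriched terms the Bernoulli probability is raised so
    its odds are ``odds_ratio`` times the baseline odds (``odds_ratio=inf``
    plants the term on every candidate and nowhere else). Terms cycle through
    the PO/GO categories unless an explicit term -> category map is given.
    Returns the tidy annotation frame and the ground-truth record.
    """
    if not set(enriched_terms) <= set(term_universe):
        raise ValueError("enriched_terms must be a subset of term_universe")
    if not candidate_set:
        raise ValueError("candidate_set must be non-empty")
    rng = _stage_rng(seed, "annotations")
    cats = ("plant_ontology",) + ("biological_process", "molecular_function",
                                  "cellular_component")
    if categories is None:
        categories = {t: cats[i % len(cats)] for i, t in enumerate(term_universe)}
    cand = set(candidate_set)
    base_odds = baseline_rate / (1 - baseline_rate)
    if np.isinf(odds_ratio):
        p_enr = 1.0
    else:
        o = base_odds * odds_ratio
        p_enr = o / (1 + o)
    rows = []
    for term in term_universe:
        enr = term in set(enriched_terms)
        for locus in loci:
            if np.isinf(odds_ratio) and enr:
                hit = locus in cand
            else:
                p = p_enr if (enr and locus in cand) else baseline_rate
                hit = rng.random() < p
            if hit:
                rows.append((locus, term, categories[term]))
    df = pd.DataFrame(rows, columns=["locus", "term", "category"])
    truth = {"enriched_terms": list(enriched_terms), "odds_ratio": odds_ratio,
             "baseline_rate": baseline_rate}
    return validate_annotations(df), truth


# ---------------------------------------------------------------------------
# full dataset
# ---------------------------------------------------------------------------

def generate_dataset(config: SimulationConfig,
                     *, annotate: bool = True, n_terms: int = 40,
                     n_enriched: int = 4) -> SyntheticDataset:
    """Generate the full synthetic study: genotypes, phenotypes, annotations, truth."""
    freqs = draw_parental_frequencies(config.n_loci, config.fst_target,
                                      config.base_freq_law, config.seed)
    if config.selected_loci and config.selected_locus_freqs is not None:
        pi, pm = config.selected_locus_freqs
        sel = list(config.selected_loci)
        freqs.iloc[sel, freqs.columns.get_loc("p_island")] = pi
        freqs.iloc[sel, freqs.columns.get_loc("p_mainland")] = pm
    if config.n_families_island:
        isl = simulate_family_genotypes(freqs, config.n_island,
                                        config.n_families_island, config.seed, "island")
    else:
        isl = simulate_parental_genotypes(freqs, config.n_island, config.seed, "island")
    if config.n_families_mainland:
        mnl = simulate_family_genotypes(freqs, config.n_mainland,
                                        config.n_families_mainland, config.seed, "mainland")
    else:
        mnl = simulate_parental_genotypes(freqs, config.n_mainland, config.seed, "mainland")
    f1 = simulate_f1_cohort(freqs, config.n_f1, config.selected_loci,
                            config.s, config.seed)
    codes = np.hstack([isl.genotypes, mnl.genotypes, f1.genotypes])
    inds = isl.individuals + mnl.individuals + f1.individuals
    ancestry = {**isl.ancestry, **mnl.ancestry, **f1.ancestry}
    if config.missing_rate > 0:
        rng = _stage_rng(config.seed, "missing")
        mask = rng.random(codes.shape) < config.missing_rate
        codes = codes.copy()
        codes[mask] = MISSING
    n_loci, n_ind = codes.shape
    gm = GenotypeMatrix(
        genotypes=codes, locus_ids=list(freqs.index), individuals=inds,
        ancestry=ancestry,
        qual=np.full(n_loci, 60.0),
        gq=np.full((n_loci, n_ind), 99.0),
        dp=np.full((n_loci, n_ind), 15.0),
    )
    phenotypes, pheno_truth = simulate_phenotypes(gm, config)
    annotations, annot_truth = None, {}
    if annotate:
        universe = [f"TERM:{k:04d}" for k in range(n_terms)]
        enriched = universe[:n_enriched]
        candidates = [gm.locus_ids[i] for i in config.selected_loci] or gm.locus_ids[:10]
        annotations, annot_truth = generate_annotation_table(
            gm.locus_ids, universe, enriched, candidates, config.seed)
    truth = {
        "selected_loci": [int(i) for i in config.selected_loci],
        "selected_locus_ids": [gm.locus_ids[i] for i in config.selected_loci],
        "s": config.s,
        "fst_target": config.fst_target,
        "realized_fst": nei_fst_from_freqs(freqs["p_island"], freqs["p_mainland"]),
        **pheno_truth,
        "annotations": annot_truth,
        "seed": config.seed,
    }
    return SyntheticDataset(genotypes=gm, phenotypes=phenotypes,
                            annotations=annotations, truth=truth)


def write_dataset(dataset: SyntheticDataset, out_dir) -> dict[str, Path]:
    """Emit VCF + phenotype/ancestry/annotation TSVs + truth JSON.

    The VCF round-trips losslessly through :func:`admixscan.variant_io.read_vcf`.
    """
    from .variant_io import write_ancestry, write_vcf

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "genotypes.vcf",
        "phenotypes": out / "phenotypes.tsv",
        "ancestry": out / "ancestry.tsv",
        "truth": out / "truth.json",
    }
    write_vcf(dataset.genotypes, paths["vcf"])
    dataset.phenotypes.to_csv(paths["phenotypes"], sep="\t", index=False)
    write_ancestry(dataset.genotypes.ancestry, paths["ancestry"])
    if dataset.annotations is not None:
        paths["annotations"] = out / "annotations.tsv"
        dataset.annotations.to_csv(paths["annotations"], sep="\t", index=False)
    with open(paths["truth"], "w") as fh:
        json.dump(dataset.truth, fh, indent=2, default=float)
    return paths
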