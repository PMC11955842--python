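"""End-to-end orchestration of the admixture-scan analysis.

Stages, in order: filter -> diversity -> hetdeficit -> clines -> gwas ->
overlap (heterozygosity-deficit candidates intersected with GWAS hits) ->
follow-ups at shared loci (genotype-frequency chi-square, expected marginal
means) -> enrichment. Every stage writes plain-text TSV/JSON artifacts under
the output directory and records row counts in MANIFEST.json; identical
config + seed yields identical outputs.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc, clines, enrichment, hybrid_null, popgen, variant_io
from .data import GenotypeMatrix, validate_annotations, validate_phenotypes


@dataclass
class PipelineConfig:
    """Paths, thresholds and stage toggles for a full run."""

    vcf: str
    ancestry: str
    out_dir: str
    phenotypes: str | None = None
    annotations: str | None = None
    seed: int = 0
    B: int = 1000
    cline_B: int = 200
    fdr: float = 0.1
    background_size: int = 500
    gq_min: float = 20
    dp_min: float = 3
    qual_min: float = 20
    mac_min: int = 3
    maf_min: float = 0.01
    callrate_min: float = 0.8
    mean_dp_max: float = 23
    fis_bound: float = 0.5
    max_missing: float = 0.5
    stages: tuple[str, ...] = ("filter", "diversity", "hetdeficit", "clines",
                               "gwas", "overlap", "followup", "enrichment")

    def __post_init__(self) -> None:
        for p in (self.vcf, self.ancestry, self.phenotypes, self.annotations):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must lie in (0, 1)")
        if self.B < 1 or self.cline_B < 1:
            raise ValueError("iteration counts must be >= 1")


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured stages; returns the artifact directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {},
                      "started": time.strftime("%Y-%m-%dT%H:%M:%S")}
    stages = set(config.stages)

    gm = variant_io.read_vcf(config.vcf, config.ancestry)
    manifest["input_sites"] = gm.n_loci
    manifest["input_individuals"] = gm.n_individuals

    if "filter" in stages:
        t0 = time.time()
        gm = variant_io.mask_genotypes(gm, config.gq_min, config.dp_min)
        gm, site_report = variant_io.filter_sites(
            gm, config.qual_min, config.mac_min, config.maf_min,
            config.callrate_min, config.mean_dp_max, config.fis_bound)
        gm, ind_report = variant_io.filter_individuals(gm, config.max_missing)
        site_report.to_frame().to_csv(out / "filter_sites.tsv", sep="\t", index=False)
        with open(out / "filter_report.json", "w") as fh:
            json.dump({"sites": site_report.to_dict(),
                       "individuals": ind_report.to_dict()}, fh, indent=2)
        manifest["stages"]["filter"] = {
            "sites_out": gm.n_loci, "individuals_out": gm.n_individuals,
            "seconds": round(time.time() - t0, 2)}

    het_res = cline_res = gwas_res = None
    freqs = None

    if "diversity" in stages:
        t0 = time.time()
        stats = popgen.basic_stats(gm)
        stats.per_locus.to_csv(out / "diversity_per_locus.tsv", sep="\t")
        stats.group_means().to_csv(out / "diversity_group_means.tsv", sep="\t", index=False)
        counts, totals = {}, {}
        for g in ("island", "mainland", "F1"):
            c = popgen.count_fixed_loci(gm, g)
            counts[g] = c["fixed"]
            totals[g] = c["total"] - c["all_missing"]
        fixed_cmp = popgen.compare_fixed_counts(counts, totals, fdr=config.fdr,
                                                seed=config.seed)
        fixed_cmp["pairwise"].to_csv(out / "fixed_loci_pairwise.tsv", sep="\t", index=False)
        with open(out / "fixed_loci.json", "w") as fh:
            json.dump({"counts": counts, "totals": totals,
                       "overall_p": fixed_cmp["overall_p"]}, fh, indent=2)
        manifest["stages"]["diversity"] = {
            "fixed_counts": counts, "seconds": round(time.time() - t0, 2)}

    if "hetdeficit" in stages:
        t0 = time.time()
        freqs = hybrid_null.parental_allele_freqs(gm)
        null = hybrid_null.simulate_null_het(freqs, n_f1=len(gm.group_columns("F1")),
                                             B=config.B, seed=config.seed)
        het_res = hybrid_null.het_deficit_test(gm, null, fdr=config.fdr)
        het_res.to_csv(out / "het_deficit.tsv", sep="\t")
        manifest["stages"]["hetdeficit"] = {
            "tested": int(het_res["p"].notna().sum()),
            "candidates": int(het_res["candidate"].sum()),
            "seconds": round(time.time() - t0, 2)}

    if "clines" in stages and het_res is not None:
        t0 = time.time()
        if freqs is None:
            freqs = hybrid_null.parental_allele_freqs(gm)
        h = clines.estimate_hybrid_index(gm, freqs)
        h.to_csv(out / "hybrid_index.tsv", sep="\t")
        cand_loci = list(het_res[het_res["candidate"]].index)
        if cand_loci:
            cline_res = clines.genomic_cline_scan(gm, h, freqs, cand_loci,
                                                  B=config.cline_B, seed=config.seed,
                                                  fdr=config.fdr)
            cline_res.to_csv(out / "genomic_clines.tsv", sep="\t")
            summary = clines.corroborate(het_res, cline_res)
            with open(out / "corroboration.json", "w") as fh:
                json.dump(summary, fh, indent=2)
            manifest["stages"]["clines"] = {
                "tested": len(cline_res),
                "corroborated_percent": summary["percent_corroborated"],
                "seconds": round(time.time() - t0, 2)}
        else:
            manifest["stages"]["clines"] = {"tested": 0,
                                            "seconds": round(time.time() - t0, 2)}

    phenotypes = None
    if config.phenotypes is not None:
        phenotypes = validate_phenotypes(pd.read_csv(config.phenotypes, sep="\t"))
        keep = set(gm.individuals)
        phenotypes = phenotypes[phenotypes["individual"].isin(keep)]

    grm = None
    if "gwas" in stages and phenotypes is not None:
        t0 = time.time()
        grm = assoc.compute_grm(gm)
        grm.to_csv(out / "grm.tsv", sep="\t")
        h2_rows = []
        for trait in pd.unique(phenotypes["trait"]):
            vc = assoc.estimate_h2(phenotypes, grm, trait)
            h2_rows.append({"trait": trait, "h2": vc.heritability(),
                            **{f"sigma2_{k}": v for k, v in vc.variances.items()}})
        pd.DataFrame(h2_rows).to_csv(out / "heritability.tsv", sep="\t", index=False)
        gwas_res = assoc.gwas_rgls(gm, phenotypes, grm=grm, fdr=config.fdr)
        gwas_res.to_csv(out / "gwas.tsv", sep="\t", index=False)
        manifest["stages"]["gwas"] = {
            "tests": len(gwas_res),
            "hits": int(gwas_res["candidate"].sum()),
            "seconds": round(time.time() - t0, 2)}

    shared: list[str] = []
    if "overlap" in stages and het_res is not None and gwas_res is not None:
        het_cand = set(het_res[het_res["candidate"]].index)
        gwas_hits = set(gwas_res[gwas_res["candidate"]]["locus"])
        shared = sorted(het_cand & gwas_hits)
        with open(out / "overlap.json", "w") as fh:
            json.dump({"het_candidates": len(het_cand), "gwas_hits": len(gwas_hits),
                       "shared_loci": shared}, fh, indent=2)
        manifest["stages"]["overlap"] = {"shared": len(shared)}

    if "followup" in stages and shared and phenotypes is not None:
        t0 = time.time()
        pcs = assoc.genotype_pca(gm)["scores"]
        follow = {}
        for locus in shared:
            chis = assoc.genotype_class_chisq(gm, locus)
            li = gm.locus_ids.index(locus)
            geno = pd.Series(gm.genotypes[li], index=gm.individuals)
            emm_by_trait = {}
            for trait in pd.unique(phenotypes["trait"]):
                res = assoc.emm_contrasts(phenotypes, geno, pcs, trait=trait)
                emm_by_trait[trait] = {
                    "emm": res["emm"].to_dict(orient="records"),
                    "contrasts": res["contrasts"].to_dict(orient="records")}
            follow[locus] = {"chisq": chis.statistic, "chisq_p": chis.p,
                             "emm": emm_by_trait}
        with open(out / "shared_locus_followup.json", "w") as fh:
            json.dump(follow, fh, indent=2)
        manifest["stages"]["followup"] = {"loci": len(shared),
                                          "seconds": round(time.time() - t0, 2)}

    if "enrichment" in stages and config.annotations is not None and het_res is not None:
        t0 = time.time()
        ann = validate_annotations(pd.read_csv(config.annotations, sep="\t"))
        cand_loci = set(het_res[het_res["candidate"]].index)
        if cand_loci:
            bg_loci = enrichment.sample_background(
                gm.locus_ids, min(config.background_size, gm.n_loci - len(cand_loci)),
                seed=config.seed, exclude=cand_loci)
            cand_map = ann[ann["locus"].isin(cand_loci)]
            back_map = ann[ann["locus"].isin(set(bg_loci))]
            if not cand_map.empty and not back_map.empty:
                enr = enrichment.enrichment_scan(cand_map, back_map, fdr=config.fdr)
                enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
                manifest["stages"]["enrichment"] = {
                    "terms": len(enr), "flagged": int(enr["flag"].sum()),
                    "seconds": round(time.time() - t0, 2)}

    with open(out / "MANIFEST.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out
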