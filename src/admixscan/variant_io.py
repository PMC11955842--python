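"""VCF ingestion and the post-calling filter cascade.

Reads a multi-sample VCF (via cyvcf2) into a :class:`~admixscan.data.GenotypeMatrix`
with GT/GQ/DP layers and site QUAL, then applies the standard ddRAD-style
quality cascade:

1. genotype masking: GQ < 20 or DP < 3 -> missing;
2. site filters, in order: non-biallelic/indel, QUAL <= 20, MAC < 3,
   MAF < 0.01, call rate < 0.8, mean depth > 23, any ancestry-group
   F_IS outside [-0.5, +0.5] (a paralog-collapse guard);
3. individual filter: more than 50% missing genotypes.

MAF/MAC and call rate are computed on post-masking non-missing genotypes
across all individuals; mean depth averages DP over non-missing genotypes.
Every rule's removal count is recorded in a :class:`~admixscan.data.FilterReport`.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np

from .data import MISSING, ANCESTRY_LABELS, FilterReport, GenotypeMatrix

# cyvcf2 gt_types codes
_HOM_REF, _HET, _UNKNOWN, _HOM_ALT = 0, 1, 2, 3


def read_ancestry(path) -> dict[str, str]:
    """Read a two-column (individual, ancestry) TSV, with or without header."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if row[0] == "individual" and row[1] == "ancestry":
                continue
            ind, anc = row[0], row[1]
            if anc not in ANCESTRY_LABELS:
                raise ValueError(f"unknown ancestry label {anc!r} for {ind!r}")
            out[ind] = anc
    return out


def read_vcf(path, ancestry_path=None) -> GenotypeMatrix:
    """Load a VCF 4.x into a GenotypeMatrix.

    Genotype codes count reference-allele copies (hom-ref = 2). Multiallelic
    records and indels are retained but flagged non-SNP so the filter stage
    can drop them; missing GTs become the missing code. When an ancestry file
    is given, every VCF sample must appear in it or be explicitly unlabeled.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    locus_ids, quals, gts, gqs, dps, snp_flags = [], [], [], [], [], []
    for var in vcf:
        locus_ids.append(f"{var.CHROM}:{var.POS}")
        quals.append(var.QUAL if var.QUAL is not None else np.nan)
        snp_flags.append(var.is_snp and len(var.ALT) == 1)
        t = var.gt_types
        row = np.full(len(samples), MISSING, dtype=np.int8)
        row[t == _HOM_REF] = 2
        row[t == _HET] = 1
        row[t == _HOM_ALT] = 0
        gts.append(row)
        gq = var.gt_quals
        gqs.append(np.where(np.isnan(gq) | (gq < 0), np.nan, gq))
        dp = var.format("DP")
        if dp is None:
            dps.append(np.full(len(samples), np.nan))
        else:
            dp = dp.astype(float).reshape(-1)
            dps.append(np.where(dp < 0, np.nan, dp))
    vcf.close()
    ancestry = None
    if ancestry_path is not None:
        ancestry = read_ancestry(ancestry_path)
        unlabeled = [s for s in samples if s not in ancestry]
        if unlabeled:
            import warnings

            warnings.warn(f"{len(unlabeled)} VCF samples without ancestry label")
    if not locus_ids:
        raise ValueError(f"no records found in {path}")
    return GenotypeMatrix(
        genotypes=np.vstack(gts),
        locus_ids=locus_ids,
        individuals=samples,
        ancestry=ancestry,
        qual=np.asarray(quals, dtype=float),
        gq=np.vstack(gqs),
        dp=np.vstack(dps),
        is_biallelic_snp=np.asarray(snp_flags, dtype=bool),
    )


def mask_genotypes(gm: GenotypeMatrix, gq_min: float = 20, dp_min: float = 3) -> GenotypeMatrix:
    """Mark genotypes with GQ below ``gq_min`` or DP below ``dp_min`` missing.

    Boundary semantics follow the strict inequalities: GQ = 20 and DP = 3 are
    kept. NaN quality values are treated as passing (no information).
    """
    if gm.gq is None or gm.dp is None:
        raise ValueError("gq/dp layers absent; skip masking for this dataset")
    out = gm.copy()
    with np.errstate(invalid="ignore"):
        fail = (out.gq < gq_min) | (out.dp < dp_min)
    out.genotypes[fail] = MISSING
    return out


def _site_metrics(gm: GenotypeMatrix):
    codes = gm.genotypes
    present = codes != MISSING
    n = present.sum(axis=1).astype(float)
    refs = np.where(present, codes, 0).sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_ref = np.where(n > 0, refs / (2 * n), np.nan)
    maf = np.fmin(p_ref, 1 - p_ref)
    mac = np.fmin(refs, 2 * n - refs)
    call_rate = present.mean(axis=1)
    if gm.dp is not None:
        with np.errstate(invalid="ignore"):
            dp = np.where(present, gm.dp, np.nan)
            mean_dp = np.nanmean(np.where(np.isnan(dp), np.nan, dp), axis=1)
    else:
        mean_dp = np.full(gm.n_loci, np.nan)
    return maf, mac, call_rate, mean_dp


def _group_fis(gm: GenotypeMatrix) -> np.ndarray:
    """Per-locus F_IS per ancestry group (rows = groups), NaN where undefined."""
    from .popgen import basic_stats

    stats = basic_stats(gm)
    return np.vstack([df["fis"].to_numpy() for df in stats.per_group.values()])


def filter_sites(
    gm: GenotypeMatrix,
    qual_min: float = 20,
    mac_min: int = 3,
    maf_min: float = 0.01,
    callrate_min: float = 0.8,
    mean_dp_max: float = 23,
    fis_bound: float = 0.5,
    *,
    fis_rule: str = "any-group",
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the site-level filter cascade in a fixed order.

    Drops, in order: non-biallelic/indel records; QUAL <= ``qual_min``
    (inclusive, i.e. QUAL must exceed the threshold to survive); MAC <
    ``mac_min``; MAF < ``maf_min``; call rate < ``callrate_min``; mean DP >
    ``mean_dp_max``; and sites whose F_IS falls outside
    ``[-fis_bound, +fis_bound]`` in any ancestry group
    (``fis_rule="all-groups"`` requires every group to be outside instead).
    The F_IS rule is skipped when no ancestry labels are available. Counts
    per rule are attributed sequentially, so each site is charged to the
    first rule it violates.
    """
    report = FilterReport(input_count=gm.n_loci)
    keep = np.ones(gm.n_loci, dtype=bool)

    def apply_rule(name: str, violates: np.ndarray) -> None:
        hit = keep & violates
        report.add(name, int(hit.sum()))
        keep[hit] = False

    apply_rule("non_biallelic_snp", ~gm.is_biallelic_snp)
    if gm.qual is not None:
        with np.errstate(invalid="ignore"):
            apply_rule("qual_le", np.nan_to_num(gm.qual, nan=np.inf) <= qual_min)
    maf, mac, call_rate, mean_dp = _site_metrics(gm)
    with np.errstate(invalid="ignore"):
        apply_rule("mac_lt", np.nan_to_num(mac, nan=-1) < mac_min)
        apply_rule("maf_lt", np.nan_to_num(maf, nan=-1) < maf_min)
        apply_rule("callrate_lt", call_rate < callrate_min)
        apply_rule("mean_dp_gt", np.nan_to_num(mean_dp, nan=-np.inf) > mean_dp_max)
    if gm.ancestry:
        fis = _group_fis(gm)
        with np.errstate(invalid="ignore"):
            outside = np.abs(fis) > fis_bound
        outside = np.where(np.isnan(fis), False, outside)
        if fis_rule == "any-group":
            violates = outside.any(axis=0)
        elif fis_rule == "all-groups":
            violates = outside.all(axis=0)
        else:
            raise ValueError("fis_rule must be 'any-group' or 'all-groups'")
        apply_rule("fis_outside", violates)
    out = gm.subset_loci(np.flatnonzero(keep))
    return out, report


def filter_individuals(gm: GenotypeMatrix, max_missing: float = 0.5) -> tuple[GenotypeMatrix, FilterReport]:
    """Drop individuals with a missing-genotype fraction strictly above ``max_missing``."""
    report = FilterReport(input_count=gm.n_individuals)
    frac = gm.missing_mask.mean(axis=0)
    keep = frac <= max_missing
    report.add("missing_gt", int((~keep).sum()))
    return gm.subset_individuals(np.flatnonzero(keep)), report


# ---------------------------------------------------------------------------
# writing (used by the synthetic generator's round-trip guarantee)
# ---------------------------------------------------------------------------

_GT_STR = {2: "0/0", 1: "0/1", 0: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2 with GT:GQ:DP that round-trips through read_vcf."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        contigs = []
        for lid in gm.locus_ids:
            chrom = lid.rsplit(":", 1)[0]
            if chrom not in contigs:
                contigs.append(chrom)
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(gm.individuals) + "\n")
        qual = gm.qual if gm.qual is not None else np.full(gm.n_loci, 60.0)
        for i, lid in enumerate(gm.locus_ids):
            chrom, pos = lid.rsplit(":", 1)
            cells = []
            for j in range(gm.n_individuals):
                gt = _GT_STR[int(gm.genotypes[i, j])]
                gq = 99 if gm.gq is None or np.isnan(gm.gq[i, j]) else int(gm.gq[i, j])
                dp = 30 if gm.dp is None or np.isnan(gm.dp[i, j]) else int(gm.dp[i, j])
                cells.append(f"{gt}:{gq}:{dp}")
            q = "." if np.isnan(qual[i]) else f"{qual[i]:.6g}"
            fh.write(f"{chrom}\t{pos}\t{lid}\tA\tG\t{q}\t.\t.\tGT:GQ:DP\t")
            fh.write("\t".join(cells) + "\n")


def write_ancestry(ancestry: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        fh.write("individual\tancestry\n")
        for ind, anc in ancestry.items():
            fh.write(f"{ind}\t{anc}\n")
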