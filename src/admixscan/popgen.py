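"""Per-locus diversity statistics and fixed-allele accounting.

Implements the Nei (1987) family of estimators for biallelic SNPs:

* ``H_O`` — observed heterozygosity: fraction of non-missing individuals in a
  group that are heterozygous at a locus.
* ``H_S`` — within-group gene diversity with the small-sample correction
  ``H_S = (2n / (2n - 1)) * (1 - p^2 - q^2 - H_O / (2n))``.
* ``F_IS = 1 - H_O / H_S`` (undefined where ``H_S = 0``).
* ``H_T`` — total gene diversity from the unweighted mean of group allele
  frequencies; ``F_ST = 1 - mean(H_S) / H_T`` per locus, and a multi-locus
  ratio-of-averages version for genome-wide summaries.

Fixed-locus utilities implement the "all non-missing genotypes are the same
homozygote" definition, with an optional looser reading (any mix of the two
homozygote classes) behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import MISSING, GenotypeMatrix
from .stattests import benjamini_hochberg, dunn_test, fisher_exact


@dataclass
class DiversityStats:
    """Per-locus, per-group diversity estimates plus per-locus totals.

    ``per_group[group]`` is a DataFrame indexed by locus with columns
    ``n`` (non-missing individuals), ``p`` (reference-allele frequency),
    ``ho``, ``hs``, ``fis``. ``per_locus`` holds ``ht``, ``hs_mean``,
    ``fst``. All undefined cells are NaN and excluded from means.
    """

    per_group: dict[str, pd.DataFrame]
    per_locus: pd.DataFrame

    def group_means(self) -> pd.DataFrame:
        rows = []
        for g, df in self.per_group.items():
            rows.append({
                "group": g,
                "ho_mean": df["ho"].mean(),
                "hs_mean": df["hs"].mean(),
                "fis_mean": df["fis"].mean(),
                "n_loci": int(df["ho"].notna().sum()),
            })
        return pd.DataFrame(rows)

    def overall_fst(self) -> float:
        """Multi-locus Nei F_ST as a ratio of sums: 1 - sum(Hs)/sum(Ht)."""
        ok = self.per_locus[["ht", "hs_mean"]].dropna()
        ok = ok[ok["ht"] > 0]
        if ok.empty:
            return float("nan")
        return float(1.0 - ok["hs_mean"].sum() / ok["ht"].sum())


def _group_locus_stats(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized (n, p, ho, hs) for one group; codes are loci x members."""
    present = codes != MISSING
    n = present.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        refs = np.where(present, codes, 0).sum(axis=1).astype(float)
        p = np.where(n > 0, refs / (2 * n), np.nan)
        ho = np.where(n > 0, (codes == 1).sum(axis=1) / n, np.nan)
        hs_naive = 1.0 - p**2 - (1.0 - p) ** 2
        hs = np.where(
            n > 0, (2 * n / np.maximum(2 * n - 1, 1)) * (hs_naive - ho / (2 * n)), np.nan
        )
        hs = np.where(n > 0, np.clip(hs, 0.0, 1.0), np.nan)
    return n, p, ho, hs


def basic_stats(gm: GenotypeMatrix, groups: list[str] | None = None) -> DiversityStats:
    """Nei diversity estimates per locus per ancestry group.

    A locus entirely missing within a group is undefined (NaN) for that group
    and excluded from group means; ``H_T`` and ``F_ST`` at a locus use only
    groups with defined frequencies there.
    """
    if gm.ancestry is None:
        raise ValueError("ancestry labels are required")
    if groups is None:
        present = set(gm.ancestry_array()) - {""}
        groups = [g for g in ("island", "mainland", "F1") if g in present]
    per_group: dict[str, pd.DataFrame] = {}
    p_stack, hs_stack = [], []
    for g in groups:
        cols = gm.group_columns(g)
        if cols.size == 0:
            raise ValueError(f"group {g!r} has no individuals")
        n, p, ho, hs = _group_locus_stats(gm.genotypes[:, cols])
        fis = np.where(
            np.nan_to_num(hs, nan=0.0) > 0, 1.0 - ho / np.where(hs > 0, hs, np.nan), np.nan
        )
        per_group[g] = pd.DataFrame(
            {"n": n, "p": p, "ho": ho, "hs": hs, "fis": fis}, index=gm.locus_ids
        )
        p_stack.append(p)
        hs_stack.append(hs)
    p_arr = np.vstack(p_stack)
    hs_arr = np.vstack(hs_stack)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_bar = np.nanmean(p_arr, axis=0)
        ht = 1.0 - p_bar**2 - (1.0 - p_bar) ** 2
        hs_mean = np.nanmean(hs_arr, axis=0)
        fst = np.where(ht > 0, 1.0 - hs_mean / np.where(ht > 0, ht, np.nan), np.nan)
    per_locus = pd.DataFrame(
        {"ht": ht, "hs_mean": hs_mean, "fst": fst}, index=gm.locus_ids
    )
    return DiversityStats(per_group=per_group, per_locus=per_locus)


def nei_fst_from_freqs(p1, p2) -> float:
    """Two-deme multi-locus Nei F_ST from population allele frequencies.

    Ratio-of-sums estimator on the frequencies themselves (no sampling
    correction): ``1 - sum(Hs) / sum(Ht)`` with ``Hs`` the mean within-deme
    gene diversity and ``Ht`` from the mean frequency.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    hs = (2 * p1 * (1 - p1) + 2 * p2 * (1 - p2)) / 2.0
    pbar = (p1 + p2) / 2.0
    ht = 2 * pbar * (1 - pbar)
    ok = ht > 0
    if not ok.any():
        return float("nan")
    return float(1.0 - hs[ok].sum() / ht[ok].sum())


# ---------------------------------------------------------------------------
# fixed-locus accounting
# ---------------------------------------------------------------------------

def _fixed_flags(codes: np.ndarray, allow_mixed_homozygotes: bool) -> tuple[np.ndarray, np.ndarray]:
    """(fixed, all_missing) boolean flags per locus for one group."""
    present = codes != MISSING
    any_present = present.any(axis=1)
    het = (codes == 1) & present
    hom_ref = (codes == 2) & present
    hom_alt = (codes == 0) & present
    no_het = ~het.any(axis=1)
    if allow_mixed_homozygotes:
        fixed = any_present & no_het
    else:
        single_class = ~(hom_ref.any(axis=1) & hom_alt.any(axis=1))
        fixed = any_present & no_het & single_class
    return fixed, ~any_present


def count_fixed_loci(gm: GenotypeMatrix, group: str, *,
                     allow_mixed_homozygotes: bool = False) -> dict:
    """Count loci fixed within an ancestry group.

    A locus is fixed when every non-missing genotype in the group is the same
    homozygote class (``allow_mixed_homozygotes=True`` relaxes this to "no
    heterozygotes"). Loci entirely missing in the group are tallied
    separately, not counted as fixed.
    """
    cols = gm.group_columns(group)
    if cols.size == 0:
        raise ValueError(f"group {group!r} has no individuals")
    fixed, all_missing = _fixed_flags(gm.genotypes[:, cols], allow_mixed_homozygotes)
    return {
        "group": group,
        "fixed": int(fixed.sum()),
        "variable": int((~fixed & ~all_missing).sum()),
        "all_missing": int(all_missing.sum()),
        "total": gm.n_loci,
        "fixed_locus_ids": [gm.locus_ids[i] for i in np.flatnonzero(fixed)],
    }


def percent_fixed_variable(gm: GenotypeMatrix, group: str, within: str = "F1",
                           *, allow_mixed_homozygotes: bool = False) -> dict:
    """Share of loci fixed in ``group`` that segregate in ``within``.

    Returns the counts and the percentage (0-100, one use of which is the
    "fixed parental alleles that vary in hybrids" summary).
    """
    fixed = count_fixed_loci(gm, group, allow_mixed_homozygotes=allow_mixed_homozygotes)
    idx = {lid: i for i, lid in enumerate(gm.locus_ids)}
    rows = np.array([idx[l] for l in fixed["fixed_locus_ids"]], dtype=int)
    cols = gm.group_columns(within)
    if cols.size == 0:
        raise ValueError(f"group {within!r} has no individuals")
    if rows.size == 0:
        return {"group": group, "within": within, "fixed": 0, "variable_in_within": 0,
                "percent": float("nan")}
    sub = gm.genotypes[np.ix_(rows, cols)]
    fixed_within, all_missing = _fixed_flags(sub, allow_mixed_homozygotes)
    variable = ~fixed_within & ~all_missing
    return {
        "group": group,
        "within": within,
        "fixed": int(rows.size),
        "variable_in_within": int(variable.sum()),
        "percent": float(100.0 * variable.sum() / rows.size),
    }


def compare_fixed_counts(counts: dict[str, int], totals: dict[str, int],
                         *, fdr: float = 0.1, seed: int = 0) -> dict:
    """Fisher tests on fixed-locus counts across ancestry groups.

    Builds the r x 2 successes/failures table (successes = fixed loci),
    computes the overall Fisher p (Monte Carlo for r > 2) and all pairwise
    2x2 exact tests with BH-adjusted q-values.
    """
    groups = list(counts)
    for g in groups:
        if counts[g] > totals[g]:
            raise ValueError(f"count exceeds total for group {g!r}")
        if totals[g] <= 0:
            raise ValueError(f"zero total for group {g!r}")
    table = np.array([[counts[g], totals[g] - counts[g]] for g in groups])
    overall = fisher_exact(table, seed=seed)
    pairs = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            res = fisher_exact(table[[i, j]])
            pairs.append({"group1": groups[i], "group2": groups[j],
                          "odds_ratio": res.statistic, "p": res.p})
    pair_df = pd.DataFrame(pairs)
    pair_df["q"] = benjamini_hochberg(pair_df["p"].to_numpy())
    pair_df["significant"] = pair_df["q"] < fdr
    return {"overall_p": overall.p, "pairwise": pair_df}


# ---------------------------------------------------------------------------
# group diversity comparisons
# ---------------------------------------------------------------------------

def assign_significance_letters(labels: list[str], pair_sig: dict[frozenset, bool]) -> dict[str, str]:
    """Compact letter display: groups share a letter iff not significantly different.

    Greedy insert-and-absorb over the non-significance graph; adequate for the
    three-group comparisons made here.
    """
    letter_sets: list[set[str]] = []
    for lab in labels:
        placed = False
        for s in letter_sets:
            if all(not pair_sig.get(frozenset((lab, other)), False) for other in s):
                s.add(lab)
                placed = True
        if not placed:
            letter_sets.append({lab})
    # drop subsets produced by absorption
    keep = [s for i, s in enumerate(letter_sets)
            if not any(s < t for j, t in enumerate(letter_sets) if i != j)]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out: dict[str, str] = {lab: "" for lab in labels}
    for k, s in enumerate(keep):
        for lab in labels:
            if lab in s:
                out[lab] += alphabet[k]
    return out


def compare_group_diversity(stats: DiversityStats, snp_sets: dict[str, list[str]],
                            *, fdr: float = 0.1) -> pd.DataFrame:
    """Dunn's tests of per-locus H_O across ancestry groups within SNP sets.

    For each named set of locus IDs, pools the per-locus H_O values of every
    group, runs all pairwise Dunn comparisons (BH within the set) and assigns
    significance letters at the requested FDR.
    """
    rows = []
    groups = list(stats.per_group)
    for set_name, loci in snp_sets.items():
        if len(loci) < 2:
            raise ValueError(f"SNP set {set_name!r} has fewer than 2 loci")
        values, labels = [], []
        for g in groups:
            ho = stats.per_group[g].loc[loci, "ho"].dropna()
            values.append(ho.to_numpy())
            labels.append(np.repeat(g, ho.size))
        res = dunn_test(np.concatenate(values), np.concatenate(labels))
        sig = {frozenset((r.group1, r.group2)): bool(r.q < fdr) for r in res.itertuples()}
        letters = assign_significance_letters(groups, sig)
        for g, vals in zip(groups, values):
            rows.append({
                "snp_set": set_name, "group": g, "ho_mean": float(np.mean(vals)),
                "n_loci": int(vals.size), "letter": letters[g],
            })
    return pd.DataFrame(rows)
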