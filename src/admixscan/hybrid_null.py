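"""Simulation null for F1 observed heterozygosity and the deficit test.

The null hypothesis at each locus is neutral gamete union: an F1 inherits one
gamete from each parental gene pool, carrying the reference allele with the
population frequencies ``p_I`` (island) and ``p_M`` (mainland) estimated by
plug-in from parental genotypes. Under that law an F1 is heterozygous with
probability

    ``h = p_I (1 - p_M) + (1 - p_I) p_M``

so the per-cohort observed heterozygosity is ``Binomial(n_f1, h) / n_f1``.
Simulating B cohorts gives a per-locus null distribution of H_O; the test
compares the observed F1 heterozygosity against it with a lower-tail
add-one empirical p-value, BH-corrected across loci. Candidates are called
at FDR < 0.1.

Each locus draws from its own RNG substream keyed on (seed, locus index), so
per-locus p-values are invariant to locus order and subsetting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import MISSING, GenotypeMatrix
from .stattests import benjamini_hochberg, empirical_one_sided_p


@dataclass
class NullDistribution:
    """Per-locus simulated null H_O draws (loci x B) plus simulation metadata."""

    locus_ids: list[str]
    draws: np.ndarray  # shape (n_loci, B)
    n_f1_sim: int
    seed: int

    @property
    def B(self) -> int:
        return self.draws.shape[1]

    def mean(self) -> np.ndarray:
        return self.draws.mean(axis=1)


def parental_allele_freqs(gm: GenotypeMatrix) -> pd.DataFrame:
    """Plug-in reference-allele frequencies per locus in each parental group.

    Returns a frame indexed by locus with columns ``p_island``, ``p_mainland``,
    ``n_island``, ``n_mainland`` (non-missing individuals used). A locus with
    zero non-missing parents in a group gets a NaN frequency there and is
    excluded from downstream testing.
    """
    out = {}
    for group, p_col, n_col in (("island", "p_island", "n_island"),
                                ("mainland", "p_mainland", "n_mainland")):
        cols = gm.group_columns(group)
        if cols.size == 0:
            raise ValueError(f"parental group {group!r} is empty")
        codes = gm.genotypes[:, cols]
        present = codes != MISSING
        n = present.sum(axis=1).astype(float)
        refs = np.where(present, codes, 0).sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[p_col] = np.where(n > 0, refs / (2 * n), np.nan)
        out[n_col] = n.astype(int)
    return pd.DataFrame(out, index=gm.locus_ids)


def neutral_het_probability(p_i, p_m):
    """Expected F1 heterozygosity under neutral gamete union."""
    p_i = np.asarray(p_i, dtype=float)
    p_m = np.asarray(p_m, dtype=float)
    return p_i * (1 - p_m) + (1 - p_i) * p_m


def locus_rng(seed: int, locus_id: str) -> np.random.Generator:
    """Per-locus substream keyed on the locus ID (order/subset invariant)."""
    import zlib

    return np.random.default_rng([int(seed), zlib.crc32(str(locus_id).encode())])


def simulate_null_het(freqs: pd.DataFrame, n_f1: int, B: int = 1000,
                      seed: int = 0) -> NullDistribution:
    """Simulate B cohorts of ``n_f1`` F1s per locus and record each cohort's H_O.

    Each simulated hybrid receives one island gamete (reference with
    probability ``p_island``) and one mainland gamete (``p_mainland``); the
    cohort H_O is the heterozygote fraction, whose exact sampling law is
    ``Binomial(n_f1, h)/n_f1`` — sampled directly, per-locus substreams.
    Loci with undefined frequencies get NaN draws.
    """
    if n_f1 < 1 or B < 1:
        raise ValueError("n_f1 and B must be >= 1")
    p_i = freqs["p_island"].to_numpy(dtype=float)
    p_m = freqs["p_mainland"].to_numpy(dtype=float)
    h = neutral_het_probability(p_i, p_m)
    draws = np.full((len(h), B), np.nan)
    for k, lid in enumerate(freqs.index):
        if np.isnan(h[k]):
            continue
        rng = locus_rng(seed, lid)
        draws[k] = rng.binomial(n_f1, h[k], size=B) / n_f1
    return NullDistribution(locus_ids=list(freqs.index), draws=draws,
                            n_f1_sim=int(n_f1), seed=int(seed))


def observed_f1_het(gm: GenotypeMatrix) -> pd.DataFrame:
    """Observed H_O among non-missing F1 genotypes, per locus."""
    cols = gm.group_columns("F1")
    if cols.size == 0:
        raise ValueError("F1 group is empty")
    codes = gm.genotypes[:, cols]
    present = codes != MISSING
    n = present.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ho = np.where(n > 0, (codes == 1).sum(axis=1) / n, np.nan)
    return pd.DataFrame({"obs_ho": ho, "n_f1": n.astype(int)}, index=gm.locus_ids)


def het_deficit_test(gm: GenotypeMatrix, null: NullDistribution,
                     snp_subset: list[str] | None = None,
                     *, fdr: float = 0.1) -> pd.DataFrame:
    """Per-locus test for reduced F1 heterozygosity against the simulation null.

    Returns a frame with observed H_O, null mean, the lower-tail empirical
    p-value, BH q across all testable loci, and the candidate flag
    (q < ``fdr``). Loci with no non-missing F1 genotype or undefined parental
    frequencies are excluded from testing (NaN p, not counted in the BH m).
    """
    obs = observed_f1_het(gm)
    common = [l for l in null.locus_ids if l in set(obs.index)]
    if snp_subset is not None:
        wanted = set(snp_subset)
        common = [l for l in common if l in wanted]
    if not common:
        raise ValueError("no loci shared between observed data and null")
    draw_idx = {l: i for i, l in enumerate(null.locus_ids)}
    rows = []
    for lid in common:
        draws = null.draws[draw_idx[lid]]
        o = obs.at[lid, "obs_ho"]
        if np.isnan(o) or np.isnan(draws).all():
            rows.append({"locus": lid, "obs_ho": o, "null_mean": np.nan,
                         "p": np.nan})
            continue
        rows.append({
            "locus": lid,
            "obs_ho": float(o),
            "null_mean": float(np.nanmean(draws)),
            "p": empirical_one_sided_p(float(o), draws[~np.isnan(draws)]),
        })
    res = pd.DataFrame(rows).set_index("locus")
    res["q"] = benjamini_hochberg(res["p"].to_numpy())
    res["candidate"] = res["q"] < fdr
    return res
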