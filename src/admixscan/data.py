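"""Core in-memory containers shared across the toolkit.

The central object is :class:`GenotypeMatrix`, a loci x individuals matrix of
genotype codes. A code counts copies of the REFERENCE allele, so

* ``2`` = homozygous reference,
* ``1`` = heterozygous,
* ``0`` = homozygous alternate,
* ``MISSING`` (``-1``) = no call.

Phenotypes travel as a long-format :class:`pandas.DataFrame` (one row per
individual x year x trait measurement) and annotations as a tidy
(locus, term, category) frame; light validators below enforce their schemas.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING: int = -1

ANCESTRY_LABELS = ("island", "mainland", "F1")

PHENOTYPE_COLUMNS = ("individual", "trait", "year", "block", "value")
ANNOTATION_COLUMNS = ("locus", "term", "category")


@dataclass
class GenotypeMatrix:
    """Loci x individuals genotype codes with optional quality layers.

    Parameters
    ----------
    genotypes
        ``(n_loci, n_individuals)`` int8 array of codes in ``{0, 1, 2, -1}``.
    locus_ids
        Per-locus identifiers, conventionally ``"scaffold:position"``.
    individuals
        Sample identifiers, one per column.
    ancestry
        Optional map individual -> ``{"island", "mainland", "F1"}``.
    qual
        Optional per-locus PHRED site quality.
    gq, dp
        Optional per-genotype quality / depth layers, same shape as
        ``genotypes``.
    is_biallelic_snp
        Per-locus flag; multiallelic records and indels read from a VCF are
        retained but marked ``False`` so the filter stage can drop them.
    """

    genotypes: np.ndarray
    locus_ids: list[str]
    individuals: list[str]
    ancestry: dict[str, str] | None = None
    qual: np.ndarray | None = None
    gq: np.ndarray | None = None
    dp: np.ndarray | None = None
    is_biallelic_snp: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D (loci x individuals) array")
        n_loci, n_ind = self.genotypes.shape
        if len(self.locus_ids) != n_loci:
            raise ValueError("locus_ids length does not match genotype rows")
        if len(self.individuals) != n_ind:
            raise ValueError("individuals length does not match genotype columns")
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype codes must be in {0, 1, 2, -1}")
        if self.qual is not None:
            self.qual = np.asarray(self.qual, dtype=float)
            if self.qual.shape != (n_loci,):
                raise ValueError("qual must be per-locus")
        for name in ("gq", "dp"):
            layer = getattr(self, name)
            if layer is not None:
                layer = np.asarray(layer)
                if layer.shape != self.genotypes.shape:
                    raise ValueError(f"{name} layer shape mismatch")
                setattr(self, name, layer)
        if self.is_biallelic_snp is None:
            self.is_biallelic_snp = np.ones(n_loci, dtype=bool)
        else:
            self.is_biallelic_snp = np.asarray(self.is_biallelic_snp, dtype=bool)
        if self.ancestry is not None:
            unknown = {a for a in self.ancestry.values() if a not in ANCESTRY_LABELS}
            if unknown:
                raise ValueError(f"unknown ancestry labels: {sorted(unknown)}")

    # ------------------------------------------------------------------ basics
    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return self.genotypes == MISSING

    def ancestry_array(self) -> np.ndarray:
        """Per-column ancestry labels ('' where unlabeled)."""
        anc = self.ancestry or {}
        return np.array([anc.get(ind, "") for ind in self.individuals])

    def group_columns(self, group: str) -> np.ndarray:
        """Column indices of the individuals labeled ``group``."""
        return np.flatnonzero(self.ancestry_array() == group)

    def dosages(self) -> np.ndarray:
        """Float copy of the codes with missing as NaN."""
        out = self.genotypes.astype(float)
        out[self.genotypes == MISSING] = np.nan
        return out

    # ----------------------------------------------------------------- subsets
    def subset_loci(self, idx: Iterable[int] | np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(list(idx) if not isinstance(idx, np.ndarray) else idx)
        return GenotypeMatrix(
            genotypes=self.genotypes[idx],
            locus_ids=[self.locus_ids[i] for i in idx],
            individuals=list(self.individuals),
            ancestry=dict(self.ancestry) if self.ancestry else None,
            qual=None if self.qual is None else self.qual[idx],
            gq=None if self.gq is None else self.gq[idx],
            dp=None if self.dp is None else self.dp[idx],
            is_biallelic_snp=self.is_biallelic_snp[idx],
        )

    def subset_individuals(self, idx: Iterable[int] | np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(list(idx) if not isinstance(idx, np.ndarray) else idx)
        keep = [self.individuals[i] for i in idx]
        anc = None
        if self.ancestry is not None:
            anc = {k: v for k, v in self.ancestry.items() if k in set(keep)}
        return GenotypeMatrix(
            genotypes=self.genotypes[:, idx],
            locus_ids=list(self.locus_ids),
            individuals=keep,
            ancestry=anc,
            qual=None if self.qual is None else self.qual.copy(),
            gq=None if self.gq is None else self.gq[:, idx],
            dp=None if self.dp is None else self.dp[:, idx],
            is_biallelic_snp=self.is_biallelic_snp.copy(),
        )

    def copy(self) -> "GenotypeMatrix":
        return self.subset_loci(np.arange(self.n_loci))


@dataclass
class FilterReport:
    """Ordered per-rule removal counts from a filtering cascade."""

    input_count: int
    removed: list[tuple[str, int]] = field(default_factory=list)

    def add(self, rule: str, count: int) -> None:
        if count < 0:
            raise ValueError("removal count must be non-negative")
        self.removed.append((rule, int(count)))

    @property
    def output_count(self) -> int:
        return self.input_count - sum(c for _, c in self.removed)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.removed, columns=["rule", "removed"])

    def to_dict(self) -> dict:
        return {
            "input": self.input_count,
            "output": self.output_count,
            "removed": [{"rule": r, "count": c} for r, c in self.removed],
        }


def validate_phenotypes(df: pd.DataFrame) -> pd.DataFrame:
    """Check a long-format phenotype table and return it with ordered columns."""
    missing = set(PHENOTYPE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    return df.loc[:, list(PHENOTYPE_COLUMNS)]


def validate_annotations(df: pd.DataFrame) -> pd.DataFrame:
    """Check a (locus, term, category) annotation table.

    Every term must belong to exactly one category.
    """
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    cats = df.groupby("term")["category"].nunique()
    multi = cats[cats > 1]
    if len(multi):
        raise ValueError(f"terms with multiple categories: {list(multi.index)[:5]}")
    return df.loc[:, list(ANNOTATION_COLUMNS)]
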