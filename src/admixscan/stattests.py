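"""Shared statistical primitives.

Implements the small set of tests the pipeline leans on: Benjamini-Hochberg
FDR, add-one empirical one-sided p-values for simulation nulls, Pearson's
chi-square with Yates' continuity correction, Fisher's exact test (2x2 exact;
r x 2 by fixed-margins Monte Carlo), Haldane-Anscombe-corrected log odds
ratios, Dunn's rank-based post hoc test, and a repeated-measures correlation
screen.

Conventions
-----------
* 2x2 tables are ``[[a, b], [c, d]]`` with rows = set 1 / set 2 and columns =
  success / failure; a positive log odds ratio means successes are enriched
  in row 1.
* Empirical p-values use the add-one rule ``(1 + #{null <= obs}) / (B + 1)``
  so that no p-value is exactly zero before FDR correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class TestResult:
    statistic: float
    p: float
    df: int | None = None
    q: float | None = None


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    ``q_i = min_{j: p_(j) >= p_i} m * p_(j) / rank(j)``, capped at 1. NaNs
    propagate and are excluded from the number of tests ``m``.
    """
    p = np.asarray(p_values, dtype=float)
    flat = p.ravel()
    ok = ~np.isnan(flat)
    if ((flat[ok] < 0) | (flat[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full(flat.shape, np.nan)
    m = int(ok.sum())
    if m:
        pv = flat[ok]
        order = np.argsort(pv, kind="mergesort")
        ranked = pv[order] * m / np.arange(1, m + 1)
        qv = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty(m)
        out[order] = np.minimum(qv, 1.0)
        q[ok] = out
    return q.reshape(p.shape)


def empirical_one_sided_p(observed: float, null_draws) -> float:
    """Lower-tail empirical p-value with the add-one correction.

    Probability that a null draw is less than or equal to the observed value,
    estimated as ``(1 + #{draw <= observed}) / (B + 1)``.
    """
    draws = np.asarray(null_draws, dtype=float)
    if draws.size == 0:
        raise ValueError("null_draws must be non-empty")
    return (1.0 + np.count_nonzero(draws <= observed)) / (draws.size + 1.0)


# ---------------------------------------------------------------------------
# contingency tables
# ---------------------------------------------------------------------------

def _as_table(table) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if t.sum() <= 0:
        raise ValueError("table total must be positive")
    return t


def yates_chi_square(table) -> TestResult:
    """Pearson chi-square on a 2x2 table with Yates' continuity correction.

    The correction term is ``min(0.5, |O - E|)`` so exactly proportional
    tables yield a statistic of 0 (matching R's ``chisq.test``).
    """
    t = _as_table(table)
    if t.shape != (2, 2):
        raise ValueError("yates_chi_square expects a 2x2 table")
    row = t.sum(axis=1, keepdims=True)
    col = t.sum(axis=0, keepdims=True)
    if (row == 0).any() or (col == 0).any():
        raise ValueError("chi-square undefined with a zero margin")
    expected = row @ col / t.sum()
    adj = np.abs(t - expected) - np.minimum(0.5, np.abs(t - expected))
    statistic = float((adj**2 / expected).sum())
    p = float(stats.chi2.sf(statistic, df=1))
    return TestResult(statistic=statistic, p=p, df=1)


def fisher_exact(table, alternative: str = "two-sided", *,
                 n_mc: int = 100_000, seed: int = 0) -> TestResult:
    """Fisher's exact test for a 2x2 or r x 2 table of counts.

    2x2 tables use the exact hypergeometric distribution with the two-sided
    probability-mass rule (tables at most as probable as the observed one),
    identical to R's ``fisher.test``. Larger ``r x 2`` tables use a
    fixed-margins Monte-Carlo version of the same rule (``n_mc`` sampled
    tables, add-one p-value), since full network enumeration is only needed
    for the pairwise follow-ups which are 2x2.
    """
    t = _as_table(table)
    if t.shape == (2, 2):
        odds, p = stats.fisher_exact(t, alternative=alternative)
        return TestResult(statistic=float(odds), p=float(p))
    if t.ndim != 2 or t.shape[1] != 2:
        raise ValueError("fisher_exact expects a 2x2 or r x 2 table")
    if alternative != "two-sided":
        raise ValueError("r x 2 tables support only the two-sided test")
    return _fisher_rx2_montecarlo(t.astype(int), n_mc=n_mc, seed=seed)


def _log_table_prob(t: np.ndarray, lgam_rows, lgam_cols, lgam_n) -> float:
    """Log multivariate hypergeometric probability of a fixed-margins table."""
    from scipy.special import gammaln

    return float(lgam_rows + lgam_cols - lgam_n - gammaln(t + 1.0).sum())


def _fisher_rx2_montecarlo(t: np.ndarray, n_mc: int, seed: int) -> TestResult:
    from scipy.special import gammaln

    rows = t.sum(axis=1)
    col1 = int(t[:, 0].sum())
    n = int(t.sum())
    lgam_rows = gammaln(rows + 1.0).sum() + gammaln(np.array([col1, n - col1]) + 1.0).sum()
    lgam_n = gammaln(n + 1.0)
    logp_obs = _log_table_prob(t.astype(float), lgam_rows, 0.0, lgam_n)
    rng = np.random.default_rng(seed)
    # Draw first columns row by row from the sequential hypergeometric scheme
    # (equivalent to R's r2dtable).
    hits = 0
    remaining = np.empty(len(rows), dtype=int)
    for _ in range(n_mc):
        left = col1
        pool = n
        for i, r in enumerate(rows):
            pool -= r
            draw = rng.hypergeometric(r, pool, left) if left else 0
            remaining[i] = draw
            left -= draw
        sim = np.column_stack([remaining, rows - remaining]).astype(float)
        if _log_table_prob(sim, lgam_rows, 0.0, lgam_n) <= logp_obs + 1e-12:
            hits += 1
    p = (1 + hits) / (n_mc + 1)
    return TestResult(statistic=np.nan, p=float(p))


def haldane_anscombe_log_or(table) -> tuple[float, float]:
    """Log odds ratio and SE with 0.5 added to every cell.

    Finite for tables with zero cells; ``log_or > 0`` means successes are
    enriched in row 1.
    """
    t = _as_table(table)
    if t.shape != (2, 2):
        raise ValueError("haldane_anscombe_log_or expects a 2x2 table")
    a, b, c, d = (t + 0.5).ravel()
    log_or = float(np.log(a * d / (b * c)))
    se = float(np.sqrt(1 / a + 1 / b + 1 / c + 1 / d))
    return log_or, se


# ---------------------------------------------------------------------------
# rank-based post hoc comparisons
# ---------------------------------------------------------------------------

def dunn_test(values, groups) -> pd.DataFrame:
    """Dunn's pairwise z-tests on pooled mid-ranks, BH-adjusted.

    The nonparametric analogue of one-way ANOVA post hoc contrasts: all
    observations are ranked jointly (ties get mid-ranks), and each pair of
    groups is compared through

    ``z = (Rbar_i - Rbar_j) / sqrt([N(N+1)/12 - T] (1/n_i + 1/n_j))``

    where ``T = sum(t^3 - t) / (12 (N - 1))`` corrects for ties. Returns one
    row per pair with z, two-sided normal p, and BH q across the pairs.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if v.shape != g.shape:
        raise ValueError("values and groups must align")
    labels = list(pd.unique(g))
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    sizes = {lab: int((g == lab).sum()) for lab in labels}
    if min(sizes.values()) == 0:
        raise ValueError("every group must be non-empty")
    ranks = stats.rankdata(v)
    n = v.size
    _, tie_counts = np.unique(v, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (12.0 * (n - 1)) if n > 1 else 0.0
    var_base = n * (n + 1) / 12.0 - tie_term
    mean_rank = {lab: ranks[g == lab].mean() for lab in labels}
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a, b = labels[i], labels[j]
            se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
            z = 0.0 if se == 0 else (mean_rank[a] - mean_rank[b]) / se
            p = 2 * stats.norm.sf(abs(z))
            rows.append({"group1": a, "group2": b, "z": z, "p": min(1.0, p)})
    out = pd.DataFrame(rows)
    out["q"] = benjamini_hochberg(out["p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# repeated-measures correlation screen
# ---------------------------------------------------------------------------

def repeated_measures_correlation(trait_pairs, phenotypes: pd.DataFrame,
                                  *, flag_threshold: float = 0.6,
                                  alpha: float = 0.05) -> pd.DataFrame:
    """Within-individual correlation for each trait pair.

    Uses the ANCOVA formulation of repeated-measures correlation (common
    slope after removing individual means; delegated to ``pingouin.rm_corr``)
    on the records shared by both traits at the same (individual, year).
    A pair is flagged redundant when ``|r| >= flag_threshold``.
    """
    import pingouin as pg

    rows = []
    for t1, t2 in trait_pairs:
        wide = _paired_records(phenotypes, t1, t2)
        n_multi = wide.groupby("individual").size()
        if (n_multi >= 2).sum() < 3:
            raise ValueError(
                f"need >=3 individuals with repeated shared records for ({t1}, {t2})"
            )
        res = pg.rm_corr(data=wide, x="y1", y="y2", subject="individual")
        r = float(res["r"].iloc[0])
        p = float(res["pval"].iloc[0])
        rows.append({
            "trait1": t1, "trait2": t2, "r": r, "p": p,
            "significant": p < alpha, "flag_redundant": abs(r) >= flag_threshold,
        })
    return pd.DataFrame(rows)


def _paired_records(phenotypes: pd.DataFrame, t1: str, t2: str) -> pd.DataFrame:
    a = phenotypes[phenotypes["trait"] == t1][["individual", "year", "value"]]
    b = phenotypes[phenotypes["trait"] == t2][["individual", "year", "value"]]
    wide = a.merge(b, on=["individual", "year"], suffixes=("_1", "_2"))
    wide = wide.rename(columns={"value_1": "y1", "value_2": "y2"}).dropna()
    if len(wide) < 2:
        raise ValueError(f"fewer than 2 shared records for traits ({t1}, {t2})")
    return wide
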