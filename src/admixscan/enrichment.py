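"""Annotation-term enrichment of candidate loci versus a background set.

For every term, a 2x2 table counts successes (occurrences of the term) and
failures (all other annotation instances) in the candidate set and a random
background set of loci. Tables go through Fisher's exact test; BH correction
runs within each (annotation set x category) stratum — PO as one stratum,
GO split into biological process / molecular function / cellular component.
Effect sizes are Haldane-Anscombe-corrected log odds ratios (+0.5 in every
cell) so zero cells remain informative; a positive log-OR means the term is
enriched among candidates.

The counting unit is annotation INSTANCES (a locus annotated twice with a
term contributes two successes), matching the literal successes/failures
definition; ``unique_per_locus=True`` switches to counting loci.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import validate_annotations
from .stattests import benjamini_hochberg, fisher_exact, haldane_anscombe_log_or

GO_CATEGORIES = ("biological_process", "molecular_function", "cellular_component")


def _term_counts(annotations: pd.DataFrame, loci: set, unique_per_locus: bool) -> pd.Series:
    sub = annotations[annotations["locus"].isin(loci)]
    if unique_per_locus:
        sub = sub.drop_duplicates(["locus", "term"])
    return sub.groupby("term").size()


def sample_background(loci: list[str], size: int, seed: int = 0,
                      exclude: set | None = None) -> list[str]:
    """Sample a background locus set without replacement (fixed seed)."""
    pool = [l for l in loci if not exclude or l not in exclude]
    if size > len(pool):
        raise ValueError("background size exceeds available loci")
    rng = np.random.default_rng(seed)
    return list(rng.choice(pool, size=size, replace=False))


def build_term_table(term: str, candidate_map: pd.DataFrame,
                     background_map: pd.DataFrame,
                     *, unique_per_locus: bool = False) -> np.ndarray:
    """2x2 successes/failures table for one term.

    Rows are (candidate, background); successes count instances of ``term``,
    failures all remaining annotation instances in that set. A term absent
    from one set simply contributes zero successes there; a term absent from
    both raises.
    """
    cand = validate_annotations(candidate_map)
    back = validate_annotations(background_map)
    if cand.empty or back.empty:
        raise ValueError("candidate and background maps must be non-empty")
    rows = []
    for df in (cand, back):
        sub = df.drop_duplicates(["locus", "term"]) if unique_per_locus else df
        succ = int((sub["term"] == term).sum())
        total = int(len(sub))
        rows.append([succ, total - succ])
    table = np.asarray(rows)
    if table[:, 0].sum() == 0:
        raise ValueError(f"term {term!r} absent from both sets")
    return table


def enrichment_scan(candidate_map: pd.DataFrame, background_map: pd.DataFrame,
                    *, fdr: float = 0.1, unique_per_locus: bool = False) -> pd.DataFrame:
    """Per-term Fisher enrichment scan with within-category BH correction.

    Returns one row per term observed in either set: the 2x2 counts, Fisher
    two-sided p, BH q within the term's (set x category) stratum, the
    Haldane-Anscombe log-OR with SE, direction ('enriched' when candidates
    carry the term more often), and the flag at q < ``fdr``.
    """
    cand = validate_annotations(candidate_map)
    back = validate_annotations(background_map)
    if cand.empty or back.empty:
        raise ValueError("candidate and background maps must be non-empty")
    categories = pd.concat([cand, back]).drop_duplicates("term").set_index("term")["category"]
    c_counts = _term_counts(cand, set(cand["locus"]), unique_per_locus)
    b_counts = _term_counts(back, set(back["locus"]), unique_per_locus)
    c_total = int(c_counts.sum())
    b_total = int(b_counts.sum())
    rows = []
    for term in categories.index:
        a = int(c_counts.get(term, 0))
        c = int(b_counts.get(term, 0))
        if a + c == 0:
            continue
        table = np.array([[a, c_total - a], [c, b_total - c]])
        res = fisher_exact(table)
        log_or, se = haldane_anscombe_log_or(table)
        rows.append({
            "term": term, "category": categories[term],
            "cand_success": a, "cand_failure": c_total - a,
            "back_success": c, "back_failure": b_total - c,
            "p": res.p, "log_or": log_or, "log_or_se": se,
            "direction": "enriched" if log_or > 0 else ("depleted" if log_or < 0 else "none"),
        })
    out = pd.DataFrame(rows)
    if out.empty:
        raise ValueError("no terms to test")
    out["q"] = np.nan
    for cat, sel in out.groupby("category").groups.items():
        out.loc[sel, "q"] = benjamini_hochberg(out.loc[sel, "p"].to_numpy())
    out["flag"] = out["q"] < fdr
    return out.sort_values(["category", "q"]).reset_index(drop=True)
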