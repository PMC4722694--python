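"""Tiered gene-set over-representation analysis.

Significant features are ranked (most significant first) and Fisher
enrichment is evaluated on nested top-k prefixes ("tiers", e.g. top 25, 50,
100, ... genes), so sets driven by the strongest hits are not diluted by
weaker ones. Sets are restricted to the analysis background and sets with
fewer than ``min_set_size`` background members are excluded. Within each
tier the one-sided Fisher p-values are BH-adjusted; the per-set summary is
the minimum p over tiers (a descriptive ranking, not an adjusted statistic).
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_adjust

DEFAULT_TIERS = (25, 50, 100, 350, 600, 850)


def fisher_enrichment_p(overlap: int, tier_k: int, set_size: int, background: int) -> float:
    """One-sided (enrichment) Fisher exact p: P(X >= overlap) hypergeometric."""
    return float(stats.hypergeom.sf(overlap - 1, background, set_size, tier_k))


def tiered_fisher(
    ranked_sig,
    background,
    gene_sets: dict[str, tuple[str, list[str]]],
    tiers=None,
    min_set_size: int = 10,
) -> pd.DataFrame:
    """Enrichment table over nested top-k tiers of a ranked significant list.

    ``ranked_sig`` is ordered most-significant-first; features absent from
    ``background`` are dropped with a warning. ``tiers`` defaults to
    (25, 50, 100, 350, 600, 850) plus the full list length; tiers are capped
    at the ranked-list length and deduplicated.
    """
    background = set(background)
    if not background:
        raise ValueError("empty background")
    ranked = [f for f in ranked_sig if f in background]
    if len(ranked) < len(list(ranked_sig)):
        warnings.warn(
            f"dropped {len(list(ranked_sig)) - len(ranked)} ranked features "
            "absent from background",
            stacklevel=2,
        )
    if tiers is None:
        tiers = list(DEFAULT_TIERS) + [len(ranked)]
    tiers = sorted({min(int(t), len(ranked)) for t in tiers if t > 0})

    restricted = {}
    for name, (desc, members) in gene_sets.items():
        mem = set(members) & background
        if len(mem) >= min_set_size:
            restricted[name] = mem

    n_bg = len(background)
    rows = []
    for k in tiers:
        top = set(ranked[:k])
        if not top:
            warnings.warn(f"tier {k} is empty; skipped", stacklevel=2)
            continue
        pvals, metas = [], []
        for name, mem in restricted.items():
            overlap = len(top & mem)
            pvals.append(fisher_enrichment_p(overlap, k, len(mem), n_bg))
            metas.append((name, k, overlap, len(mem)))
        adj = bh_adjust(pvals) if pvals else []
        for (name, tier_k, overlap, size), p_raw, p_adj in zip(metas, pvals, adj):
            rows.append(
                {"set_name": name, "tier_k": tier_k, "overlap_count": overlap,
                 "set_size_in_background": size, "p_fisher": p_raw, "adj_p": p_adj}
            )
    return pd.DataFrame(
        rows,
        columns=["set_name", "tier_k", "overlap_count",
                 "set_size_in_background", "p_fisher", "adj_p"],
    )


def summarize_top_terms(table: pd.DataFrame, n: int = 15) -> pd.DataFrame:
    """Top sets by minimum p over tiers.

    Ties broken by larger overlap at the argmin tier, then set name.
    """
    if table.empty:
        raise ValueError("empty enrichment table")
    best_idx = table.groupby("set_name")["p_fisher"].idxmin()
    best = table.loc[best_idx].copy()
    best = best.rename(columns={"p_fisher": "min_p", "tier_k": "best_tier"})
    best = best.sort_values(
        by=["min_p", "overlap_count", "set_name"],
        ascending=[True, False, True],
        kind="mergesort",
    )
    return best.head(n).reset_index(drop=True)
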