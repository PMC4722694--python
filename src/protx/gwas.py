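"""Locus-to-gene mapping for genome-wide-significant SNPs.

A SNP qualifies for a gene when its association p-value is strictly below
the genome-wide threshold (5e-8) and its position falls inside the gene's
primary regulatory window [start - 100 kb, end + 100 kb] (1-based inclusive
coordinates, inclusive endpoints). Per gene only the best SNP (minimal p,
ties to the smaller position) is reported, together with a simplified
positional class and, optionally, differential-evidence annotation from the
proteomics and RNA tables.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

GENOME_WIDE_P = 5e-8
DEFAULT_WINDOW = 100_000

EVIDENCE_ORDER = {"both": 0, "Proteomics": 1, "RNA-Seq": 2, "none": 3}


def _position_class(pos: int, gene: pd.Series) -> str:
    if gene.start <= pos <= gene.end:
        return "intronic"  # no exon/UTR sub-annotation: gene-body default
    upstream_side = pos < gene.start
    if gene.strand == "+":
        return "upstream" if upstream_side else "downstream"
    return "downstream" if upstream_side else "upstream"


def genes_near_snps(
    snps: pd.DataFrame,
    gene_models: pd.DataFrame,
    window: int = DEFAULT_WINDOW,
    p_threshold: float = GENOME_WIDE_P,
) -> pd.DataFrame:
    """Best genome-wide-significant SNP within ``window`` bp of each gene.

    Returns one row per implicated gene: symbol, best SNP (chrom, pos, rsid,
    p), distance (0 inside the gene body) and positional class. SNPs on
    chromosomes absent from the gene models are skipped with a warning.
    """
    sig = snps[snps["p"] < p_threshold]
    known_chroms = set(gene_models["chrom"])
    unknown = sig[~sig["chrom"].isin(known_chroms)]
    if len(unknown):
        warnings.warn(
            f"skipped {len(unknown)} significant SNP(s) on chromosomes absent "
            "from the gene models",
            stacklevel=2,
        )
        sig = sig[sig["chrom"].isin(known_chroms)]

    by_chrom = {
        chrom: sub.sort_values(["p", "pos"], kind="mergesort")
        for chrom, sub in sig.groupby("chrom")
    }
    rows = []
    for _, gene in gene_models.iterrows():
        sub = by_chrom.get(gene.chrom)
        if sub is None:
            continue
        pos_arr = sub["pos"].to_numpy()
        in_window = (pos_arr >= gene.start - window) & (pos_arr <= gene.end + window)
        if not in_window.any():
            continue
        best = sub.iloc[int(np.argmax(in_window))]  # first hit = minimal (p, pos)
        pos = int(best.pos)
        if gene.start <= pos <= gene.end:
            distance = 0
        else:
            distance = int(gene.start - pos) if pos < gene.start else int(pos - gene.end)
        rows.append(
            {
                "symbol": gene.symbol,
                "chrom": gene.chrom,
                "pos": pos,
                "rsid": best.rsid,
                "p": float(best.p),
                "distance": distance,
                "position_class": _position_class(pos, gene),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["symbol", "chrom", "pos", "rsid", "p", "distance", "position_class"],
    )
    return out.sort_values("symbol", kind="mergesort").reset_index(drop=True)


def join_de_evidence(
    hits: pd.DataFrame,
    de_protein: pd.DataFrame | None,
    de_rna: pd.DataFrame | None,
    alpha_protein: float = 0.05,
    alpha_rna: float = 0.05,
) -> pd.DataFrame:
    """Annotate locus genes with corrected-significance evidence per platform.

    ``de_evidence`` is one of Proteomics / RNA-Seq / both / none; the report
    is sorted by evidence strength then symbol.
    """
    def sig_set(tab: pd.DataFrame | None, alpha: float) -> set:
        if tab is None or tab.empty:
            return set()
        return set(tab.index[tab["adj_p"] < alpha])

    sig_p = sig_set(de_protein, alpha_protein)
    sig_r = sig_set(de_rna, alpha_rna)
    out = hits.copy()
    evidence = []
    for sym in out["symbol"]:
        in_p, in_r = sym in sig_p, sym in sig_r
        evidence.append(
            "both" if in_p and in_r
            else "Proteomics" if in_p
            else "RNA-Seq" if in_r
            else "none"
        )
    out["de_evidence"] = evidence
    out["_rank"] = out["de_evidence"].map(EVIDENCE_ORDER)
    out = out.sort_values(["_rank", "symbol"], kind="mergesort").drop(columns="_rank")
    return out.reset_index(drop=True)
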