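"""Protein-level preprocessing for multiplexed (TMT) intensity data.

Stages, in pipeline order:

1. keep only proteins identified in every plex (common-protein filter);
2. within each plex, divide each protein's channel signal by the protein's
   total ion intensity in that plex (rows then sum to 1);
3. collapse protein IDs to gene symbols, dropping unmapped IDs and averaging
   duplicate-symbol proteins;
4. across plexes, divide each value by the protein's mean over all samples
   (rows then have mean 1), removing per-plex scale by construction.

Downstream modeling uses log2 of the stage-2 matrix, so group effects read
as symmetric fold changes.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datatypes import AbundanceMatrix, PlexIntensitySet
from .errors import MappingError, NormalizationError


def filter_common_proteins(plexes: list[PlexIntensitySet]) -> pd.Index:
    """Proteins present (fully observed row) in every plex."""
    if len(plexes) < 2:
        raise ValueError("need at least two plexes to intersect")
    common = plexes[0].proteins
    for plex in plexes[1:]:
        common = common.intersection(plex.proteins)
    if len(common) == 0:
        warnings.warn("no proteins common to all plexes", stacklevel=2)
    return common.sort_values()


def normalize_intra_plex(
    plex: PlexIntensitySet, proteins: pd.Index | None = None
) -> AbundanceMatrix:
    """Per-protein fraction of the protein's total ion intensity in the plex."""
    data = plex.by_sample()
    if proteins is not None:
        data = data.loc[proteins]
    totals = data.sum(axis=1)
    zero = totals[totals <= 0]
    if len(zero):
        raise NormalizationError(
            f"plex {plex.plex_id}: zero total intensity for protein(s) "
            f"{list(zero.index[:5])}"
        )
    return AbundanceMatrix(data.div(totals, axis=0), stage="intra_norm")


def map_to_genes(matrix: AbundanceMatrix, id_map: pd.DataFrame) -> AbundanceMatrix:
    """Collapse protein IDs to unique gene symbols.

    Unmapped proteins are dropped; proteins sharing a symbol are replaced by
    their per-sample arithmetic mean. A protein ID mapping to more than one
    symbol is an error (ambiguous map).
    """
    dup_ids = id_map[id_map.duplicated("protein_id", keep=False)]
    if len(dup_ids):
        amb = sorted(dup_ids["protein_id"].unique())
        raise MappingError(f"protein IDs map to multiple symbols: {amb[:5]}")
    lookup = id_map.set_index("protein_id")["symbol"]
    keep = matrix.data.index.intersection(lookup.index)
    mapped = matrix.data.loc[keep]
    symbols = lookup.loc[keep]
    collapsed = mapped.groupby(symbols.to_numpy()).mean()
    collapsed.index.name = "feature"
    return AbundanceMatrix(collapsed.sort_index(), stage=matrix.stage)


def join_plexes(matrices: list[AbundanceMatrix]) -> AbundanceMatrix:
    """Column-concatenate per-plex matrices on their shared feature set."""
    common = matrices[0].data.index
    for m in matrices[1:]:
        common = common.intersection(m.data.index)
    joined = pd.concat([m.data.loc[common] for m in matrices], axis=1)
    return AbundanceMatrix(joined, stage=matrices[0].stage)


def normalize_inter_plex(joined: AbundanceMatrix) -> AbundanceMatrix:
    """Divide by the per-protein mean over all samples (row means become 1)."""
    if joined.stage != "intra_norm":
        raise ValueError("inter-plex normalization expects an intra_norm matrix")
    means = joined.data.mean(axis=1)
    zero = means[means <= 0]
    if len(zero):
        raise NormalizationError(
            f"zero mean normalized value for protein(s) {list(zero.index[:5])}"
        )
    return AbundanceMatrix(joined.data.div(means, axis=0), stage="inter_norm")


def prep_proteomics(
    plexes: list[PlexIntensitySet], id_map: pd.DataFrame
) -> tuple[AbundanceMatrix, AbundanceMatrix]:
    """Full chain: filter -> intra-norm -> gene mapping -> inter-norm.

    Returns the inter-normalized matrix and its log2 transform (the modeling
    input).
    """
    common = filter_common_proteins(plexes)
    intra = [normalize_intra_plex(p, common) for p in plexes]
    mapped = [map_to_genes(m, id_map) for m in intra]
    joined = join_plexes(mapped)
    inter = normalize_inter_plex(joined)
    log2 = AbundanceMatrix(np.log2(inter.data), stage="log2")
    return inter, log2
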