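"""Core in-memory containers shared across pipeline stages.

Matrices are pandas DataFrames (features as rows, samples as columns);
these thin dataclasses add the metadata the analysis contracts depend on
(channel -> sample maps for a plex, the normalization stage of an
abundance matrix) and validate the associated invariants.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_STAGES = ("raw", "intra_norm", "inter_norm", "log2")


@dataclass
class PlexIntensitySet:
    """Raw reporter-ion intensities for one multiplexed (6-plex) run.

    ``intensities`` is protein x channel; a protein identified in the plex has
    a fully observed row (MS identification is per plex, so missingness is
    whole-row). ``channel_map`` maps channel label -> (sample_id, group).
    """

    plex_id: str
    intensities: pd.DataFrame
    channel_map: pd.DataFrame  # index: channel, columns: sample_id, group

    def __post_init__(self) -> None:
        if list(self.intensities.columns) != list(self.channel_map.index):
            raise ValueError(
                f"plex {self.plex_id}: intensity columns do not match channel map"
            )
        vals = self.intensities.to_numpy()
        if np.any(vals < 0) or not np.all(np.isfinite(vals)):
            raise ValueError(f"plex {self.plex_id}: intensities must be finite and >= 0")

    @property
    def proteins(self) -> pd.Index:
        return self.intensities.index

    @property
    def sample_ids(self) -> list[str]:
        return list(self.channel_map["sample_id"])

    def by_sample(self) -> pd.DataFrame:
        """Intensities with columns relabelled channel -> sample_id."""
        out = self.intensities.copy()
        out.columns = self.sample_ids
        return out


@dataclass
class AbundanceMatrix:
    """Feature x sample abundance matrix tagged with its normalization stage."""

    data: pd.DataFrame
    stage: str = "raw"

    def __post_init__(self) -> None:
        if self.stage not in VALID_STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {VALID_STAGES}")

    @property
    def features(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    def check_invariants(self, atol: float = 1e-9) -> None:
        if self.stage == "intra_norm":
            sums = self.data.sum(axis=1).to_numpy()
            if self.data.shape[1] and not np.allclose(sums, 1.0, atol=atol):
                raise AssertionError("intra_norm rows must sum to 1 per plex")
        elif self.stage == "inter_norm":
            means = self.data.mean(axis=1).to_numpy()
            if self.data.shape[1] and not np.allclose(means, 1.0, atol=atol):
                raise AssertionError("inter_norm rows must have mean 1")


@dataclass
class SurrogateVariables:
    """Orthonormal sample-level scores of estimated latent factors."""

    scores: pd.DataFrame  # sample x k
    eigen_share: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def k(self) -> int:
        return self.scores.shape[1]

    def __post_init__(self) -> None:
        s = self.scores.to_numpy()
        if s.shape[1]:
            gram = s.T @ s
            if not np.allclose(gram, np.eye(s.shape[1]), atol=1e-8):
                raise ValueError("surrogate-variable scores must be orthonormal")


#: Canonical column order of a differential-result table.
DE_COLUMNS = [
    "feature",
    "log2fc",
    "raw_p",
    "adj_p",
    "adj_method",
    "direction",
    "mean_abundance",
    "engine",
    "converged",
]


def make_de_table(
    features,
    log2fc,
    raw_p,
    adj_p,
    adj_method: str,
    mean_abundance,
    engine: str,
    converged=None,
) -> pd.DataFrame:
    """Assemble a differential-result table with consistent direction labels."""
    log2fc = np.asarray(log2fc, dtype=float)
    direction = np.where(log2fc > 0, "up", np.where(log2fc < 0, "down", "zero"))
    if converged is None:
        converged = np.ones(len(log2fc), dtype=bool)
    tab = pd.DataFrame(
        {
            "feature": np.asarray(features),
            "log2fc": log2fc,
            "raw_p": np.asarray(raw_p, dtype=float),
            "adj_p": np.asarray(adj_p, dtype=float),
            "adj_method": adj_method,
            "direction": direction,
            "mean_abundance": np.asarray(mean_abundance, dtype=float),
            "engine": engine,
            "converged": np.asarray(converged, dtype=bool),
        }
    )
    return tab.set_index("feature", drop=False)
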