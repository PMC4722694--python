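import numpy as np
import pandas as pd
import pytest

from protx import SimConfig, generate_cohort
from protx import simulate as sim


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A 400-gene, 2-plex cohort: fast but exercises every stage."""
    return SimConfig(
        n_genes=400, n_rna_case=12, n_rna_control=12, plex_count=2, seed=11
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    samples, truth = generate_cohort(small_config)
    counts = sim.simulate_counts(truth, samples, small_config)
    plexes = sim.simulate_tmt(truth, samples, small_config)
    id_map = sim.make_id_map(truth, small_config)
    models = sim.make_gene_models(truth, small_config)
    snps = sim.simulate_gwas_snps(models, truth, small_config)
    return {
        "config": small_config, "samples": samples, "truth": truth,
        "counts": counts, "plexes": plexes, "id_map": id_map,
        "gene_models": models, "snps": snps,
    }


@pytest.fixture
def samples24() -> pd.DataFrame:
    """A balanced 12 PD / 12 control proteomics-style sample table."""
    ids = [f"s{i:02d}" for i in range(24)]
    return pd.DataFrame(
        {"group": ["PD"] * 12 + ["control"] * 12}, index=pd.Index(ids, name="sample_id")
    )


def make_plex(plex_id: str, proteins, values, groups=None) -> "object":
    """Helper: build a PlexIntensitySet from a dense value array."""
    from protx.datatypes import PlexIntensitySet

    values = np.asarray(values, dtype=float)
    n_ch = values.shape[1]
    channels = [f"ch{126 + i}" for i in range(n_ch)]
    if groups is None:
        groups = ["PD"] * (n_ch // 2) + ["control"] * (n_ch - n_ch // 2)
    cmap = pd.DataFrame(
        {"sample_id": [f"{plex_id}_{c}" for c in channels], "group": groups},
        index=pd.Index(channels, name="channel"),
    )
    inten = pd.DataFrame(values, index=pd.Index(proteins, name="protein"), columns=channels)
    return PlexIntensitySet(plex_id, inten, cmap)
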