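"""Synthetic cohort generator with planted ground truth.

Emulates a post-mortem brain case/control study profiled on two platforms:

* RNA-Seq counts for all samples (negative-binomial, library sizes,
  covariate effects, a fraction of near-zero genes for the low-count filter);
* TMT 6-plex proteomics reporter intensities for a nested subset of samples
  (multiplicative plex batch factors, latent factors, lognormal noise), with
  protein detection following a logistic function of log mean mRNA abundance
  so that abundant transcripts are preferentially captured (detection bias);
* gene models on a toy genome, genome-wide-significant SNPs planted within
  100 kb of chosen genes plus decoys, an ID map with unmapped and
  duplicate-symbol proteins, and gene-set collections enriched for the
  planted differential genes.

Every output is a deterministic function of ``SimConfig.seed``.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .errors import ConfigError
from . import io as pio

_STREAMS = {
    "cohort": 11,
    "truth": 13,
    "counts": 17,
    "tmt": 19,
    "models": 23,
    "snps": 29,
    "sets": 31,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],)))


# Covariate ranges follow the printed cohort summary: age at death 46-97
# (control) / 64-95 (case) years, PMI 2-32 / 1-31 h, RIN 6.0-9.1 / 5.8-8.5.
_RANGES = {
    "control": {"age": (46.0, 97.0), "pmi": (2.0, 32.0), "rin": (6.0, 9.1)},
    "PD": {"age": (64.0, 95.0), "pmi": (1.0, 31.0), "rin": (5.8, 8.5)},
}

RIN_BIN_THRESHOLD = 7.0  # RIN <= 7 -> low bin


@dataclass
class SimConfig:
    """All knobs of the synthetic cohort; defaults mirror the study design."""

    n_genes: int = 20_000
    n_rna_case: int = 29
    n_rna_control: int = 44
    plex_count: int = 4
    channels_per_plex: int = 6  # 3 case / 3 control per plex
    frac_de_rna: float = 0.06
    frac_de_protein: float = 0.08
    frac_low: float = 0.135  # near-zero genes exercising the low-count filter
    effect_rho: float = 0.6  # corr(protein effect, mRNA effect) on log2 scale
    effect_sd: float = 1.0  # SD of nonzero planted log2 fold changes
    detection_bias_slope: float = 1.0
    detection_intercept: float = -1.386  # logit(0.2): ~20% of genes detected
    batch_sd: float = 0.5  # per-plex multiplicative batch, log2 units
    latent_sd: float = 0.3  # latent-factor contribution, log2 units
    n_latent: int = 3
    noise_sd: float = 0.25  # channel-level lognormal noise, log2 units
    dispersion_meanlog: float = -2.5  # lognormal NB dispersions
    dispersion_sdlog: float = 0.6
    age_effect_sd: float = 0.02  # per-gene coefficient SD on standardized age
    pmi_effect_sd: float = 0.02
    rin_effect_sd: float = 0.05  # on the RIN bin indicator
    base_log2_mean: float = 5.0  # log2 mean-count distribution of expressed genes
    base_log2_sd: float = 2.0
    libsize_sd: float = 0.25  # log2 SD of sample library-size factors
    n_snp_linked: int = 20
    n_decoy_snps: int = 200
    n_gene_sets: int = 50
    n_unmapped_proteins: int = 4
    n_duplicate_symbols: int = 35
    seed: int = 0

    def validate(self) -> None:
        def positive(name):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive, got {getattr(self, name)}")

        for name in ("n_genes", "plex_count", "channels_per_plex",
                     "n_rna_case", "n_rna_control"):
            positive(name)
        for name in ("frac_de_rna", "frac_de_protein", "frac_low"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if not -1.0 <= self.effect_rho <= 1.0:
            raise ConfigError(f"effect_rho must lie in [-1, 1], got {self.effect_rho}")
        for name in ("batch_sd", "latent_sd", "noise_sd", "effect_sd",
                     "libsize_sd", "age_effect_sd", "pmi_effect_sd", "rin_effect_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.channels_per_plex % 2 != 0:
            raise ConfigError("channels_per_plex must be even (balanced case/control)")
        half = self.plex_count * self.channels_per_plex // 2
        if self.n_rna_case < half or self.n_rna_control < half:
            raise ConfigError(
                "n_rna_case/n_rna_control must cover the proteomics subset "
                f"({half} per group)"
            )
        if self.n_latent < 0:
            raise ConfigError(f"n_latent must be >= 0, got {self.n_latent}")

    @property
    def n_prot_per_group(self) -> int:
        return self.plex_count * self.channels_per_plex // 2

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Planted per-gene truth plus the nuisance structure used to generate data."""

    genes: pd.DataFrame  # per-gene: effects, detection, base abundance, flags
    plex_batch_log2: np.ndarray  # (plex_count,)
    latent_loadings: np.ndarray  # (n_genes, n_latent)
    latent_scores: np.ndarray  # (n_prot_samples, n_latent)
    dispersion: np.ndarray  # (n_genes,) NB dispersion alpha
    covariate_coefs: pd.DataFrame  # per-gene coefficients (age, pmi, rin_bin)

    @property
    def symbols(self) -> pd.Index:
        return self.genes.index


def _gene_symbols(n: int) -> pd.Index:
    width = max(5, len(str(n)))
    return pd.Index([f"G{i:0{width}d}" for i in range(1, n + 1)], name="symbol")


def generate_cohort(config: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw sample metadata and per-gene ground truth.

    Returns a sample table (rows = RNA samples; the proteomics subset is the
    ``plex_count * channels_per_plex`` samples with lowest PMI per group,
    mirroring a design where proteomics samples are nested in the RNA cohort)
    and the :class:`GroundTruth` that the simulators consume.
    """
    config.validate()
    rng = _rng(config.seed, "cohort")

    rows = []
    for group, n in (("control", config.n_rna_control), ("PD", config.n_rna_case)):
        rg = _RANGES[group]
        for i in range(n):
            rows.append(
                {
                    "sample_id": f"{'C' if group == 'control' else 'P'}{i + 1:03d}",
                    "group": group,
                    "age": rng.uniform(*rg["age"]),
                    "pmi": rng.uniform(*rg["pmi"]),
                    "rin": rng.uniform(*rg["rin"]),
                }
            )
    samples = pd.DataFrame(rows).set_index("sample_id", drop=False)
    samples["rin_bin"] = (samples["rin"] > RIN_BIN_THRESHOLD).astype(int)

    # proteomics subset: lowest-PMI samples per group, balanced across plexes
    half = config.n_prot_per_group
    samples["in_proteomics"] = False
    samples["plex"] = ""
    samples["channel"] = ""
    per_plex = config.channels_per_plex // 2
    for group in ("control", "PD"):
        chosen = samples[samples.group == group].nsmallest(half, "pmi").index
        samples.loc[chosen, "in_proteomics"] = True
        for j, sid in enumerate(chosen):
            samples.loc[sid, "plex"] = f"plex{j // per_plex + 1}"
    for plex, sub in samples[samples.in_proteomics].groupby("plex"):
        for ch, sid in enumerate(sub.index):
            samples.loc[sid, "channel"] = f"ch{126 + ch}"

    truth = _generate_truth(config, samples)
    return samples, truth


def _generate_truth(config: SimConfig, samples: pd.DataFrame) -> GroundTruth:
    rng = _rng(config.seed, "truth")
    n = config.n_genes
    symbols = _gene_symbols(n)

    n_low = int(round(config.frac_low * n))
    is_low = np.zeros(n, dtype=bool)
    is_low[rng.choice(n, size=n_low, replace=False)] = True

    base_log2 = rng.normal(config.base_log2_mean, config.base_log2_sd, size=n)
    base_log2[is_low] = np.log2(0.02)  # near-zero: all-zero in most samples

    # correlated planted effects; zeroed outside the chosen DE sets
    cov = config.effect_sd ** 2 * np.array(
        [[1.0, config.effect_rho], [config.effect_rho, 1.0]]
    )
    eff = rng.multivariate_normal([0.0, 0.0], cov, size=n)
    expressed = np.flatnonzero(~is_low)
    n_de_rna = int(round(config.frac_de_rna * n))
    n_de_prot = int(round(config.frac_de_protein * n))
    if max(n_de_rna, n_de_prot) > expressed.size:
        raise ConfigError("frac_de_rna/frac_de_protein exceed the expressed gene count")
    de_rna = rng.choice(expressed, size=n_de_rna, replace=False)
    de_prot = rng.choice(expressed, size=n_de_prot, replace=False)
    lfc_rna = np.zeros(n)
    lfc_prot = np.zeros(n)
    lfc_rna[de_rna] = eff[de_rna, 0]
    lfc_prot[de_prot] = eff[de_prot, 1]
    # guard against effects drawn exactly zero (the DE count is exact)
    for arr, idx in ((lfc_rna, de_rna), (lfc_prot, de_prot)):
        zero = idx[arr[idx] == 0.0]
        arr[zero] = config.effect_sd

    # detection probability: logistic in standardized log mean mRNA abundance
    z = (base_log2 - base_log2[expressed].mean()) / max(base_log2[expressed].std(), 1e-12)
    logit = config.detection_intercept + config.detection_bias_slope * z
    detected = rng.uniform(size=n) < 1.0 / (1.0 + np.exp(-logit))
    detected[is_low] = False

    snp_linked = np.zeros(n, dtype=bool)
    n_linked = min(config.n_snp_linked, expressed.size)
    snp_linked[rng.choice(expressed, size=n_linked, replace=False)] = True

    genes = pd.DataFrame(
        {
            "true_log2fc_rna": lfc_rna,
            "true_log2fc_protein": lfc_prot,
            "is_detected_protein": detected,
            "is_low": is_low,
            "base_log2_mrna": base_log2,
            "snp_linked": snp_linked,
        },
        index=symbols,
    )

    n_prot = 2 * config.n_prot_per_group
    loadings = rng.normal(0.0, config.latent_sd, size=(n, config.n_latent))
    scores = rng.normal(0.0, 1.0, size=(n_prot, config.n_latent))
    batch = rng.normal(0.0, config.batch_sd, size=config.plex_count)
    dispersion = np.exp(
        rng.normal(config.dispersion_meanlog, config.dispersion_sdlog, size=n)
    )
    cov_coefs = pd.DataFrame(
        {
            "age": rng.normal(0.0, config.age_effect_sd, size=n),
            "pmi": rng.normal(0.0, config.pmi_effect_sd, size=n),
            "rin_bin": rng.normal(0.0, config.rin_effect_sd, size=n),
        },
        index=symbols,
    )
    return GroundTruth(genes, batch, loadings, scores, dispersion, cov_coefs)


def simulate_counts(
    truth: GroundTruth, samples: pd.DataFrame, config: SimConfig
) -> pd.DataFrame:
    """RNA-Seq count matrix: gene x sample negative-binomial draws.

    Mean model: ``s_j * mu_g * 2^(group_j * lfc_g + x_j' beta_g)`` with
    library-size factors ``s_j`` and per-gene covariate coefficients on
    standardized age/PMI and the RIN bin; gene dispersions are the configured
    lognormal draws (Poisson in the dispersion -> 0 limit).
    """
    if len(truth.genes) != config.n_genes:
        raise ConfigError("truth and config disagree on n_genes")
    rng = _rng(config.seed, "counts")
    n_s = len(samples)
    group = (samples["group"] == "PD").to_numpy(dtype=float)
    age_z = _standardize(samples["age"].to_numpy())
    pmi_z = _standardize(samples["pmi"].to_numpy())
    rin_b = samples["rin_bin"].to_numpy(dtype=float)

    libsize = 2.0 ** rng.normal(0.0, config.libsize_sd, size=n_s)
    libsize /= np.exp(np.mean(np.log(libsize)))

    mu0 = 2.0 ** truth.genes["base_log2_mrna"].to_numpy()
    eta = (
        np.outer(truth.genes["true_log2fc_rna"].to_numpy(), group)
        + np.outer(truth.covariate_coefs["age"].to_numpy(), age_z)
        + np.outer(truth.covariate_coefs["pmi"].to_numpy(), pmi_z)
        + np.outer(truth.covariate_coefs["rin_bin"].to_numpy(), rin_b)
    )
    mean = mu0[:, None] * (2.0 ** eta) * libsize[None, :]
    if not np.all(np.isfinite(mean)):
        raise ConfigError("non-finite count means; check effect sizes")

    counts = np.empty(mean.shape, dtype=np.int64)
    # gamma-Poisson mixture; near-zero dispersion falls back to pure Poisson
    small = truth.dispersion < 1e-8
    if small.any():
        counts[small] = rng.poisson(mean[small])
    big = ~small
    if big.any():
        shape = 1.0 / truth.dispersion[big][:, None]
        lam = rng.gamma(shape, mean[big] / shape)
        counts[big] = rng.poisson(lam)
    return pd.DataFrame(counts, index=truth.symbols, columns=samples.index)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def simulate_tmt(
    truth: GroundTruth, samples: pd.DataFrame, config: SimConfig
):
    """Per-plex reporter-ion intensity sets for the proteomics subset.

    log2 intensity = base + plex batch + group effect + latent loadings·scores
    + N(0, noise_sd); proteins for undetected genes are absent from every plex.
    The ID space is proteins (``P_<symbol>``), with configured duplicate-symbol
    proteins (second independent measurement of the same gene) and unmapped
    proteins that the ID map will not cover.
    """
    from .datatypes import PlexIntensitySet

    rng = _rng(config.seed, "tmt")
    prot_samples = samples[samples.in_proteomics].copy()
    prot_samples = prot_samples.sort_values(["plex", "channel"])
    n_prot = len(prot_samples)
    if n_prot != 2 * config.n_prot_per_group:
        raise ConfigError("proteomics subset size mismatch")

    det = truth.genes[truth.genes.is_detected_protein]
    det_symbols = list(det.index)
    dup_pool = det_symbols[: config.n_duplicate_symbols]
    protein_ids = [f"P_{s}" for s in det_symbols]
    dup_ids = [f"P_{s}.2" for s in dup_pool]
    unk_ids = [f"P_UNK{i + 1}" for i in range(config.n_unmapped_proteins)]
    all_ids = protein_ids + dup_ids + unk_ids
    sym_of = det_symbols + dup_pool + [None] * len(unk_ids)

    base = rng.normal(10.0, 2.0, size=len(all_ids))
    group = (prot_samples["group"] == "PD").to_numpy(dtype=float)
    lfc = np.zeros(len(all_ids))
    load = np.zeros((len(all_ids), config.n_latent))
    for i, sym in enumerate(sym_of):
        if sym is not None:
            lfc[i] = truth.genes.loc[sym, "true_log2fc_protein"]
            load[i] = truth.latent_loadings[truth.symbols.get_loc(sym)]
        else:
            load[i] = rng.normal(0.0, config.latent_sd, size=config.n_latent)

    scores = truth.latent_scores  # ordered as prot_samples
    log2 = (
        base[:, None]
        + np.outer(lfc, group)
        + load @ scores.T
        + rng.normal(0.0, config.noise_sd, size=(len(all_ids), n_prot))
    )

    plexes = []
    plex_ids = sorted(prot_samples["plex"].unique())
    for pi, plex_id in enumerate(plex_ids):
        cols = prot_samples[prot_samples.plex == plex_id]
        idx = [prot_samples.index.get_loc(s) for s in cols.index]
        vals = 2.0 ** (log2[:, idx] + truth.plex_batch_log2[pi])
        inten = pd.DataFrame(vals, index=pd.Index(all_ids, name="protein"),
                             columns=list(cols["channel"]))
        cmap = pd.DataFrame(
            {"sample_id": cols["sample_id"].to_numpy(), "group": cols["group"].to_numpy()},
            index=pd.Index(cols["channel"], name="channel"),
        )
        plexes.append(PlexIntensitySet(plex_id, inten, cmap))
    return plexes


def make_id_map(truth: GroundTruth, config: SimConfig) -> pd.DataFrame:
    """Protein-ID -> gene-symbol map covering all but the unmapped proteins."""
    det_symbols = list(truth.genes.index[truth.genes.is_detected_protein])
    dup_pool = det_symbols[: config.n_duplicate_symbols]
    rows = [{"protein_id": f"P_{s}", "symbol": s} for s in det_symbols]
    rows += [{"protein_id": f"P_{s}.2", "symbol": s} for s in dup_pool]
    return pd.DataFrame(rows)


def make_gene_models(truth: GroundTruth, config: SimConfig) -> pd.DataFrame:
    """Lay genes along toy chromosomes, 1-based inclusive coordinates.

    Inter-gene gaps exceed 2x the 100 kb SNP window so decoy SNPs placed in
    gap centers are unambiguously outside every window.
    """
    rng = _rng(config.seed, "models")
    n = len(truth.genes)
    chrom_count = 22
    per_chrom = -(-n // chrom_count)
    rows = []
    gi = 0
    for c in range(1, chrom_count + 1):
        pos = 1
        for _ in range(per_chrom):
            if gi >= n:
                break
            gap = int(rng.integers(250_000, 1_000_000))
            length = int(rng.integers(2_000, 200_000))
            start = pos + gap
            rows.append(
                {
                    "chrom": f"chr{c}",
                    "start": start,
                    "end": start + length - 1,
                    "strand": "+" if rng.uniform() < 0.5 else "-",
                    "symbol": truth.genes.index[gi],
                }
            )
            pos = start + length
            gi += 1
    return pd.DataFrame(rows)


def simulate_gwas_snps(
    gene_models: pd.DataFrame, truth: GroundTruth, config: SimConfig
) -> pd.DataFrame:
    """SNP association table with planted genome-wide-significant hits.

    Each snp_linked gene receives 1-4 SNPs with p < 5e-8 inside
    [start - 100 kb, end + 100 kb] (some inside the gene body, some flanking);
    decoys are either sub-threshold SNPs anywhere or significant SNPs placed
    in gap centers, > 100 kb from every gene.
    """
    rng = _rng(config.seed, "snps")
    models = gene_models.set_index("symbol")
    rows = []
    rsid = 10_000
    window = 100_000
    linked = truth.genes.index[truth.genes.snp_linked]
    for sym in linked:
        if sym not in models.index:
            continue
        g = models.loc[sym]
        n_snp = int(rng.integers(1, 5))
        for _ in range(n_snp):
            u = rng.uniform()
            if u < 0.5:  # inside the gene body
                pos = int(rng.integers(g.start, g.end + 1))
            elif u < 0.75:  # upstream flank
                pos = int(rng.integers(max(1, g.start - window), g.start))
            else:  # downstream flank
                pos = int(rng.integers(g.end + 1, g.end + window + 1))
            rsid += 1
            name = f"rs{rsid}" if rng.uniform() > 0.05 else "No rs# available"
            rows.append(
                {"chrom": g.chrom, "pos": pos, "rsid": name,
                 "p": 10.0 ** -rng.uniform(8.5, 30.0)}
            )
    # decoys: sub-threshold anywhere near genes
    n_half = config.n_decoy_snps // 2
    model_rows = gene_models.sample(
        n=min(n_half, len(gene_models)), random_state=int(rng.integers(2**31)),
        replace=True,
    )
    for _, g in model_rows.iterrows():
        rsid += 1
        rows.append(
            {"chrom": g.chrom, "pos": int(rng.integers(g.start, g.end + 1)),
             "rsid": f"rs{rsid}", "p": 10.0 ** -rng.uniform(0.0, 7.25)}
        )
    # decoys: significant but far (>100 kb) from every gene — gap midpoints
    by_chrom = gene_models.sort_values(["chrom", "start"]).groupby("chrom")
    gaps = []
    for chrom, sub in by_chrom:
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        for i in range(len(sub) - 1):
            mid = (ends[i] + starts[i + 1]) // 2
            if mid - ends[i] > window + 1_000 and starts[i + 1] - mid > window + 1_000:
                gaps.append((chrom, int(mid)))
    if gaps:
        pick = rng.choice(len(gaps), size=min(config.n_decoy_snps - n_half, len(gaps)),
                          replace=False)
        for j in pick:
            chrom, mid = gaps[j]
            rsid += 1
            rows.append({"chrom": chrom, "pos": mid, "rsid": f"rs{rsid}",
                         "p": 10.0 ** -rng.uniform(8.5, 30.0)})
    return pd.DataFrame(rows, columns=["chrom", "pos", "rsid", "p"])


def make_gene_sets(truth: GroundTruth, config: SimConfig) -> dict:
    """GMT-style collection; a handful of sets are enriched in planted DE genes."""
    rng = _rng(config.seed, "sets")
    symbols = np.asarray(truth.genes.index)
    de = np.asarray(truth.genes.index[truth.genes.true_log2fc_rna != 0])
    sets = {}
    n_enriched = min(5, config.n_gene_sets)
    for i in range(config.n_gene_sets):
        size = int(rng.integers(10, 101))
        if i < n_enriched and de.size >= size // 2:
            k = size // 2
            members = np.concatenate(
                [rng.choice(de, size=k, replace=False),
                 rng.choice(symbols, size=size - k, replace=False)]
            )
        else:
            members = rng.choice(symbols, size=size, replace=False)
        members = list(dict.fromkeys(members.tolist()))
        sets[f"SET_{i + 1:03d}"] = ("synthetic gene set", members)
    return sets


def write_cohort(outdir, config: SimConfig) -> dict:
    """Generate the full cohort and write every artifact as plain text.

    Returns a dict of the in-memory objects for direct pipeline use.
    """
    outdir = pio.ensure_dir(outdir)
    samples, truth = generate_cohort(config)
    counts = simulate_counts(truth, samples, config)
    plexes = simulate_tmt(truth, samples, config)
    id_map = make_id_map(truth, config)
    models = make_gene_models(truth, config)
    snps = simulate_gwas_snps(models, truth, config)
    sets = make_gene_sets(truth, config)

    samples.drop(columns="sample_id").to_csv(outdir / "samples.tsv", sep="\t")
    pio.write_matrix(counts, outdir / "counts.tsv", "gene")
    pio.write_plexes(plexes, outdir)
    pio.write_id_map(id_map, outdir / "id_map.tsv")
    pio.write_gene_models(models, outdir / "gene_models.tsv")
    pio.write_snps(snps, outdir / "snps.tsv")
    pio.write_gmt(sets, outdir / "gene_sets.gmt")
    truth.genes.to_csv(outdir / "ground_truth.tsv", sep="\t")
    return {
        "samples": samples, "truth": truth, "counts": counts, "plexes": plexes,
        "id_map": id_map, "gene_models": models, "snps": snps, "gene_sets": sets,
    }
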