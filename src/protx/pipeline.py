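"""End-to-end orchestration: simulate/ingest -> prep -> SVs -> DE -> enrichment
-> integration -> GWAS mapping, from a single validated configuration."""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import de, enrich, gwas, integrate, io as pio, proteomics, simulate, sva
from .errors import ConfigError

log = logging.getLogger("protx")

DEFAULT_TIERS = [25, 50, 100, 350, 600, 850]


@dataclass
class RunConfig:
    """Pipeline run configuration (simulation-driven or from input files)."""

    outdir: str = "protx_run"
    seed: int = 0
    simulate: dict | None = field(default_factory=dict)  # SimConfig overrides
    inputs: dict | None = None  # dir with pre-generated cohort files
    alpha_corrected: float = 0.05
    alpha_nominal: float = 0.05
    gwas_p: float = gwas.GENOME_WIDE_P
    window: int = gwas.DEFAULT_WINDOW
    tiers: list = field(default_factory=lambda: list(DEFAULT_TIERS))
    n_sv: str | int = "auto"
    sv_permutations: int = 100

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for name in ("alpha_corrected", "alpha_nominal", "gwas_p"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigError(f"{name} must lie in (0, 1), got {v}")
        if self.window <= 0:
            raise ConfigError(f"window must be positive, got {self.window}")
        if self.inputs is not None:
            for key, path in self.inputs.items():
                if not Path(path).exists():
                    raise ConfigError(f"inputs.{key}: path {path} does not exist")
        if self.inputs is None and self.simulate is None:
            raise ConfigError("either 'simulate' or 'inputs' must be given")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class _StageTimer:
    def __init__(self) -> None:
        self.timings: dict[str, float] = {}

    def run(self, name: str, fn, *args, **kwargs):
        log.info("stage %s: start", name)
        t0 = time.perf_counter()
        try:
            result = fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        self.timings[name] = round(time.perf_counter() - t0, 3)
        log.info("stage %s: done in %.2fs", name, self.timings[name])
        return result


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage, write intermediates, return the run manifest."""
    config.validate()
    outdir = pio.ensure_dir(config.outdir)
    timer = _StageTimer()
    manifest: dict = {"seed": config.seed, "config": {
        k: v for k, v in asdict(config).items() if k != "simulate"
    }}

    # ------------------------------------------------------------------ inputs
    if config.inputs is not None:
        cohort = timer.run("load", _load_inputs, config.inputs)
        truth = None
    else:
        sim_cfg = simulate.SimConfig(**{**(config.simulate or {}), "seed": config.seed})
        cohort = timer.run("simulate", simulate.write_cohort, outdir / "cohort", sim_cfg)
        truth = cohort["truth"]
        manifest["sim_config"] = sim_cfg.to_dict()

    samples = cohort["samples"]
    counts = cohort["counts"]

    # -------------------------------------------------------------- proteomics
    inter, prot_log2 = timer.run(
        "prep_proteomics", proteomics.prep_proteomics, cohort["plexes"], cohort["id_map"]
    )
    pio.write_abundance(inter, outdir / "protein_abundance.tsv")

    prot_samples = samples[samples.in_proteomics]
    prot_design0 = de.design_matrix(prot_samples.loc[prot_log2.samples])
    if config.n_sv == "auto":
        k = timer.run(
            "estimate_num_sv", sva.estimate_num_sv, prot_log2, prot_design0,
            config.sv_permutations, 0.95, config.seed,
        )
    else:
        k = int(config.n_sv)
    svs = timer.run("estimate_svs", sva.estimate_svs, prot_log2, prot_design0, k)
    svs.scores.to_csv(outdir / "sv_scores.tsv", sep="\t")

    prot_design = de.design_matrix(prot_samples.loc[prot_log2.samples], svs=svs.scores)
    de_protein = timer.run(
        "de_protein", de.fit_moderated_lm, prot_log2, prot_design, "group", "qvalue"
    )
    de_protein.drop(columns="feature").to_csv(outdir / "de_protein.tsv", sep="\t")

    # --------------------------------------------------------------------- RNA
    filtered = timer.run("low_count_filter", de.low_count_filter, counts, samples["group"])
    rna_design = de.design_matrix(samples, covariates=("age", "pmi", "rin_bin"))
    de_rna = timer.run("de_rna", de.fit_nb_glm, filtered, rna_design, "group", "bh")
    de_rna.drop(columns="feature").to_csv(outdir / "de_rna.tsv", sep="\t")

    # -------------------------------------------------------------- enrichment
    ranked = de_rna[de_rna["adj_p"] < config.alpha_corrected].sort_values("raw_p")
    enr = timer.run(
        "enrichment", enrich.tiered_fisher, list(ranked.index),
        set(de_rna.index), cohort["gene_sets"],
        config.tiers + [len(ranked)] if len(ranked) else None,
    )
    enr.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)

    # -------------------------------------------------------------- integration
    report = timer.run(
        "integration", integrate.overlap_summary, de_rna, de_protein,
        config.alpha_corrected, config.alpha_nominal,
    )
    sf = de.size_factors(filtered)
    rna_norm = filtered / sf
    prot_cols = [s for s in prot_log2.samples if s in rna_norm.columns]
    rna_log2 = np.log2(rna_norm[prot_cols] + 1.0)
    per_gene_r = integrate.per_gene_abundance_correlation(prot_log2.data, rna_log2)
    ev = integrate.classify_evidence(de_rna, de_protein,
                                     config.alpha_corrected, config.alpha_nominal)
    and_genes = ev.index[ev["class"] == "AND"]
    abs_corr_test = None
    if len(and_genes) >= 2 and per_gene_r.notna().sum() >= 4:
        t, p = integrate.compare_abs_correlations(
            per_gene_r.dropna(), per_gene_r.loc[per_gene_r.index.intersection(and_genes)].dropna()
        )
        abs_corr_test = {"t": t, "p": p, "n_and": int(len(and_genes))}
    bias = integrate.detected_vs_undetected_abundance(rna_norm[prot_cols], set(prot_log2.features))
    with open(outdir / "concordance.json", "w") as fh:
        json.dump({"overlap": report.to_dict(), "abs_corr_test": abs_corr_test,
                   "detected_vs_undetected": bias}, fh, indent=2, default=float)

    # --------------------------------------------------------------------- GWAS
    hits = timer.run(
        "gwas_map", gwas.genes_near_snps, cohort["snps"], cohort["gene_models"],
        config.window, config.gwas_p,
    )
    hits = gwas.join_de_evidence(hits, de_protein, de_rna,
                                 config.alpha_corrected, config.alpha_corrected)
    hits.to_csv(outdir / "gwas_hits.tsv", sep="\t", index=False)

    # ----------------------------------------------------------------- manifest
    headline = {
        "n_rna_samples": int(len(samples)),
        "n_prot_samples": int(samples.in_proteomics.sum()),
        "n_proteins_common": int(len(prot_log2.features)),
        "k_sv": int(k),
        "n_genes_filtered": int(len(filtered)),
        "n_sig_protein": int((de_protein["adj_p"] < config.alpha_corrected).sum()),
        "n_sig_rna": int((de_rna["adj_p"] < config.alpha_corrected).sum()),
        "n_sig_both": report.n_sig_both,
        "n_and_evidence": report.n_and_evidence,
        "n_or_evidence": report.n_or_evidence,
        "n_gwas_genes": int(len(hits)),
        "n_gwas_evidence_genes": int((hits["de_evidence"] != "none").sum()),
        "detection_bias_chi2": report.contingency.get("chi2"),
        "foldchange_spearman_r": report.foldchange_corr.get("r"),
    }
    if truth is not None:
        headline.update(_recovery_stats(truth, de_rna, de_protein))
    manifest["headline"] = headline
    manifest["timings"] = timer.timings
    manifest["files"] = {
        p.name: _sha256(p) for p in sorted(outdir.glob("*.tsv"))
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
    return manifest


def _recovery_stats(truth, de_rna: pd.DataFrame, de_protein: pd.DataFrame) -> dict:
    """Planted-truth recovery diagnostics for simulated runs."""
    from scipy import stats as sstats

    out = {}
    g = truth.genes
    de_true = g.index[g["true_log2fc_rna"] != 0].intersection(de_rna.index)
    if len(de_true) >= 3:
        rho = sstats.spearmanr(
            g.loc[de_true, "true_log2fc_rna"], de_rna.loc[de_true, "log2fc"]
        )[0]
        out["rna_recovery_spearman"] = float(rho)
    de_true_p = g.index[g["true_log2fc_protein"] != 0].intersection(de_protein.index)
    if len(de_true_p) >= 3:
        rho = sstats.spearmanr(
            g.loc[de_true_p, "true_log2fc_protein"], de_protein.loc[de_true_p, "log2fc"]
        )[0]
        out["protein_recovery_spearman"] = float(rho)
    return out


def _load_inputs(paths: dict) -> dict:
    """Load a cohort from the file layout written by ``simulate.write_cohort``."""
    indir = Path(paths["dir"]) if "dir" in paths else None
    if indir is None:
        raise ConfigError("inputs.dir is required")
    samples = pd.read_csv(indir / "samples.tsv", sep="\t", index_col=0)
    samples["sample_id"] = samples.index
    samples["plex"] = samples["plex"].fillna("")
    samples["channel"] = samples["channel"].fillna("")
    return {
        "samples": samples,
        "counts": pio.read_matrix(indir / "counts.tsv"),
        "plexes": pio.read_plexes(indir),
        "id_map": pio.read_id_map(indir / "id_map.tsv"),
        "gene_models": pio.read_gene_models(indir / "gene_models.tsv"),
        "snps": pio.read_snps(indir / "snps.tsv"),
        "gene_sets": pio.read_gmt(indir / "gene_sets.gmt"),
        "truth": None,
    }
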