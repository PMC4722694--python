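"""Readers and writers for the plain-text formats the pipeline exchanges.

Everything is TSV (pandas), GMT (one set per line: name, description,
members) or a BED-like 1-based inclusive gene-model table.
"""
from __future__ import annotations

import os
from pathlib import Path

import pandas as pd

from .datatypes import AbundanceMatrix, PlexIntensitySet
from .errors import ParseError

GENE_MODEL_COLUMNS = ["chrom", "start", "end", "strand", "symbol"]
SNP_COLUMNS = ["chrom", "pos", "rsid", "p"]


def write_matrix(df: pd.DataFrame, path, label: str = "feature") -> None:
    df.to_csv(path, sep="\t", index_label=label)


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_abundance(matrix: AbundanceMatrix, path) -> None:
    """Write a matrix with a ``# stage: <stage>`` header line."""
    with open(path, "w") as fh:
        fh.write(f"# stage: {matrix.stage}\n")
        matrix.data.to_csv(fh, sep="\t", index_label="feature")


def read_abundance(path) -> AbundanceMatrix:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# stage:"):
            raise ParseError(f"{path}:1: missing '# stage:' header")
        stage = first.split(":", 1)[1].strip()
        data = pd.read_csv(fh, sep="\t", index_col=0)
    return AbundanceMatrix(data=data, stage=stage)


def write_plexes(plexes: list[PlexIntensitySet], outdir) -> None:
    """One intensity TSV per plex plus a shared design sheet."""
    outdir = Path(outdir)
    design_rows = []
    for plex in plexes:
        write_matrix(plex.intensities, outdir / f"intensities_{plex.plex_id}.tsv", "protein")
        for channel, row in plex.channel_map.iterrows():
            design_rows.append(
                {"plex": plex.plex_id, "channel": channel,
                 "sample_id": row["sample_id"], "group": row["group"]}
            )
    pd.DataFrame(design_rows).to_csv(outdir / "plex_design.tsv", sep="\t", index=False)


def read_plexes(indir) -> list[PlexIntensitySet]:
    indir = Path(indir)
    design = pd.read_csv(indir / "plex_design.tsv", sep="\t")
    plexes = []
    for plex_id, sub in design.groupby("plex", sort=True):
        cmap = sub.set_index("channel")[["sample_id", "group"]]
        inten = read_matrix(indir / f"intensities_{plex_id}.tsv")
        plexes.append(PlexIntensitySet(str(plex_id), inten[cmap.index], cmap))
    return plexes


def read_id_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    expected = {"protein_id", "symbol"}
    if not expected.issubset(df.columns):
        raise ParseError(f"{path}: id map needs columns {sorted(expected)}")
    return df


def write_id_map(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_gene_models(path) -> pd.DataFrame:
    """BED-like TSV, 1-based inclusive: chrom, start, end, strand, symbol."""
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in GENE_MODEL_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}:1: missing columns {missing}")
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if not (0 < row.start <= row.end):
            raise ParseError(f"{path}:{i}: invalid interval [{row.start}, {row.end}]")
    return df


def write_gene_models(df: pd.DataFrame, path) -> None:
    df[GENE_MODEL_COLUMNS].to_csv(path, sep="\t", index=False)


def read_snps(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in SNP_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}:1: missing columns {missing}")
    return df


def write_snps(df: pd.DataFrame, path) -> None:
    df[SNP_COLUMNS].to_csv(path, sep="\t", index=False)


def read_gmt(path) -> dict[str, tuple[str, list[str]]]:
    """Parse GMT: name <tab> description <tab> member1 <tab> member2 ..."""
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            name, desc, members = parts[0], parts[1], [m for m in parts[2:] if m]
            if not members:
                raise ParseError(f"{path}:{lineno}: gene set {name!r} is empty")
            sets[name] = (desc, list(dict.fromkeys(members)))
    return sets


def write_gmt(sets: dict[str, tuple[str, list[str]]], path) -> None:
    with open(path, "w") as fh:
        for name, (desc, members) in sets.items():
            fh.write("\t".join([name, desc, *members]) + "\n")


def ensure_dir(path) -> Path:
    path = Path(path)
    os.makedirs(path, exist_ok=True)
    return path
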