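"""Readers and writers for the pipeline's plain-text interchange formats.

All genomic intervals are 0-based half-open BED. Genes travel as BED12 (one
row per gene, blocks = exons); per-sample peak calls as 4-column BED with the
bin id in the name field plus a samples.tsv manifest (sample_id, study_id,
path); binding sites as 6-column BED with the RBP in the name field; regions
as BED with stratum and gene columns; expression as entity x tissue TSV; the
synthetic truth as a JSON sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    ExpressionTable,
    GeneModel,
    GenomicBin,
    InputError,
    PeakCallMatrix,
)
from .enrichment import SITE_COLUMNS


# ---------------------------------------------------------------- genes

def write_genes_bed12(genes: Sequence[GeneModel], path: str | Path) -> None:
    rows = []
    for g in genes:
        starts, ends = zip(*g.exons)
        span_start, span_end = g.span
        rows.append(
            [
                g.chrom, span_start, span_end, g.gene_id, 0, g.strand,
                span_start, span_end, "0,0,0", len(g.exons),
                ",".join(str(e - s) for s, e in g.exons) + ",",
                ",".join(str(s - span_start) for s in starts) + ",",
            ]
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_genes_bed12(path: str | Path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 12:
        raise InputError(f"{path}: expected BED12 (12 columns), got {df.shape[1]}")
    genes = []
    for row in df.itertuples(index=False):
        chrom, chrom_start, name, strand = row[0], int(row[1]), str(row[3]), str(row[5])
        sizes = [int(x) for x in str(row[10]).rstrip(",").split(",")]
        starts = [int(x) for x in str(row[11]).rstrip(",").split(",")]
        if len(sizes) != len(starts):
            raise InputError(f"{path}: blockSizes/blockStarts mismatch for {name}")
        exons = tuple(
            (chrom_start + s, chrom_start + s + L) for s, L in zip(starts, sizes)
        )
        genes.append(GeneModel(gene_id=name, chrom=chrom, strand=strand, exons=exons))
    return genes


# ---------------------------------------------------------------- peak calls

def write_peak_calls(pcm: PeakCallMatrix, outdir: str | Path) -> Path:
    """One BED file per sample (called bins only) plus samples.tsv; returns
    the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for j, sample in enumerate(pcm.samples):
        rel = f"calls_{sample}.bed"
        rows = [
            [b.chrom, b.start, b.end, b.bin_id]
            for b, c in zip(pcm.bins, pcm.calls[:, j])
            if c
        ]
        pd.DataFrame(rows).to_csv(outdir / rel, sep="\t", header=False, index=False)
        manifest.append({"sample_id": sample, "study_id": pcm.study_of[sample], "path": rel})
    mpath = outdir / "samples.tsv"
    pd.DataFrame(manifest).to_csv(mpath, sep="\t", index=False)
    return mpath


def read_peak_calls(samples_tsv: str | Path, bins: Sequence[GenomicBin]) -> PeakCallMatrix:
    """Rebuild the call matrix over a known bin set from per-sample BEDs."""
    samples_tsv = Path(samples_tsv)
    mf = pd.read_csv(samples_tsv, sep="\t")
    for col in ("sample_id", "study_id", "path"):
        if col not in mf.columns:
            raise InputError(f"{samples_tsv}: samples manifest missing column {col!r}")
    bin_idx = {b.bin_id: i for i, b in enumerate(bins)}
    calls = np.zeros((len(bins), len(mf)), dtype=np.int8)
    for j, row in enumerate(mf.itertuples(index=False)):
        p = samples_tsv.parent / row.path
        try:
            bed = pd.read_csv(p, sep="\t", header=None)
        except pd.errors.EmptyDataError:
            continue
        for name in bed[3]:
            i = bin_idx.get(str(name))
            if i is None:
                raise InputError(f"{p}: call names unknown bin {name!r}")
            calls[i, j] = 1
    return PeakCallMatrix(
        bins=list(bins),
        samples=mf["sample_id"].tolist(),
        study_of=dict(zip(mf["sample_id"], mf["study_id"])),
        calls=calls,
    )


# ---------------------------------------------------------------- sites

def write_sites_bed(sites: pd.DataFrame, path: str | Path) -> None:
    sites[SITE_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_sites_bed(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=SITE_COLUMNS)
    if df.shape[1] < 4:
        raise InputError(f"{path}: expected >= 4 BED columns, got {df.shape[1]}")
    df = df.iloc[:, :6]
    while df.shape[1] < 6:
        df[df.shape[1]] = "." if df.shape[1] == 5 else 0
    df.columns = SITE_COLUMNS
    return df.astype({"start": int, "end": int})


# ---------------------------------------------------------------- regions

def write_regions_bed(regions: Sequence[GenomicBin], path: str | Path) -> None:
    rows = [
        [b.chrom, b.start, b.end, b.bin_id, b.gene_id, b.stratum,
         ";".join(f"{s}-{e}" for s, e in b.fragments)]
        for b in regions
    ]
    pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "gene_id", "stratum", "fragments"]
    ).to_csv(path, sep="\t", index=False)


def read_regions_bed(path: str | Path) -> list[GenomicBin]:
    df = pd.read_csv(path, sep="\t")
    regions = []
    for row in df.itertuples(index=False):
        frags = tuple(
            tuple(int(x) for x in part.split("-")) for part in str(row.fragments).split(";")
        )
        regions.append(
            GenomicBin(
                bin_id=str(row.name), chrom=str(row.chrom), start=int(row.start),
                end=int(row.end), gene_id=str(row.gene_id), stratum=str(row.stratum),
                fragments=frags,
            )
        )
    return regions


# ---------------------------------------------------------------- expression

def write_expression_tsv(expr: ExpressionTable, path: str | Path) -> None:
    df = pd.DataFrame(expr.values, index=list(expr.entities), columns=list(expr.tissues))
    df.index.name = "entity"
    df.to_csv(path, sep="\t")


def read_expression_tsv(path: str | Path, level: str = "protein") -> ExpressionTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionTable(
        entities=df.index.tolist(),
        tissues=df.columns.tolist(),
        values=df.to_numpy(dtype=float),
        level=level,
    )


# ---------------------------------------------------------------- misc

def write_truth_json(truth: Mapping | "object", path: str | Path) -> None:
    payload = truth.to_dict() if hasattr(truth, "to_dict") else dict(truth)
    Path(path).write_text(json.dumps(payload, indent=1))


def read_ppi_scores(path: str | Path) -> dict[tuple[str, str], float]:
    """TSV with columns effector, partner, score."""
    df = pd.read_csv(path, sep="\t")
    for col in ("effector", "partner", "score"):
        if col not in df.columns:
            raise InputError(f"{path}: ppi table missing column {col!r}")
    return {
        (str(r.effector), str(r.partner)): float(r.score)
        for r in df.itertuples(index=False)
    }
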