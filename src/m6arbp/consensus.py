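"""Reproducible m6A region calling from multi-study bin-level peak calls.

The consensus rule has two thresholds: within a study, a bin must be called in
at least ``min_replicate_frac`` of that study's replicates (default 60%); a
bin is then a reproducible m6A region iff it passes the within-study rule in
at least ``min_studies`` independent studies (default 3). Regions are
individual fixed-width bins, not merged runs, because every downstream
statistic (enrichment counts, classifier features) is defined per bin.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np

from .core import (
    EXONIC,
    JUNCTION,
    GeneModel,
    GenomicBin,
    InputError,
    ParameterError,
    PeakCallMatrix,
)

logger = logging.getLogger(__name__)

# numerical guard for the >= comparison at the replicate-fraction threshold:
# 3/5 must pass a 0.6 cutoff despite binary floating point
_FRAC_EPS = 1e-9


def bin_transcriptome(genes: Sequence[GeneModel], bin_size: int = 200) -> list[GenomicBin]:
    """Tile each gene's mature transcript with fixed-width bins.

    Binning runs in transcript (spliced) coordinates and each bin is lifted
    back to its genomic fragments; a bin touching > 1 exon is labelled
    ``junction``, otherwise ``exonic``. A trailing remainder shorter than
    ``bin_size`` is dropped, so genes shorter than one bin contribute nothing.
    Bins with identical genomic spans (isoform duplicates) are deduplicated,
    keeping the first gene id encountered.
    """
    if bin_size < 1:
        raise ParameterError(f"bin_size must be >= 1, got {bin_size}")
    bins: list[GenomicBin] = []
    seen_spans: set[tuple[str, int, int]] = set()
    for gene in genes:
        n_full = gene.tx_length // bin_size
        if n_full == 0:
            logger.info(
                "gene %s transcript length %d < bin_size %d; contributes no bins",
                gene.gene_id, gene.tx_length, bin_size,
            )
            continue
        # exons in transcript order (5'->3'): reversed for minus strand
        tx_exons = gene.exons if gene.strand == "+" else tuple(reversed(gene.exons))
        # cumulative transcript offsets of each exon
        offsets = np.cumsum([0] + [e - s for s, e in tx_exons])
        for k in range(n_full):
            t0, t1 = k * bin_size, (k + 1) * bin_size
            fragments: list[tuple[int, int]] = []
            for (es, ee), off in zip(tx_exons, offsets[:-1]):
                ex_len = ee - es
                lo, hi = max(t0, off), min(t1, off + ex_len)
                if lo >= hi:
                    continue
                if gene.strand == "+":
                    fragments.append((es + (lo - off), es + (hi - off)))
                else:
                    fragments.append((ee - (hi - off), ee - (lo - off)))
            fragments.sort()
            span = (gene.chrom, fragments[0][0], fragments[-1][1])
            if span in seen_spans:
                continue
            seen_spans.add(span)
            bins.append(
                GenomicBin(
                    bin_id=f"{gene.gene_id}|{k}",
                    chrom=gene.chrom,
                    start=span[1],
                    end=span[2],
                    gene_id=gene.gene_id,
                    stratum=JUNCTION if len(fragments) > 1 else EXONIC,
                    fragments=tuple(fragments),
                    tx_start=t0,
                )
            )
    bins.sort(key=lambda b: (b.chrom, b.start, b.end))
    return bins


def study_level_calls(
    m: PeakCallMatrix, min_replicate_frac: float = 0.6
) -> tuple[list[str], np.ndarray]:
    """Collapse replicate calls to per-study calls.

    A study calls a bin iff the fraction of its replicates calling the bin is
    >= ``min_replicate_frac`` (inclusive: 3 of 5 replicates passes 0.6).
    Returns (study ids, bins x studies binary matrix).
    """
    if not 0.0 < min_replicate_frac <= 1.0:
        raise ParameterError(f"min_replicate_frac must be in (0, 1], got {min_replicate_frac}")
    studies = m.studies
    sample_idx = {
        st: [j for j, s in enumerate(m.samples) if m.study_of[s] == st] for st in studies
    }
    for st, idx in sample_idx.items():
        if not idx:
            raise InputError(f"study {st} has no samples")
    out = np.zeros((len(m.bins), len(studies)), dtype=np.int8)
    for j, st in enumerate(studies):
        cols = m.calls[:, sample_idx[st]]
        frac = cols.sum(axis=1) / cols.shape[1]
        out[:, j] = (frac + _FRAC_EPS >= min_replicate_frac).astype(np.int8)
    return studies, out


def reproducible_regions(
    bins: Sequence[GenomicBin], study_calls: np.ndarray, min_studies: int = 3
) -> list[GenomicBin]:
    """Bins called by at least ``min_studies`` studies, in genomic order."""
    study_calls = np.asarray(study_calls)
    if min_studies > study_calls.shape[1]:
        raise ParameterError(
            f"min_studies={min_studies} exceeds number of studies {study_calls.shape[1]}"
        )
    if min_studies < 1:
        raise ParameterError("min_studies must be >= 1")
    keep = study_calls.sum(axis=1) >= min_studies
    out = [b for b, k in zip(bins, keep) if k]
    out.sort(key=lambda b: (b.chrom, b.start, b.end))
    return out


def call_consensus(
    m: PeakCallMatrix,
    min_replicate_frac: float = 0.6,
    min_studies: int = 3,
) -> list[GenomicBin]:
    """Convenience wrapper: replicate rule then study rule."""
    _, sc = study_level_calls(m, min_replicate_frac)
    return reproducible_regions(m.bins, sc, min_studies)


def consensus_summary(
    m: PeakCallMatrix, min_replicate_frac: float = 0.6, min_studies: int = 3
):
    """Per-study call counts and per-threshold region counts, for reporting."""
    import pandas as pd

    studies, sc = study_level_calls(m, min_replicate_frac)
    rows = [
        {"metric": f"bins_called_in_study:{st}", "value": int(sc[:, j].sum())}
        for j, st in enumerate(studies)
    ]
    support = sc.sum(axis=1)
    for k in range(1, len(studies) + 1):
        rows.append({"metric": f"bins_in_ge_{k}_studies", "value": int((support >= k).sum())})
    rows.append(
        {
            "metric": "reproducible_regions",
            "value": int((support >= min_studies).sum()),
        }
    )
    return pd.DataFrame(rows)
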