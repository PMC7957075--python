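"""Stratified permutation test for RBP binding enrichment in m6A regions.

For each RBP the observed statistic is N_t, the number of m6A regions
overlapped by at least one of its binding sites. Control region sets of the
same size and the same exonic/junction stratum composition are drawn from the
non-m6A bins of m6A-containing genes; the enrichment ratio is

    R = N_t / E(N_c)

with E(N_c) the mean control count over permutations, and the one-sided
empirical p-value is the proportion of control counts equal to or greater
than N_t. Matching the stratum composition removes the bin-position
confounder (junction bins see systematically different binding).
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from statsmodels.stats.multitest import multipletests

from .core import (
    BindingMatrix,
    ControlPool,
    EnrichmentResult,
    GenomicBin,
    InputError,
    ParameterError,
)

logger = logging.getLogger(__name__)

SITE_COLUMNS = ["chrom", "start", "end", "rbp", "score", "strand"]


def overlap_matrix(regions: Sequence[GenomicBin], sites: pd.DataFrame) -> BindingMatrix:
    """Binary region x RBP overlap indicators.

    A region is bound by an RBP iff >= 1 bp of one of its sites intersects one
    of the region's transcriptomic fragments. Strand is ignored. ``sites``
    needs columns chrom, start, end, rbp.
    """
    for col in ("chrom", "start", "end", "rbp"):
        if col not in sites.columns:
            raise InputError(f"sites table missing column {col!r}")
    bad = sites[sites["end"] <= sites["start"]]
    if len(bad):
        rec = bad.iloc[0]
        raise InputError(
            f"malformed site interval (end <= start): "
            f"{rec['chrom']}:{rec['start']}-{rec['end']} ({rec['rbp']})"
        )
    rbps = sorted(sites["rbp"].unique())
    rbp_idx = {r: j for j, r in enumerate(rbps)}
    trees: dict[str, IntervalTree] = {}
    for i, reg in enumerate(regions):
        t = trees.setdefault(reg.chrom, IntervalTree())
        for fs, fe in reg.fragments:
            t.addi(fs, fe, i)
    bound = np.zeros((len(regions), len(rbps)), dtype=np.int8)
    for chrom, start, end, rbp in zip(
        sites["chrom"].to_numpy(),
        sites["start"].to_numpy(),
        sites["end"].to_numpy(),
        sites["rbp"].to_numpy(),
    ):
        tree = trees.get(chrom)
        if tree is None:
            continue
        j = rbp_idx[rbp]
        for hit in tree.overlap(start, end):
            bound[hit.data, j] = 1
    return BindingMatrix(regions=list(regions), rbps=rbps, bound=bound)


def build_control_pool(
    all_bins: Sequence[GenomicBin], m6a_regions: Sequence[GenomicBin]
) -> ControlPool:
    """Control candidates: bins of genes containing >= 1 m6A region, minus the
    m6A regions themselves. ``required`` records the m6A set's stratum counts."""
    m6a_ids = {b.bin_id for b in m6a_regions}
    m6a_genes = {b.gene_id for b in m6a_regions}
    pool = [b for b in all_bins if b.gene_id in m6a_genes and b.bin_id not in m6a_ids]
    required: dict[str, int] = {}
    for b in m6a_regions:
        required[b.stratum] = required.get(b.stratum, 0) + 1
    return ControlPool(regions=pool, required=required)


def sample_matched_control(
    pool: ControlPool, n_perm: int = 1000, seed: int = 0
) -> list[np.ndarray]:
    """Draw ``n_perm`` stratum-matched control index sets from the pool.

    Each set reproduces the m6A set's per-stratum counts exactly, sampled
    without replacement within a set and independently across sets. Raises if
    any stratum cannot supply its required count — no silent fallback.
    """
    if n_perm < 1:
        raise ParameterError("n_perm must be >= 1")
    strata = pool.stratum_indices()
    for stratum, need in pool.required.items():
        have = len(strata.get(stratum, ()))
        if have < need:
            raise ParameterError(
                f"control pool exhausted for stratum {stratum!r}: "
                f"need {need}, have {have}"
            )
    rng = np.random.default_rng(seed)
    sets: list[np.ndarray] = []
    for _ in range(n_perm):
        parts = [
            rng.choice(strata[stratum], size=need, replace=False)
            for stratum, need in sorted(pool.required.items())
            if need > 0
        ]
        sets.append(np.sort(np.concatenate(parts)) if parts else np.empty(0, dtype=np.intp))
    return sets


def control_counts(
    bm_pool: BindingMatrix, control_sets: Iterable[np.ndarray]
) -> np.ndarray:
    """Per-permutation, per-RBP control counts N_c (n_perm x n_rbps)."""
    return np.stack([bm_pool.bound[idx].sum(axis=0) for idx in control_sets])


def enrichment_test(
    bm_m6a: BindingMatrix,
    bm_pool: BindingMatrix,
    pool: ControlPool,
    n_perm: int = 1000,
    seed: int = 0,
    pseudo: bool = False,
) -> list[EnrichmentResult]:
    """Run the stratified permutation test for every RBP.

    One shared sequence of control sets serves all RBPs. With ``pseudo`` the
    empirical p is (k+1)/(n_perm+1) instead of the raw proportion k/n_perm.
    """
    if list(bm_m6a.rbps) != list(bm_pool.rbps):
        raise InputError("m6A and pool binding matrices must share the RBP universe")
    sets = sample_matched_control(pool, n_perm=n_perm, seed=seed)
    nc = control_counts(bm_pool, sets)  # n_perm x n_rbps
    nt = bm_m6a.bound.sum(axis=0).astype(int)
    e_nc = nc.mean(axis=0)
    k = (nc >= nt[None, :]).sum(axis=0)
    p = (k + 1) / (n_perm + 1) if pseudo else k / n_perm
    p[(e_nc == 0) & (nt == 0)] = 1.0  # undefined ratio: nothing observed anywhere
    q = bh_adjust(p)
    results: list[EnrichmentResult] = []
    for j, rbp in enumerate(bm_m6a.rbps):
        flag = ""
        if e_nc[j] == 0:
            if nt[j] > 0:
                ratio, flag = math.inf, "infinite"
            else:
                ratio, flag = math.nan, "undefined"
        else:
            ratio = nt[j] / e_nc[j]
        results.append(
            EnrichmentResult(
                rbp=rbp,
                n_t=int(nt[j]),
                e_nc=float(e_nc[j]),
                ratio=float(ratio),
                p_value=float(p[j]),
                q_value=float(q[j]),
                n_perm=n_perm,
                ratio_flag=flag,
            )
        )
    return results


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped to 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def filter_enriched(
    results: Sequence[EnrichmentResult],
    min_ratio: float = 1.3,
    max_fdr: float = 0.05,
) -> list[EnrichmentResult]:
    """Keep RBPs with R >= min_ratio and q <= max_fdr, ranked by R descending."""
    kept = [
        r
        for r in results
        if not math.isnan(r.ratio) and r.ratio >= min_ratio and r.q_value <= max_fdr
    ]
    kept.sort(key=lambda r: (-r.ratio, r.rbp))
    return kept


def co_overlap_table(
    bm_m6a: BindingMatrix,
    enriched: Sequence[str],
    min_regions: int = 100,
    frac: float = 0.6,
) -> pd.DataFrame:
    """Pairs (A, B) where B covers more than ``frac`` of enriched RBP A's bound
    m6A regions; A restricted to enriched RBPs bound in more than
    ``min_regions`` regions (strict), B ranges over all RBPs, self-pairs
    suppressed."""
    unknown = set(enriched) - set(bm_m6a.rbps)
    if unknown:
        raise InputError(f"enriched RBPs not in binding matrix: {sorted(unknown)}")
    bound = bm_m6a.bound.astype(bool)
    idx = {r: j for j, r in enumerate(bm_m6a.rbps)}
    rows = []
    for a in enriched:
        ja = idx[a]
        n_a = int(bound[:, ja].sum())
        if n_a <= min_regions:
            continue
        for b in bm_m6a.rbps:
            if b == a:
                continue
            shared = int((bound[:, ja] & bound[:, idx[b]]).sum())
            f = shared / n_a
            if f > frac:
                rows.append(
                    {"rbp_a": a, "rbp_b": b, "n_a": n_a, "n_shared": shared, "fraction": f}
                )
    return pd.DataFrame(rows, columns=["rbp_a", "rbp_b", "n_a", "n_shared", "fraction"])


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Tabulate results; p_display formats p=0 as '<1/n_perm' while p_value
    keeps the raw proportion."""
    rows = []
    for r in results:
        rows.append(
            {
                "rbp": r.rbp,
                "n_t": r.n_t,
                "e_nc": r.e_nc,
                "ratio": r.ratio,
                "p_value": r.p_value,
                "p_display": f"<{1 / r.n_perm:g}" if r.p_value == 0 else f"{r.p_value:g}",
                "q_value": r.q_value,
                "n_perm": r.n_perm,
                "ratio_flag": r.ratio_flag,
            }
        )
    return pd.DataFrame(rows)
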