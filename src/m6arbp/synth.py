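"""Synthetic-data generators with planted ground truth.

Every input the pipeline consumes can be simulated here: a toy one-chromosome
transcriptome, per-sample bin-level peak calls across several studies with
tunable reproducibility, RBP binding-site tracks with planted enrichment or
depletion relative to the methylated bins, and tissue expression tables with
a planted between-group difference in correlation to a shared latent profile.

Generation starts at the bin-call level a transcriptome-based peak caller
reaches — no reads, no coverage. Truth labels travel in a separate sidecar
structure and never appear in the emitted files, so downstream stages cannot
leak them. Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .consensus import bin_transcriptome
from .core import (
    ExpressionTable,
    GeneModel,
    GenomicBin,
    ParameterError,
    PeakCallMatrix,
    RbpSpec,
)


def _as_range(r, name: str) -> tuple[int, int]:
    if isinstance(r, int):
        r = (r, r)
    lo, hi = int(r[0]), int(r[1])
    if lo < 1 or hi < lo:
        raise ParameterError(f"{name} must be a positive range, got {r}")
    return lo, hi


def simulate_transcriptome(
    n_genes: int,
    exons_per_gene=(2, 5),
    exon_len=(150, 600),
    intron_len=(100, 2000),
    seed: int = 0,
    chrom: str = "chrS",
    gene_gap=(500, 2000),
) -> list[GeneModel]:
    """Non-overlapping genes laid left to right on one synthetic chromosome.

    Ranges may be a single int or an inclusive (lo, hi) pair; draws are
    uniform. Strand alternates deterministically (+,-,+,...), exercising both
    lift-over directions without an extra random stream.
    """
    if n_genes < 1:
        raise ParameterError("n_genes must be >= 1")
    ex_n = _as_range(exons_per_gene, "exons_per_gene")
    ex_l = _as_range(exon_len, "exon_len")
    in_l = _as_range(intron_len, "intron_len")
    gap = _as_range(gene_gap, "gene_gap")
    rng = np.random.default_rng(seed)
    genes: list[GeneModel] = []
    cursor = int(rng.integers(gap[0], gap[1] + 1))
    for g in range(n_genes):
        n_ex = int(rng.integers(ex_n[0], ex_n[1] + 1))
        exons = []
        pos = cursor
        for i in range(n_ex):
            length = int(rng.integers(ex_l[0], ex_l[1] + 1))
            exons.append((pos, pos + length))
            pos += length
            if i < n_ex - 1:
                pos += int(rng.integers(in_l[0], in_l[1] + 1))
        genes.append(
            GeneModel(
                gene_id=f"G{g:04d}",
                chrom=chrom,
                strand="+" if g % 2 == 0 else "-",
                exons=tuple(exons),
            )
        )
        cursor = pos + int(rng.integers(gap[0], gap[1] + 1))
    return genes


def simulate_peak_calls(
    genes: Sequence[GeneModel],
    bin_size: int = 200,
    n_studies: int = 4,
    replicates: Sequence[int] = (3, 2, 2, 2),
    true_m6a_fraction: float = 0.15,
    call_prob_true: float = 0.8,
    call_prob_false: float = 0.05,
    seed: int = 0,
) -> tuple[PeakCallMatrix, np.ndarray]:
    """Per-sample Bernoulli peak calls over the binned transcriptome.

    A fixed fraction of bins is secretly methylated; every sample calls a
    truly-m6A bin with ``call_prob_true`` and any other bin with
    ``call_prob_false``, independently. Returns the call matrix and the
    hidden truth mask (testing only — never written with the calls).
    """
    if len(replicates) != n_studies:
        raise ParameterError(
            f"replicates has {len(replicates)} entries for n_studies={n_studies}"
        )
    for p, lab in ((true_m6a_fraction, "true_m6a_fraction"),
                   (call_prob_true, "call_prob_true"),
                   (call_prob_false, "call_prob_false")):
        if not 0.0 <= p <= 1.0:
            raise ParameterError(f"{lab}={p} outside [0,1]")
    if any(r < 1 for r in replicates):
        raise ParameterError("every study needs >= 1 replicate")
    bins = bin_transcriptome(genes, bin_size=bin_size)
    rng = np.random.default_rng(seed)
    n_true = int(round(true_m6a_fraction * len(bins)))
    truth = np.zeros(len(bins), dtype=bool)
    truth[rng.choice(len(bins), size=n_true, replace=False)] = True
    samples, study_of = [], {}
    for st in range(n_studies):
        for r in range(replicates[st]):
            sid = f"S{st + 1}R{r + 1}"
            samples.append(sid)
            study_of[sid] = f"study{st + 1}"
    rate = np.where(truth, call_prob_true, call_prob_false)
    calls = (rng.random((len(bins), len(samples))) < rate[:, None]).astype(np.int8)
    return PeakCallMatrix(bins=bins, samples=samples, study_of=study_of, calls=calls), truth


def simulate_binding_sites(
    genes: Sequence[GeneModel],
    bins: Sequence[GenomicBin],
    m6a_mask: np.ndarray,
    specs: Sequence[RbpSpec],
    site_len=(20, 60),
    seed: int = 0,
) -> pd.DataFrame:
    """Planted binding-site intervals for each RBP.

    Per RBP and bin, a site is emitted with probability ``p_m6a`` if the bin
    is methylated, ``p_bg`` otherwise. The site is placed uniformly inside
    one of the bin's genomic fragments (so it overlaps exactly that bin and
    stays within the gene span); site length is clipped to the fragment.
    Output columns follow 6-column BED: chrom, start, end, rbp, score, strand.
    """
    if len(specs) == 0:
        raise ParameterError("specs must be non-empty")
    m6a_mask = np.asarray(m6a_mask, dtype=bool)
    if m6a_mask.shape != (len(bins),):
        raise ParameterError("m6a_mask length must equal number of bins")
    sl = _as_range(site_len, "site_len")
    rng = np.random.default_rng(seed)
    rows = []
    for spec in specs:
        rate = np.where(m6a_mask, spec.p_m6a, spec.p_bg)
        emit = rng.random(len(bins)) < rate
        for i in np.flatnonzero(emit):
            b = bins[i]
            frag = b.fragments[int(rng.integers(0, len(b.fragments)))]
            length = min(int(rng.integers(sl[0], sl[1] + 1)), frag[1] - frag[0])
            start = int(rng.integers(frag[0], frag[1] - length + 1))
            rows.append(
                {
                    "chrom": b.chrom,
                    "start": start,
                    "end": start + length,
                    "rbp": spec.name,
                    "score": 0,
                    "strand": ".",
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "rbp", "score", "strand"])


def simulate_expression(
    groups: Mapping[str, Sequence[str]],
    n_tissues: int,
    latent_corr: Mapping[str, float],
    noise_sd: float = 1.0,
    seed: int = 0,
    level: str = "protein",
) -> ExpressionTable:
    """Tissue expression with a planted correlation structure.

    One latent tissue profile z ~ N(0,1) is shared by the whole table. An
    entity in group g gets c*z + sqrt(1-c^2)*noise_sd*eps with c =
    latent_corr[g], then the strictly monotone transform exp(.) for
    non-negative values (Spearman-invariant). With noise_sd=1 the population
    correlation of an entity with the latent profile is exactly c; groups
    with c=0 are independent of it.
    """
    if n_tissues < 3:
        raise ParameterError("n_tissues must be >= 3 (rank correlation undefined below)")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    for g in groups:
        c = latent_corr.get(g)
        if c is None:
            raise ParameterError(f"no latent_corr for group {g!r}")
        if not 0.0 <= c <= 1.0:
            raise ParameterError(f"latent_corr[{g!r}]={c} outside [0,1]")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n_tissues)
    entities, profiles = [], []
    for g in sorted(groups):
        c = latent_corr[g]
        for ent in groups[g]:
            eps = rng.standard_normal(n_tissues)
            profiles.append(c * z + np.sqrt(1.0 - c * c) * noise_sd * eps)
            entities.append(ent)
    values = np.exp(np.asarray(profiles))
    tissues = [f"tissue{i + 1:02d}" for i in range(n_tissues)]
    return ExpressionTable(entities=entities, tissues=tissues, values=values, level=level)


@dataclass
class SyntheticTruth:
    """Sidecar record of the planted ground truth (testing only)."""

    m6a_bin_ids: list[str]
    rbp_specs: list[RbpSpec]
    latent_corr: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "m6a_bin_ids": self.m6a_bin_ids,
            "rbp_specs": [
                {"name": s.name, "p_m6a": s.p_m6a, "p_bg": s.p_bg, "role": s.role}
                for s in self.rbp_specs
            ],
            "latent_corr": dict(self.latent_corr),
        }


def default_rbp_specs() -> list[RbpSpec]:
    """A small panel mirroring the biology the pipeline must resolve: a few
    readers enriched in methylated bins, one repelled RBP, and nulls."""
    specs = [
        RbpSpec("READER1", 0.50, 0.25, "enriched"),
        RbpSpec("READER2", 0.40, 0.20, "enriched"),
        RbpSpec("REPELLED1", 0.10, 0.60, "depleted"),
    ]
    specs += [RbpSpec(f"NULL{i:02d}", 0.30, 0.30, "null") for i in range(1, 9)]
    return specs


def simulate_dataset(
    seed: int = 0,
    n_genes: int = 300,
    bin_size: int = 200,
    n_studies: int = 4,
    replicates: Sequence[int] = (3, 2, 2, 2),
    true_m6a_fraction: float = 0.15,
    call_prob_true: float = 0.8,
    call_prob_false: float = 0.05,
    specs: Sequence[RbpSpec] | None = None,
    n_tissues: int = 30,
):
    """One coherent synthetic study: transcriptome, peak calls, binding sites
    and a protein-level expression table, plus the truth sidecar.

    Defaults emulate the study design the pipeline targets: four independent
    studies with 2-3 replicates each at 200-bp resolution, a minority of bins
    methylated, and a mixed panel of enriched / repelled / null RBPs.
    """
    specs = list(specs) if specs is not None else default_rbp_specs()
    ss = np.random.SeedSequence(seed).generate_state(4) % (2**31)
    genes = simulate_transcriptome(n_genes, seed=int(ss[0]))
    pcm, truth = simulate_peak_calls(
        genes,
        bin_size=bin_size,
        n_studies=n_studies,
        replicates=replicates,
        true_m6a_fraction=true_m6a_fraction,
        call_prob_true=call_prob_true,
        call_prob_false=call_prob_false,
        seed=int(ss[1]),
    )
    sites = simulate_binding_sites(genes, pcm.bins, truth, specs, seed=int(ss[2]))
    groups = {
        "associated": [s.name for s in specs if s.role == "enriched"],
        "other": [s.name for s in specs if s.role != "enriched"],
        "effector": ["EFFECTOR1"],
    }
    latent = {"associated": 0.8, "other": 0.1, "effector": 1.0}
    expr = simulate_expression(groups, n_tissues=n_tissues, latent_corr=latent, seed=int(ss[3]))
    truth_rec = SyntheticTruth(
        m6a_bin_ids=[b.bin_id for b, t in zip(pcm.bins, truth) if t],
        rbp_specs=specs,
        latent_corr=latent,
    )
    return genes, pcm, truth, sites, expr, truth_rec
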