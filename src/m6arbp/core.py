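"""Core domain types shared across the pipeline.

Coordinates are 0-based half-open throughout (BED convention). The unit of
analysis is the fixed-width transcriptomic bin: MeRIP-Seq peak callers that
operate on spliced transcripts emit enrichment calls per 200-bp window of the
mature mRNA, so a bin has an exact width in transcript space but may map back
to more than one genomic fragment when it straddles a splice junction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence, Tuple

import numpy as np

#: stratum labels for bins
EXONIC = "exonic"
JUNCTION = "junction"


class ParameterError(ValueError):
    """Raised when a caller-supplied parameter is outside its domain."""


class InputError(ValueError):
    """Raised when an input record is malformed."""


@dataclass(frozen=True)
class GeneModel:
    """A gene as an ordered set of exons on one strand.

    exons are (start, end) pairs in genomic coordinates, sorted by start,
    non-overlapping, each of length >= 1.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: Tuple[Tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise InputError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if not self.exons:
            raise InputError(f"gene {self.gene_id}: no exons")
        prev_end = None
        for s, e in self.exons:
            if e - s < 1:
                raise InputError(f"gene {self.gene_id}: exon [{s},{e}) has length < 1")
            if prev_end is not None and s < prev_end:
                raise InputError(f"gene {self.gene_id}: exons overlap or are unsorted")
            prev_end = e
        object.__setattr__(self, "exons", tuple((int(s), int(e)) for s, e in self.exons))

    @property
    def span(self) -> Tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def tx_length(self) -> int:
        """Length of the mature (spliced) transcript."""
        return sum(e - s for s, e in self.exons)


@dataclass(frozen=True)
class GenomicBin:
    """A fixed-width transcriptomic bin lifted back to the genome.

    ``start``/``end`` give the genomic span (first fragment start to last
    fragment end); ``fragments`` are the per-exon genomic pieces whose summed
    length equals the bin width. A bin is ``junction`` iff it has > 1 fragment.
    """

    bin_id: str
    chrom: str
    start: int
    end: int
    gene_id: str
    stratum: str
    fragments: Tuple[Tuple[int, int], ...]
    tx_start: int = 0

    def __post_init__(self) -> None:
        if self.stratum not in (EXONIC, JUNCTION):
            raise InputError(f"bin {self.bin_id}: unknown stratum {self.stratum!r}")
        if self.end <= self.start:
            raise InputError(f"bin {self.bin_id}: end <= start")

    @property
    def width(self) -> int:
        """Transcriptomic width (sum of fragment lengths)."""
        return sum(e - s for s, e in self.fragments)


@dataclass
class PeakCallMatrix:
    """Per-sample binary peak calls over a common bin set.

    ``calls`` is bins x samples in {0,1}; ``study_of`` maps each sample id to
    the study it belongs to.
    """

    bins: Sequence[GenomicBin]
    samples: Sequence[str]
    study_of: Mapping[str, str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls)
        if self.calls.shape != (len(self.bins), len(self.samples)):
            raise InputError(
                f"calls shape {self.calls.shape} != (n_bins={len(self.bins)}, "
                f"n_samples={len(self.samples)})"
            )
        if not np.isin(self.calls, (0, 1)).all():
            raise InputError("calls must be strictly binary")
        missing = [s for s in self.samples if s not in self.study_of]
        if missing:
            raise InputError(f"samples without a study assignment: {missing}")

    @property
    def studies(self) -> list[str]:
        """Study ids in order of first appearance among samples."""
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.study_of[s], None)
        return list(seen)


@dataclass
class BindingMatrix:
    """Binary region x RBP overlap indicators.

    bound[r, p] = 1 iff at least one binding site of RBP p overlaps region r
    by >= 1 bp (against the region's transcriptomic fragments).
    """

    regions: Sequence[GenomicBin]
    rbps: Sequence[str]
    bound: np.ndarray

    def __post_init__(self) -> None:
        self.bound = np.asarray(self.bound, dtype=np.int8)
        if self.bound.shape != (len(self.regions), len(self.rbps)):
            raise InputError("bound matrix shape mismatch")

    def column(self, rbp: str) -> np.ndarray:
        return self.bound[:, list(self.rbps).index(rbp)]


@dataclass
class EnrichmentResult:
    """Per-RBP outcome of the stratified permutation enrichment test."""

    rbp: str
    n_t: int
    e_nc: float
    ratio: float
    p_value: float
    q_value: float
    n_perm: int
    ratio_flag: str = ""  # "", "infinite", or "undefined"


@dataclass
class ControlPool:
    """Candidate control bins: bins of m6A-containing genes minus the m6A set.

    ``required`` holds the per-stratum counts of the m6A region set that every
    matched control draw must reproduce.
    """

    regions: Sequence[GenomicBin]
    required: Mapping[str, int]

    def stratum_indices(self) -> dict[str, np.ndarray]:
        out: dict[str, list[int]] = {}
        for i, b in enumerate(self.regions):
            out.setdefault(b.stratum, []).append(i)
        return {k: np.asarray(v, dtype=np.intp) for k, v in out.items()}


@dataclass(frozen=True)
class RbpSpec:
    """Planted truth for one simulated RBP track.

    p_m6a / p_bg are the per-bin binding probabilities in m6A vs background
    bins; ``role`` records whether the RBP was planted as enriched (reader
    style), depleted (repelled style) or null.
    """

    name: str
    p_m6a: float
    p_bg: float
    role: str = "null"

    def __post_init__(self) -> None:
        for v, lab in ((self.p_m6a, "p_m6a"), (self.p_bg, "p_bg")):
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{self.name}: {lab}={v} outside [0,1]")
        if self.role not in ("enriched", "depleted", "null"):
            raise ParameterError(f"{self.name}: unknown role {self.role!r}")
        if self.role == "enriched" and not self.p_m6a > self.p_bg:
            raise ParameterError(f"{self.name}: role=enriched requires p_m6a > p_bg")
        if self.role == "depleted" and not self.p_m6a < self.p_bg:
            raise ParameterError(f"{self.name}: role=depleted requires p_m6a < p_bg")


@dataclass
class ExpressionTable:
    """Entity x tissue expression values at one measurement level."""

    entities: Sequence[str]
    tissues: Sequence[str]
    values: np.ndarray
    level: str = "protein"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.entities), len(self.tissues)):
            raise InputError("expression values shape mismatch")
        if len(self.tissues) < 3:
            raise ParameterError("expression table needs >= 3 tissues")
        if np.isnan(self.values).any():
            raise InputError("expression table contains missing values")

    def profile(self, entity: str) -> np.ndarray:
        return self.values[list(self.entities).index(entity)]
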