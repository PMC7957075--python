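import numpy as np
import pytest

from m6arbp.core import EXONIC, JUNCTION, BindingMatrix, ControlPool, GenomicBin


def toy_bins(n, stratum=None, chrom="chrS", gene_size=10):
    """n disjoint 200-bp exonic bins (or per-bin strata from a sequence)."""
    bins = []
    for i in range(n):
        s = EXONIC if stratum is None else stratum[i]
        start = i * 1000
        bins.append(
            GenomicBin(
                bin_id=f"b{i}",
                chrom=chrom,
                start=start,
                end=start + 200,
                gene_id=f"g{i // gene_size}",
                stratum=s,
                fragments=((start, start + 200),),
            )
        )
    return bins


def bernoulli_binding(n_regions, probs, seed, strata=None):
    """BindingMatrix with independent Bernoulli columns, one per (name, p)."""
    rng = np.random.default_rng(seed)
    names = [name for name, _ in probs]
    bound = np.column_stack(
        [(rng.random(n_regions) < p).astype(np.int8) for _, p in probs]
    )
    return BindingMatrix(regions=toy_bins(n_regions, stratum=strata), rbps=names, bound=bound)


def matched_pool(bins, required):
    return ControlPool(regions=bins, required=required)


@pytest.fixture(scope="session")
def small_dataset():
    """One coherent synthetic study reused across read-only tests."""
    from m6arbp import synth

    return synth.simulate_dataset(seed=1, n_genes=120)
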