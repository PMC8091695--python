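import numpy as np
import pandas as pd
import pytest

from acrkit import genome_model as gm
from acrkit.peaks import PeakSet
from acrkit.synthetic_data import SyntheticConfig, generate


@pytest.fixture(scope="session")
def noisy_bundle(tmp_path_factory):
    """Default synthetic study: 3 stages x 4 replicates, noisy peaks/counts."""
    return generate(SyntheticConfig(seed=1), tmp_path_factory.mktemp("bundle_noisy"))


@pytest.fixture(scope="session")
def clean_bundle(tmp_path_factory):
    """Noise-free variant: every truth peak in every replicate, no jitter."""
    cfg = SyntheticConfig(seed=2, replicate_reproducibility=1.0, end_jitter_bp=0)
    return generate(cfg, tmp_path_factory.mktemp("bundle_clean"))


@pytest.fixture
def small_chrom_sizes():
    return gm.ChromSizes({"chr1": 100_000, "chr2": 50_000})


@pytest.fixture
def small_models(small_chrom_sizes):
    """Three hand-built genes: plus/minus strand on chr1, one on chr2."""
    mk = gm.GenomicInterval
    genes = [
        gm.GeneModel(
            "geneA",
            mk("chr1", 10_000, 16_000, "+"),
            (mk("chr1", 10_000, 11_000, "+"), mk("chr1", 13_000, 16_000, "+")),
        ),
        gm.GeneModel(
            "geneB",
            mk("chr1", 40_000, 48_000, "-"),
            (mk("chr1", 40_000, 42_000, "-"), mk("chr1", 46_000, 48_000, "-")),
        ),
        gm.GeneModel(
            "geneC",
            mk("chr2", 20_000, 24_000, "+"),
            (mk("chr2", 20_000, 24_000, "+"),),
        ),
    ]
    return gm.GeneModelSet(genes, small_chrom_sizes)


def truth_peakset(bundle, ids, label="truth"):
    """Build a PeakSet from truth peak ids of a synthetic bundle."""
    recs = [
        {
            "chrom": bundle.truth.peaks[p]["chrom"],
            "start": bundle.truth.peaks[p]["start"],
            "end": bundle.truth.peaks[p]["end"],
            "name": p,
        }
        for p in ids
    ]
    return PeakSet(pd.DataFrame(recs), label=label)


def random_toy_genome(rng: np.random.Generator, max_len=30_000, n_genes=6):
    """A small random genome + gene models for oracle-equivalence checks."""
    chrom_len = int(rng.integers(10_000, max_len))
    cs = gm.ChromSizes({"chrT": chrom_len})
    genes = []
    cursor = int(rng.integers(200, 2000))
    for i in range(n_genes):
        glen = int(rng.integers(500, 3000))
        if cursor + glen + 200 >= chrom_len:
            break
        start, end = cursor, cursor + glen
        strand = "+" if rng.random() < 0.5 else "-"
        cut = int(rng.integers(start + 100, end - 100))
        exons = (
            gm.GenomicInterval("chrT", start, cut, strand),
            gm.GenomicInterval("chrT", min(cut + 50, end - 1), end, strand),
        )
        genes.append(
            gm.GeneModel(f"g{i}", gm.GenomicInterval("chrT", start, end, strand), exons)
        )
        cursor = end + int(rng.integers(300, 3000))
    return cs, gm.GeneModelSet(genes, cs)


def random_intervals(rng, chrom_len, n, min_len=20, max_len=400):
    starts = rng.integers(0, chrom_len - max_len, size=n)
    lens = rng.integers(min_len, max_len, size=n)
    return sorted((int(s), int(s + l)) for s, l in zip(starts, lens))
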