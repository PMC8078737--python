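import numpy as np
import pandas as pd
import pytest

from dripmeta import AnchoredRegion, GenomeLayout, SignalTrack, WindowSpec


@pytest.fixture
def toy_genome():
    return GenomeLayout(("chr1", "chr2"), (100_000, 80_000))


@pytest.fixture
def small_spec():
    """A 2-kb window of 100-nt bins — fits easily on the toy genome."""
    return WindowSpec(half_width=1_000, bin_width=100)


@pytest.fixture
def toy_regions():
    return [
        AnchoredRegion("chr1", 10_000, 40_000, 25_000, "+", "origin_in_gene_body"),
        AnchoredRegion("chr1", 50_000, 90_000, 62_000, "-", "origin_in_gene_body"),
        AnchoredRegion("chr2", 5_000, 45_000, 25_000, "+", "gene_body_center"),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_917)


def random_reads(rng, genome, n, read_length=100):
    """Uniform random stranded reads over a genome, as a BED-like frame."""
    chrom_idx = rng.integers(0, len(genome.chrom_names), size=n)
    lengths = np.asarray(genome.chrom_lengths)
    starts = (rng.random(n) * (lengths[chrom_idx] - read_length)).astype(np.int64)
    return pd.DataFrame({
        "chrom": [genome.chrom_names[i] for i in chrom_idx],
        "start": starts,
        "end": starts + read_length,
        "strand": np.where(rng.random(n) < 0.5, "+", "-"),
    })


def track_from_counts(genome, counts, *, bin_width=100, normalized=True,
                      library_size=10_000_000, sample_id="t"):
    """Assemble a SignalTrack directly from per-chromosome arrays."""
    full = {}
    for name, length in zip(genome.chrom_names, genome.chrom_lengths):
        n_bins = -(-length // bin_width)
        arr = np.zeros(n_bins, dtype=np.float64 if normalized else np.int64)
        if name in counts:
            src = np.asarray(counts[name])
            arr[:len(src)] = src
        full[name] = arr
    return SignalTrack(genome=genome, bin_width=bin_width, counts=full,
                       library_size=library_size, normalized=normalized,
                       sample_id=sample_id)
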