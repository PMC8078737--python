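"""Independent brute-force oracles used by the unit and acceptance tests.

Each function recomputes a pipeline quantity by the most naive route
possible (explicit loops, full-support enumeration) and must stay free of
the library code paths it checks.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import hypergeom


def brute_bin_reads(reads, genome, bin_width):
    """Loop over reads, assign each strand-aware 5' end to floor(pos / width)."""
    counts = {
        name: np.zeros(-(-length // bin_width), dtype=np.int64)
        for name, length in zip(genome.chrom_names, genome.chrom_lengths)
    }
    for row in reads.itertuples(index=False):
        if row.chrom not in counts:
            continue
        pos = row.end - 1 if row.strand == "-" else row.start
        counts[row.chrom][pos // bin_width] += 1
    return counts


def brute_window_bins(region, half_width, bin_width):
    """Oriented genomic bin starts by explicit offset loop."""
    snapped = (region.anchor // bin_width) * bin_width
    n = 2 * half_width // bin_width
    out = []
    for j in range(n):
        offset = -half_width + j * bin_width
        if region.strand == "-":
            # transcription points left: offset +x sits x bp left of anchor
            start = snapped + half_width - bin_width - j * bin_width
        else:
            start = snapped + offset
        out.append(start)
    return np.array(out)


def brute_aggregate(track_counts, regions, half_width, bin_width):
    """Double loop over regions and bins; rows in transcription orientation."""
    rows = []
    for region in regions:
        starts = brute_window_bins(region, half_width, bin_width)
        rows.append([track_counts[region.chrom][s // bin_width] for s in starts])
    return np.array(rows, dtype=np.float64)


def brute_window_average(matrix, offsets, offset_start, offset_end):
    """Per-row slice-and-mean over bins with offset in [start, end)."""
    out = []
    for row in matrix:
        picked = [v for v, o in zip(row, offsets)
                  if offset_start <= o < offset_end]
        out.append(sum(picked) / len(picked))
    return np.array(out)


def fisher_two_sided_enum(a, b, c, d):
    """Two-sided Fisher p by full enumeration of the hypergeometric support.

    Sums P(table) over all tables with the observed margins whose probability
    is <= that of the observed table (minimum-likelihood rule, with the
    conventional (1 + 1e-7) guard against floating-point ties).
    """
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    support = np.arange(max(0, col1 - (c + d)), min(row1, col1) + 1)
    pmf = hypergeom.pmf(support, n, row1, col1)
    p_obs = hypergeom.pmf(a, n, row1, col1)
    return float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
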