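"""Binned DRIP-seq signal tracks: read counting and 10M-library normalization.

The signal for each 100-nt bin is a mapped read count; a whole track is
normalized to a 10-million-read library scale so samples sequenced to
different depths are comparable.  Read-to-bin assignment uses the
strand-aware 5' end of the read (start for '+', end-1 for '-'): single-point
assignment keeps count conservation exact and each read contributes to
exactly one bin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .regions import GenomeLayout

logger = logging.getLogger(__name__)

NORM_TARGET = 10_000_000

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


class TrackError(ValueError):
    """Raised for malformed coverage inputs or invalid normalization states."""


@dataclass
class SignalTrack:
    """Per-chromosome fixed-width binned coverage for one sample.

    ``counts`` maps chromosome name to an array of length
    ``ceil(chrom_length / bin_width)``.  Raw tracks hold non-negative read
    counts; after :func:`normalize_track` every bin has been multiplied by
    ``norm_target / library_size`` and ``normalized`` is True.
    """

    genome: GenomeLayout
    bin_width: int
    counts: dict[str, np.ndarray]
    library_size: int
    normalized: bool = False
    norm_target: int = NORM_TARGET
    sample_id: str = ""

    def __post_init__(self) -> None:
        for name, length in zip(self.genome.chrom_names, self.genome.chrom_lengths):
            expected = -(-length // self.bin_width)
            if name not in self.counts:
                raise TrackError(f"missing counts for chromosome {name}")
            if len(self.counts[name]) != expected:
                raise TrackError(
                    f"{name}: {len(self.counts[name])} bins, expected {expected}")

    @property
    def total(self) -> float:
        return float(sum(arr.sum() for arr in self.counts.values()))

    def copy(self) -> "SignalTrack":
        return replace(self, counts={k: v.copy() for k, v in self.counts.items()})


def _empty_counts(genome: GenomeLayout, bin_width: int,
                  dtype=np.int64) -> dict[str, np.ndarray]:
    return {
        name: np.zeros(-(-length // bin_width), dtype=dtype)
        for name, length in zip(genome.chrom_names, genome.chrom_lengths)
    }


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED3/BED6 file of aligned read intervals."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = BED_COLUMNS[: df.shape[1]]
    if "strand" not in df.columns:
        df["strand"] = "+"
    return df[["chrom", "start", "end", "strand"]]


def bin_reads(reads: pd.DataFrame | str | Path, genome: GenomeLayout,
              bin_width: int = 100, *, dedup: bool = False,
              library_size: int | None = None,
              sample_id: str = "") -> SignalTrack:
    """Count aligned reads into fixed-width bins (raw track).

    Each read increments exactly one bin: the one holding its strand-aware
    5' end.  Reads on chromosomes absent from the genome are skipped with a
    logged count.  ``dedup`` removes exact-interval duplicates first (the
    published analysis removes duplicates upstream; this switch exists for
    synthetic data).  ``library_size`` overrides the default (number of reads
    ingested) when the file holds only a subset of the mapped library.
    """
    if not isinstance(reads, pd.DataFrame):
        reads = read_bed(reads)
    if "strand" not in reads.columns:
        reads = reads.assign(strand="+")
    if bin_width < 1:
        raise TrackError("bin_width must be >= 1")
    if len(reads) and (reads["start"] < 0).any():
        raise TrackError("negative read coordinates")
    if dedup and len(reads):
        reads = reads.drop_duplicates(subset=["chrom", "start", "end", "strand"])
    known = reads["chrom"].isin(genome.chrom_names) if len(reads) else pd.Series(dtype=bool)
    n_skipped = int((~known).sum()) if len(reads) else 0
    if n_skipped:
        logger.info("skipped %d reads on unknown chromosomes", n_skipped)
        reads = reads[known]
    counts = _empty_counts(genome, bin_width)
    for chrom, grp in reads.groupby("chrom", sort=False):
        five_prime = np.where(grp["strand"].to_numpy() == "-",
                              grp["end"].to_numpy() - 1,
                              grp["start"].to_numpy())
        chrom_len = genome.length_of(str(chrom))
        if (five_prime >= chrom_len).any():
            raise TrackError(f"read 5' end beyond {chrom} length {chrom_len}")
        bins = five_prime // bin_width
        counts[str(chrom)] += np.bincount(bins, minlength=len(counts[str(chrom)]))
    n_binned = int(len(reads))
    if library_size is None:
        library_size = n_binned
    return SignalTrack(genome=genome, bin_width=bin_width, counts=counts,
                       library_size=library_size, normalized=False,
                       sample_id=sample_id)


def normalize_track(track: SignalTrack) -> SignalTrack:
    """Scale a raw track to the 10M-read library scale.

    Every bin is multiplied by ``norm_target / library_size``.  Normalizing
    an already-normalized track is an error (the transform is not meant to be
    idempotent), as is a zero library.
    """
    if track.normalized:
        raise TrackError("track is already normalized")
    if track.library_size <= 0:
        raise TrackError("cannot normalize a track with library_size 0")
    scale = track.norm_target / track.library_size
    counts = {k: v.astype(np.float64) * scale for k, v in track.counts.items()}
    return replace(track, counts=counts, normalized=True)


def read_bedgraph(path: str | Path, genome: GenomeLayout, bin_width: int = 100,
                  *, library_size: int | None = None, normalized: bool = False,
                  sample_id: str = "") -> SignalTrack:
    """Read pre-binned coverage from bedGraph; intervals must sit on the bin grid."""
    counts = _empty_counts(genome, bin_width, dtype=np.float64)
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "value"], comment="#") \
        if Path(path).stat().st_size else pd.DataFrame(
            columns=["chrom", "start", "end", "value"])
    for i, row in enumerate(df.itertuples(index=False)):
        if row.chrom not in genome:
            raise TrackError(f"line {i + 1}: unknown chromosome {row.chrom!r}")
        chrom_len = genome.length_of(row.chrom)
        expected_end = min(int(row.start) + bin_width, chrom_len)
        if int(row.start) % bin_width or int(row.end) != expected_end:
            raise TrackError(
                f"line {i + 1}: interval [{row.start}, {row.end}) off the "
                f"{bin_width}-bp bin grid")
        counts[row.chrom][int(row.start) // bin_width] = float(row.value)
    if library_size is None:
        library_size = int(round(sum(arr.sum() for arr in counts.values())))
    return SignalTrack(genome=genome, bin_width=bin_width, counts=counts,
                       library_size=library_size, normalized=normalized,
                       sample_id=sample_id)


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    """Write a track as bedGraph on the fixed bin grid, omitting zero bins."""
    with open(path, "w") as fh:
        for chrom in track.genome.chrom_names:
            arr = track.counts[chrom]
            chrom_len = track.genome.length_of(chrom)
            nz = np.nonzero(arr)[0]
            for b in nz:
                start = int(b) * track.bin_width
                end = min(start + track.bin_width, chrom_len)
                value = arr[b]
                text = repr(float(value)) if track.normalized else str(int(value))
                fh.write(f"{chrom}\t{start}\t{end}\t{text}\n")
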