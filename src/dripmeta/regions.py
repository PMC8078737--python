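"""Genome layout, anchored gene-body regions and strand-oriented windows.

The analysis anchors fixed-width windows on replication origins (or gene-body
centers, or random positions) and orients every window in the direction of
transcription, so that negative offsets always point *upstream* of the anchor.
For a gene on the minus strand the genomic bin order is therefore reversed
before aggregation.  In this frame the head-on (HO) collision sub-region —
where an incoming replication fork meets RNA polymerase face to face — lies at
negative offsets from the origin, and the co-directional (CD) sub-region at
positive offsets.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STRANDS = ("+", "-")
REGION_CLASSES = ("origin_in_gene_body", "gene_body_center", "random")

REGION_COLUMNS = ["chrom", "gene_start", "gene_end", "anchor", "strand", "region_class"]


class RegionError(ValueError):
    """Raised for malformed region tables or invalid window requests."""


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names and lengths (bp)."""

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise RegionError("chrom_names and chrom_lengths differ in length")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise RegionError("chromosome names must be unique")
        if any(length <= 0 for length in self.chrom_lengths):
            raise RegionError("all chromosome lengths must be > 0")

    @property
    def total_length(self) -> int:
        return int(sum(self.chrom_lengths))

    def length_of(self, chrom: str) -> int:
        try:
            return self.chrom_lengths[self.chrom_names.index(chrom)]
        except ValueError:
            raise RegionError(f"unknown chromosome {chrom!r}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_names

    @classmethod
    def from_file(cls, path: str | Path) -> "GenomeLayout":
        """Read a standard two-column chrom.sizes file."""
        df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"],
                         dtype={"chrom": str, "length": np.int64})
        return cls(tuple(df["chrom"]), tuple(int(x) for x in df["length"]))

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, length in zip(self.chrom_names, self.chrom_lengths):
                fh.write(f"{name}\t{length}\n")


@dataclass(frozen=True)
class AnchoredRegion:
    """One gene body with its anchor point, strand and class.

    Coordinates are 0-based half-open (BED convention).  ``anchor`` is a
    replication-origin position for class ``origin_in_gene_body``, the gene
    midpoint for ``gene_body_center``, and an arbitrary genomic point for
    ``random`` (where strand is fixed to '+': no transcription direction
    exists there).
    """

    chrom: str
    gene_start: int
    gene_end: int
    anchor: int
    strand: str
    region_class: str

    def __post_init__(self) -> None:
        if self.gene_start >= self.gene_end:
            raise RegionError(
                f"gene_start {self.gene_start} >= gene_end {self.gene_end}")
        if self.gene_start < 0:
            raise RegionError("negative gene_start")
        if self.strand not in STRANDS:
            raise RegionError(f"malformed strand {self.strand!r}")
        if self.region_class not in REGION_CLASSES:
            raise RegionError(f"unknown region_class {self.region_class!r}")
        if self.region_class != "random" and not (
                self.gene_start <= self.anchor < self.gene_end):
            raise RegionError(
                f"anchor {self.anchor} outside gene body "
                f"[{self.gene_start}, {self.gene_end}) for class {self.region_class}")
        if self.region_class == "random" and self.strand != "+":
            raise RegionError("random regions must carry + strand")

    @property
    def region_id(self) -> str:
        return f"{self.chrom}:{self.gene_start}-{self.gene_end}:{self.strand}:{self.anchor}"


@dataclass(frozen=True)
class WindowSpec:
    """Oriented aggregation window: ``2*half_width`` bp tiled by fixed bins.

    Offsets are transcription-oriented: negative means upstream of the anchor
    in the transcription direction.  Defaults give the 24 kb / 100 nt window
    used throughout the analysis.
    """

    half_width: int = 12_000
    bin_width: int = 100

    def __post_init__(self) -> None:
        if self.bin_width < 1 or self.half_width < 1:
            raise RegionError("half_width and bin_width must be positive")
        if self.half_width % self.bin_width:
            raise RegionError("half_width must be divisible by bin_width")

    @property
    def n_bins(self) -> int:
        return 2 * self.half_width // self.bin_width

    @property
    def offsets(self) -> np.ndarray:
        """Bin-start offsets, strictly increasing from -half_width."""
        return np.arange(-self.half_width, self.half_width, self.bin_width)


@dataclass(frozen=True)
class SubWindow:
    """Half-open offset interval within a window, e.g. the HO sub-region."""

    label: str
    offset_start: int
    offset_end: int

    def __post_init__(self) -> None:
        if self.offset_start >= self.offset_end:
            raise RegionError("empty sub-window")


def split_sub_windows(spec: WindowSpec, sub_half_width: int = 6_000) -> dict[str, SubWindow]:
    """The HO / CD / full quantification sub-windows of a window spec.

    HO = [-sub_half_width, 0), CD = [0, +sub_half_width); their union is the
    full quantification window.  The default 6 kb matches the published
    12 kb quantification window centred on origins.
    """
    if spec.half_width < sub_half_width:
        raise RegionError(
            f"half_width {spec.half_width} < sub-window half width {sub_half_width}")
    return {
        "HO": SubWindow("HO", -sub_half_width, 0),
        "CD": SubWindow("CD", 0, sub_half_width),
        "full_quant": SubWindow("full_quant", -sub_half_width, sub_half_width),
    }


def build_window(region: AnchoredRegion, spec: WindowSpec,
                 genome: GenomeLayout) -> np.ndarray | None:
    """Genomic bin-start coordinates of a region's window, in transcription order.

    The anchor is snapped down to the containing bin boundary so the window
    tiles exactly ``spec.n_bins`` bins.  For minus-strand regions the bin list
    is reversed so increasing offset always points downstream of transcription.
    Returns ``None`` when the window overruns a chromosome end (such regions
    are dropped from aggregation, not padded).
    """
    chrom_len = genome.length_of(region.chrom)
    snapped = (region.anchor // spec.bin_width) * spec.bin_width
    start = snapped - spec.half_width
    end = snapped + spec.half_width
    if start < 0 or end > chrom_len:
        return None
    starts = np.arange(start, end, spec.bin_width)
    if region.strand == "-":
        starts = starts[::-1]
    return starts


def load_regions(path: str | Path, genome: GenomeLayout) -> list[AnchoredRegion]:
    """Load a 6-column BED-like anchored-region table, validating every row.

    Columns: chrom, gene_start, gene_end, anchor, strand, region_class
    (tab-separated; a header line is accepted and detected).  Row order is
    preserved; a per-class count summary is logged.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=REGION_COLUMNS, dtype=str)
    if len(df) and df.iloc[0]["chrom"] == "chrom":  # optional header
        df = df.iloc[1:].reset_index(drop=True)
    regions: list[AnchoredRegion] = []
    for i, row in df.iterrows():
        if row["chrom"] not in genome:
            raise RegionError(f"row {i}: unknown chromosome {row['chrom']!r}")
        try:
            regions.append(AnchoredRegion(
                chrom=row["chrom"],
                gene_start=int(row["gene_start"]),
                gene_end=int(row["gene_end"]),
                anchor=int(row["anchor"]),
                strand=row["strand"],
                region_class=row["region_class"],
            ))
        except (RegionError, ValueError) as exc:
            raise RegionError(f"row {i}: {exc}") from exc
    counts = class_counts(regions)
    logger.info("loaded %d regions: %s", len(regions),
                ", ".join(f"{k}={v}" for k, v in counts.items()))
    return regions


def class_counts(regions: Iterable[AnchoredRegion]) -> dict[str, int]:
    """Number of loaded regions per region class (the load summary)."""
    counts: dict[str, int] = {}
    for r in regions:
        counts[r.region_class] = counts.get(r.region_class, 0) + 1
    return counts


def write_regions(regions: Sequence[AnchoredRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.gene_start}\t{r.gene_end}\t"
                     f"{r.anchor}\t{r.strand}\t{r.region_class}\n")


def sample_random_windows(genome: GenomeLayout, n: int, width: int,
                          seed: int) -> list[AnchoredRegion]:
    """Draw ``n`` random fully-in-bounds windows, uniform over the genome.

    Anchors are uniform over all positions where the full window fits; the
    chromosome is chosen proportionally to its usable length.  Strand is fixed
    to '+' (no inversion: random windows carry no transcription direction).
    Deterministic for a fixed seed; windows may overlap each other.
    """
    if n <= 0:
        raise RegionError("n must be positive")
    half = width // 2
    usable = np.array([length - width for length in genome.chrom_lengths], dtype=np.int64)
    if (usable < 0).all():
        raise RegionError(f"no chromosome can hold a {width} bp window")
    usable = np.clip(usable, 0, None)
    rng = np.random.default_rng(seed)
    probs = usable / usable.sum()
    chrom_idx = rng.choice(len(genome.chrom_names), size=n, p=probs)
    offsets = rng.integers(0, usable[chrom_idx] + 1)
    anchors = half + offsets
    return [
        AnchoredRegion(
            chrom=genome.chrom_names[ci],
            gene_start=int(a - half),
            gene_end=int(a + half),
            anchor=int(a),
            strand="+",
            region_class="random",
        )
        for ci, a in zip(chrom_idx, anchors)
    ]


def nominal_coverage(n: int, width: int, genome: GenomeLayout) -> float:
    """Overlap-ignoring genome fraction spanned by n windows of given width."""
    return n * width / genome.total_length
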