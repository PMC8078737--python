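"""Synthetic genomes, origin-anchored gene bodies and DRIP-like read sets.

The generator emulates the structure of the real inputs: a table of
transcribed gene bodies carrying classified replication origins (origins in
gene bodies, n = 727; origin-free gene-body centers, n = 484) and
DRIP-seq-like coverage with Poisson background noise, library-size
differences between samples, and — in the case sample only — a
multiplicative signal fold confined to the transcription-oriented head-on
(HO) and/or co-directional (CD) sub-windows around each origin.

The default configuration represents the study-scale conditions: 727 + 484
regions, a background of 2 expected reads per 100-nt bin, a 2-fold HO
enrichment in the case sample, no CD enrichment, and a genome large enough
(2 x 250 Mb) that realized library sizes sit at the 10-million-read scale of
the normalization target, as duplicate-removed DRIP-seq libraries do.
Expected rates are piecewise-constant over sub-windows so every window
average has a closed-form expectation for oracle tests.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .regions import (AnchoredRegion, GenomeLayout, RegionError, SubWindow,
                      WindowSpec, build_window, split_sub_windows, write_regions)
from .tracks import SignalTrack, TrackError, _empty_counts

logger = logging.getLogger(__name__)


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic dataset.

    ``background_rate`` is the expected read count per 100-nt bin everywhere
    except the case sample's HO/CD sub-windows of origin-class regions, where
    it is multiplied by ``fold_ho`` / ``fold_cd``.  ``library_size_*`` of
    ``None`` keeps the realized Poisson totals (no thinning/inflation).
    ``overdispersion`` > 0 gamma-mixes the rates (negative-binomial noise);
    the default 0 keeps pure Poisson noise with closed-form expectations.
    """

    n_chroms: int = 2
    chrom_length: int = 250_000_000
    n_origin_regions: int = 727
    n_center_regions: int = 484
    gene_length_range: tuple[int, int] = (14_000, 30_000)
    strand_prob: float = 0.5
    background_rate: float = 2.0
    fold_ho: float = 2.0
    fold_cd: float = 1.0
    library_size_control: int | None = None
    library_size_case: int | None = None
    bin_width: int = 100
    sub_half_width: int = 6_000
    overdispersion: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_rate <= 0:
            raise SimulationError("background_rate must be > 0")
        if self.fold_ho < 0 or self.fold_cd < 0:
            raise SimulationError("folds must be >= 0")
        lo, hi = self.gene_length_range
        if lo > hi or lo <= 2 * self.sub_half_width:
            raise SimulationError(
                "gene lengths must exceed twice the sub-window half width "
                "so HO and CD sub-windows fit inside gene bodies")
        if not (0.0 <= self.strand_prob <= 1.0):
            raise SimulationError("strand_prob must be a probability")

    @classmethod
    def small(cls, **overrides) -> "SimConfig":
        """A desk-sized fixture: 2 x 2 Mb genome, 60 regions, seconds to run."""
        defaults = dict(n_chroms=2, chrom_length=2_000_000,
                        n_origin_regions=40, n_center_regions=20)
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class SimTruth:
    """Everything needed to recompute expected signal analytically."""

    config: SimConfig
    genome: GenomeLayout
    regions: list[AnchoredRegion]
    rates_control: dict[str, np.ndarray]
    rates_case: dict[str, np.ndarray]

    def expected_library(self, role: str) -> float:
        rates = self.rates_case if role == "case" else self.rates_control
        return float(sum(arr.sum() for arr in rates.values()))

    def expected_window_average(self, role: str, label: str) -> float:
        """Closed-form expected *normalized* per-bin signal in a sub-window.

        For piecewise-constant rates the expected normalized window average
        is rate_in_subwindow x (norm_target / expected_library).
        """
        cfg = self.config
        fold = {"HO": cfg.fold_ho, "CD": cfg.fold_cd,
                "full_quant": (cfg.fold_ho + cfg.fold_cd) / 2}[label]
        if role != "case":
            fold = 1.0
        scale = 10_000_000 / self.expected_library(role)
        return cfg.background_rate * fold * scale


def simulate_regions(config: SimConfig) -> tuple[GenomeLayout, list[AnchoredRegion]]:
    """Place non-overlapping gene bodies uniformly and anchor them.

    Origin-class anchors fall uniformly in the gene interior at least one
    sub-window half-width (6 kb) from both gene ends, so the HO and CD
    sub-windows stay inside the transcribed gene body; center-class anchors
    sit at the gene midpoint.  Deterministic per config seed.
    """
    rng = np.random.default_rng(config.seed)
    genome = GenomeLayout(
        tuple(f"chr{i + 1}" for i in range(config.n_chroms)),
        tuple([config.chrom_length] * config.n_chroms),
    )
    n_total = config.n_origin_regions + config.n_center_regions
    lo, hi = config.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=n_total)
    classes = np.array(["origin_in_gene_body"] * config.n_origin_regions
                       + ["gene_body_center"] * config.n_center_regions)
    order = rng.permutation(n_total)
    lengths, classes = lengths[order], classes[order]

    chrom_lens = np.asarray(genome.chrom_lengths, dtype=np.float64)
    chrom_of = rng.choice(config.n_chroms, size=n_total,
                          p=chrom_lens / chrom_lens.sum())
    regions: list[AnchoredRegion] = []
    for ci, chrom in enumerate(genome.chrom_names):
        sel = np.nonzero(chrom_of == ci)[0]
        if sel.size == 0:
            continue
        chrom_len = genome.chrom_lengths[ci]
        total_genes = int(lengths[sel].sum())
        free = chrom_len - total_genes
        if free < 0:
            raise SimulationError(
                f"{chrom}: cannot place {sel.size} non-overlapping gene bodies "
                f"({total_genes} bp) on a {chrom_len} bp chromosome")
        # uniform non-overlapping placement: spread the free space as random
        # gaps before each gene (sorted uniform draws over the slack)
        gaps = np.sort(rng.integers(0, free + 1, size=sel.size))
        starts = gaps + np.concatenate([[0], np.cumsum(lengths[sel])[:-1]])
        for j, idx in enumerate(sel):
            start = int(starts[j])
            end = start + int(lengths[idx])
            strand = "+" if rng.random() < config.strand_prob else "-"
            if classes[idx] == "origin_in_gene_body":
                anchor = int(rng.integers(start + config.sub_half_width,
                                          end - config.sub_half_width))
            else:
                anchor = (start + end) // 2
            regions.append(AnchoredRegion(chrom=chrom, gene_start=start,
                                          gene_end=end, anchor=anchor,
                                          strand=strand,
                                          region_class=str(classes[idx])))
    return genome, regions


def build_rates(genome: GenomeLayout, regions: list[AnchoredRegion],
                config: SimConfig, role: str) -> dict[str, np.ndarray]:
    """Expected reads per bin: background everywhere, folds in case HO/CD.

    The fold placement reuses the oriented-window machinery, so flipping all
    gene strands mirrors the HO/CD rate blocks around each anchor exactly.
    """
    if role not in ("control", "case"):
        raise SimulationError(f"unknown sample role {role!r}")
    rates = _empty_counts(genome, config.bin_width, dtype=np.float64)
    for arr in rates.values():
        arr[:] = config.background_rate
    if role == "control":
        return rates
    spec = WindowSpec(half_width=config.sub_half_width, bin_width=config.bin_width)
    subs = split_sub_windows(spec, config.sub_half_width)
    offsets = spec.offsets
    for sub, fold in (("HO", config.fold_ho), ("CD", config.fold_cd)):
        if fold == 1.0:
            continue
        mask = (offsets >= subs[sub].offset_start) & (offsets < subs[sub].offset_end)
        for region in regions:
            if region.region_class != "origin_in_gene_body":
                continue
            starts = build_window(region, spec, genome)
            if starts is None:
                continue
            bins = starts[mask] // config.bin_width
            rates[region.chrom][bins] *= fold
    return rates


def _poisson_counts(rates: dict[str, np.ndarray], rng: np.random.Generator,
                    overdispersion: float) -> dict[str, np.ndarray]:
    counts = {}
    for chrom, lam in rates.items():
        if overdispersion > 0:
            shape = 1.0 / overdispersion
            lam = rng.gamma(shape, lam / shape)
        counts[chrom] = rng.poisson(lam)
    return counts


def _resize_library(counts: dict[str, np.ndarray], target: int,
                    rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Thin or inflate bin counts to the configured library size (multinomial)."""
    total = int(sum(arr.sum() for arr in counts.values()))
    if total == 0:
        raise SimulationError("no reads to resize")
    flat = np.concatenate([arr.astype(np.float64) for arr in counts.values()])
    new_flat = rng.multinomial(target, flat / total)
    out, pos = {}, 0
    for chrom, arr in counts.items():
        out[chrom] = new_flat[pos:pos + len(arr)].astype(np.int64)
        pos += len(arr)
    return out


def simulate_track(truth: SimTruth, role: str, seed: int,
                   sample_id: str = "") -> SignalTrack:
    """Draw a raw binned track directly from the per-bin expected rates.

    Equivalent in distribution to materializing reads and binning them with
    the 5'-end rule, but orders of magnitude faster for large genomes; use
    :func:`simulate_reads` when actual BED intervals are needed.
    """
    cfg = truth.config
    rng = np.random.default_rng(seed)
    rates = truth.rates_case if role == "case" else truth.rates_control
    counts = _poisson_counts(rates, rng, cfg.overdispersion)
    target = cfg.library_size_case if role == "case" else cfg.library_size_control
    if target is not None:
        if target <= 0:
            raise SimulationError("requested library size must be positive")
        counts = _resize_library(counts, target, rng)
    library = int(sum(arr.sum() for arr in counts.values()))
    return SignalTrack(genome=truth.genome, bin_width=cfg.bin_width,
                       counts=counts, library_size=library,
                       normalized=False, sample_id=sample_id or role)


def simulate_reads(truth: SimTruth, role: str, seed: int,
                   read_length: int = 100) -> pd.DataFrame:
    """Materialize a BED read set whose 5' ends realize the per-bin rates.

    Per bin the read count is Poisson with the configured rate (folds applied
    in the case sample's oriented sub-windows); each read is a
    ``read_length``-nt '+'-strand interval whose 5' end lies uniformly within
    its bin.  Totals are thinned/inflated to the configured library size.
    """
    track = simulate_track(truth, role, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    cfg = truth.config
    frames = []
    for chrom in truth.genome.chrom_names:
        counts = track.counts[chrom]
        chrom_len = truth.genome.length_of(chrom)
        nz = np.nonzero(counts)[0]
        starts_bins = np.repeat(nz * cfg.bin_width, counts[nz])
        five_prime = starts_bins + rng.integers(0, cfg.bin_width,
                                                size=len(starts_bins))
        five_prime = np.minimum(five_prime, chrom_len - 1)
        ends = np.minimum(five_prime + read_length, chrom_len)
        df = pd.DataFrame({"chrom": chrom, "start": five_prime, "end": ends,
                           "name": ".", "score": 0, "strand": "+"})
        frames.append(df.sort_values("start", kind="stable",
                                     ignore_index=True))
    return pd.concat(frames, ignore_index=True)


def make_truth(config: SimConfig) -> SimTruth:
    """Simulate regions and precompute expected rate fields for both roles."""
    genome, regions = simulate_regions(config)
    return SimTruth(
        config=config, genome=genome, regions=regions,
        rates_control=build_rates(genome, regions, config, "control"),
        rates_case=build_rates(genome, regions, config, "case"),
    )


def export_fixture(config: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Write a complete fixture bundle readable by the rest of the pipeline.

    Emits chrom.sizes, the 6-column region table, control/case BED read
    sets, a truth TSV of expected normalized window averages, and a JSON
    echo of the configuration.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = make_truth(config)
    seeds = np.random.SeedSequence(config.seed).generate_state(2) % (2**31)
    paths = {
        "chrom_sizes": outdir / "genome.chrom.sizes",
        "regions": outdir / "regions.tsv",
        "control": outdir / "control.bed",
        "case": outdir / "case.bed",
        "truth": outdir / "truth.tsv",
        "config": outdir / "sim_config.json",
    }
    truth.genome.to_file(paths["chrom_sizes"])
    write_regions(truth.regions, paths["regions"])
    for role in ("control", "case"):
        reads = simulate_reads(truth, role, int(seeds[0 if role == "control" else 1]))
        reads.to_csv(paths[role], sep="\t", header=False, index=False)
    rows = []
    for role in ("control", "case"):
        for label in ("HO", "CD", "full_quant"):
            rows.append({
                "role": role, "window": label,
                "rate_per_bin": config.background_rate * (
                    1.0 if role == "control" else
                    {"HO": config.fold_ho, "CD": config.fold_cd,
                     "full_quant": (config.fold_ho + config.fold_cd) / 2}[label]),
                "expected_normalized_average":
                    truth.expected_window_average(role, label),
            })
    pd.DataFrame(rows).to_csv(paths["truth"], sep="\t", index=False)
    cfg_dict = dataclasses.asdict(config)
    cfg_dict["gene_length_range"] = list(config.gene_length_range)
    paths["config"].write_text(json.dumps(cfg_dict, indent=2) + "\n")
    logger.info("fixture written to %s (%d regions)", outdir, len(truth.regions))
    return paths
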