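"""Oriented window aggregation, bootstrap metaprofile summaries and ECDFs.

A metaprofile is a regions x bins matrix of normalized signal over a fixed
window around each anchor, with every row already flipped into the
transcription-oriented frame.  Column-wise means (or medians) across regions
give the metaplot line; confidence bands come from bootstrapping regions —
the independent units of the analysis — with replacement.
"""

from __future__ import annotations

import logging
import warnings
from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .regions import AnchoredRegion, SubWindow, WindowSpec, build_window
from .tracks import SignalTrack, TrackError

logger = logging.getLogger(__name__)


class ProfileError(ValueError):
    pass


@dataclass
class MetaProfile:
    """Regions x bins matrix of oriented, normalized signal around anchors."""

    sample_id: str
    region_ids: list[str]
    offsets: np.ndarray  # bin-start offsets, strictly increasing
    matrix: np.ndarray   # shape (n_regions, n_bins)
    n_dropped: int       # regions whose window overran a chromosome end

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.region_ids,
                            columns=[int(o) for o in self.offsets])


@dataclass
class ProfileSummary:
    """Per-bin point estimate with percentile bootstrap band."""

    sample_id: str
    statistic: str          # "mean" or "median"
    offsets: np.ndarray
    point: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_boot: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "offset": self.offsets.astype(int),
            "point": self.point,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
        })


@dataclass
class WindowSummary:
    """Per-region average normalized count over one sub-window."""

    sample_id: str
    label: str
    region_ids: list[str]
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"region_id": self.region_ids,
                             "window": self.label,
                             "average": self.values})


def aggregate(track: SignalTrack, regions: Sequence[AnchoredRegion],
              spec: WindowSpec) -> MetaProfile:
    """Collect oriented per-bin signal for every region into a matrix.

    Row r, column j holds the track value of the j-th transcription-oriented
    bin of region r; minus-strand rows are genomic mirror images.  Regions
    whose window overruns a chromosome end are dropped (and counted in
    ``n_dropped``), not padded.
    """
    if not track.normalized:
        raise TrackError("aggregate expects a normalized track")
    if not regions:
        raise ProfileError("empty region list")
    rows, ids = [], []
    n_dropped = 0
    for region in regions:
        starts = build_window(region, spec, track.genome)
        if starts is None:
            n_dropped += 1
            continue
        bins = starts // spec.bin_width
        rows.append(track.counts[region.chrom][bins])
        ids.append(region.region_id)
    if n_dropped:
        logger.info("dropped %d/%d regions at chromosome edges",
                    n_dropped, len(regions))
    if not rows:
        raise ProfileError("all regions dropped at chromosome edges")
    return MetaProfile(sample_id=track.sample_id, region_ids=ids,
                       offsets=spec.offsets,
                       matrix=np.vstack(rows).astype(np.float64),
                       n_dropped=n_dropped)


def _column_stat(matrix: np.ndarray, statistic: str) -> np.ndarray:
    if statistic == "mean":
        return matrix.mean(axis=0)
    if statistic == "median":
        # lower interpolation keeps medians deterministic members of the sample
        return np.quantile(matrix, 0.5, axis=0, method="lower")
    raise ProfileError(f"unknown statistic {statistic!r}")


def summarize_profile(profile: MetaProfile, statistic: str = "mean",
                      n_boot: int = 10_000, seed: int = 0,
                      ci: tuple[float, float] = (2.5, 97.5)) -> ProfileSummary:
    """Column-wise mean/median across regions with a percentile bootstrap band.

    Regions (rows) are resampled with replacement ``n_boot`` times; the band
    is the (2.5, 97.5) percentile interval of the statistic over resamples.
    Deterministic for a fixed seed.
    """
    if n_boot < 1:
        raise ProfileError("n_boot must be >= 1")
    matrix = profile.matrix
    n_regions = matrix.shape[0]
    if n_regions == 1:
        warnings.warn("single-region profile: bootstrap band is degenerate",
                      stacklevel=2)
    point = _column_stat(matrix, statistic)
    rng = np.random.default_rng(seed)
    if statistic == "mean":
        # resampled mean = w @ matrix / n with multinomial resampling weights
        weights = rng.multinomial(n_regions, np.full(n_regions, 1 / n_regions),
                                  size=n_boot)
        boot = (weights @ matrix) / n_regions
    else:
        chunks = []
        chunk_size = max(1, 50_000_000 // (n_regions * matrix.shape[1] + 1))
        done = 0
        while done < n_boot:
            k = min(chunk_size, n_boot - done)
            idx = rng.integers(0, n_regions, size=(k, n_regions))
            chunks.append(_column_stat_3d_median(matrix[idx]))
            done += k
        boot = np.vstack(chunks)
    lo, hi = np.percentile(boot, ci, axis=0)
    return ProfileSummary(sample_id=profile.sample_id, statistic=statistic,
                          offsets=profile.offsets, point=point,
                          ci_low=lo, ci_high=hi, n_boot=n_boot, seed=seed)


def _column_stat_3d_median(cube: np.ndarray) -> np.ndarray:
    return np.quantile(cube, 0.5, axis=1, method="lower")


def window_average(profile: MetaProfile, sub: SubWindow) -> WindowSummary:
    """Per-region mean of the bins whose offsets fall in the sub-window."""
    mask = (profile.offsets >= sub.offset_start) & (profile.offsets < sub.offset_end)
    if not mask.any():
        raise ProfileError(f"sub-window {sub.label} overlaps no bins")
    return WindowSummary(sample_id=profile.sample_id, label=sub.label,
                         region_ids=profile.region_ids,
                         values=profile.matrix[:, mask].mean(axis=1))


class ECDF:
    """Right-continuous empirical cumulative distribution function.

    ``F(x)`` is the fraction of observations <= x; ties are merged into a
    single step.  ``F(min) - eps = 0`` and ``F(max) = 1``.
    """

    def __init__(self, values: np.ndarray | Sequence[float]):
        values = np.asarray(values, dtype=np.float64)
        if values.size == 0:
            raise ProfileError("empty input to ECDF")
        self.x, counts = np.unique(values, return_counts=True)
        self.y = np.cumsum(counts) / values.size

    def __call__(self, q: float | np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.x, np.asarray(q, dtype=np.float64),
                              side="right")
        return np.concatenate([[0.0], self.y])[idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"value": self.x, "cumulative_fraction": self.y})


def ecdf(values: np.ndarray | Sequence[float]) -> ECDF:
    """ECDF of per-region window averages (Fig.-1C-style cumulative curves)."""
    return ECDF(values)
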