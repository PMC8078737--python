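"""Sample-vs-control Fisher exact enrichment over quantification windows.

For each sample the in-window normalized read count (summed over every
region's sub-window, rounded half-to-even) is set against the remainder of
its 10M-normalized library, giving a 2x2 contingency table per sample and
sub-window.  Two-sided Fisher exact p-values are Bonferroni-corrected over
the whole batch of tests run in one invocation.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .regions import AnchoredRegion, SubWindow, WindowSpec, build_window
from .tracks import SignalTrack, TrackError

logger = logging.getLogger(__name__)


class EnrichmentError(ValueError):
    pass


@dataclass(frozen=True)
class ContingencyTable:
    """(sample in-window, sample rest, control in-window, control rest)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise EnrichmentError("negative contingency cell")

    @property
    def degenerate(self) -> bool:
        """True when a margin is zero and the test carries no information."""
        return (self.a + self.c == 0 or self.b + self.d == 0
                or self.a + self.b == 0 or self.c + self.d == 0)

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass
class EnrichmentResult:
    sample_id: str
    window: str
    table: ContingencyTable
    odds_ratio: float
    p_raw: float
    p_adj: float
    m: int


def window_total(track: SignalTrack, regions: Sequence[AnchoredRegion],
                 sub: SubWindow, spec: WindowSpec) -> float:
    """Sum of normalized counts over all regions' oriented sub-window bins."""
    offsets = spec.offsets
    mask = (offsets >= sub.offset_start) & (offsets < sub.offset_end)
    if not mask.any():
        raise EnrichmentError(f"sub-window {sub.label} overlaps no bins")
    total = 0.0
    for region in regions:
        starts = build_window(region, spec, track.genome)
        if starts is None:
            continue
        bins = starts[mask] // spec.bin_width
        total += float(track.counts[region.chrom][bins].sum())
    return total


def build_table(sample: SignalTrack, control: SignalTrack,
                regions: Sequence[AnchoredRegion], sub: SubWindow,
                spec: WindowSpec = WindowSpec()) -> ContingencyTable:
    """Contingency table of rounded normalized in-window counts vs the rest.

    ``a`` is the sample's normalized count summed over the sub-window of all
    regions, rounded half-to-even; ``b`` the remainder of its 10M-scaled
    library; ``c``/``d`` likewise for the control.
    """
    for track, who in ((sample, "sample"), (control, "control")):
        if not track.normalized:
            raise TrackError(f"{who} track is not normalized")
    if sample.norm_target != control.norm_target:
        raise EnrichmentError("sample and control norm_target differ")
    target = sample.norm_target
    a = int(np.round(window_total(sample, regions, sub, spec)))
    c = int(np.round(window_total(control, regions, sub, spec)))
    if a > target or c > target:
        raise EnrichmentError(
            "in-window count exceeds the normalization target; "
            "input does not look normalized")
    table = ContingencyTable(a, target - a, c, target - c)
    if table.degenerate:
        logger.warning("degenerate contingency table for window %s", sub.label)
    return table


def fisher_exact(table: ContingencyTable) -> tuple[float, float]:
    """Two-sided Fisher exact test: (odds ratio, raw p).

    The two-sided p sums hypergeometric probabilities of all tables with the
    observed margins that are no more probable than the observed one
    (minimum-likelihood rule).  The odds ratio is the sample estimate
    a*d / (b*c); 0/0 yields NaN (undefined).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if table.degenerate:
        return (np.nan, 1.0)
    if b * c == 0:
        odds = np.inf if a * d > 0 else np.nan
    else:
        odds = (a * d) / (b * c)
    res = stats.fisher_exact(table.as_array(), alternative="two-sided")
    return (float(odds), float(res.pvalue))


def bonferroni(p_values: Sequence[float], m: int | None = None) -> list[float]:
    """Bonferroni adjustment: each p multiplied by the family size, capped at 1."""
    p_values = list(p_values)
    if m is None:
        m = len(p_values)
    if m < len(p_values):
        raise EnrichmentError("family size m smaller than the number of p-values")
    for p in p_values:
        if not (0.0 <= p <= 1.0):
            raise EnrichmentError(f"p-value {p} outside [0, 1]")
    return [min(1.0, m * p) for p in p_values]


def compare_samples(samples: Mapping[str, SignalTrack], control: SignalTrack,
                    regions: Sequence[AnchoredRegion],
                    sub_windows: Sequence[SubWindow],
                    spec: WindowSpec = WindowSpec()) -> list[EnrichmentResult]:
    """One Fisher test per (sample, sub-window), Bonferroni over the batch.

    The correction family size ``m`` is the number of tests in this
    invocation (samples x sub-windows).  Results are sorted by sample id,
    then by the given sub-window order.
    """
    if not samples:
        raise EnrichmentError("empty sample map")
    m = len(samples) * len(sub_windows)
    results: list[EnrichmentResult] = []
    for sample_id in sorted(samples):
        for sub in sub_windows:
            table = build_table(samples[sample_id], control, regions, sub, spec)
            odds, p_raw = fisher_exact(table)
            results.append(EnrichmentResult(
                sample_id=sample_id, window=sub.label, table=table,
                odds_ratio=odds, p_raw=p_raw,
                p_adj=min(1.0, m * p_raw), m=m))
    return results


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Tidy TSV-ready view: sample, window, a, b, c, d, OR, p_raw, p_adj, m."""
    return pd.DataFrame([{
        "sample": r.sample_id, "window": r.window,
        "a": r.table.a, "b": r.table.b, "c": r.table.c, "d": r.table.d,
        "odds_ratio": r.odds_ratio, "p_raw": r.p_raw,
        "p_adj": r.p_adj, "m": r.m,
    } for r in results])
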