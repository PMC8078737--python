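import numpy as np
import pytest
from statsmodels.distributions.empirical_distribution import ECDF as SmECDF

from conftest import track_from_counts
from oracles import brute_aggregate, brute_window_average
from dripmeta import (AnchoredRegion, GenomeLayout, MetaProfile, WindowSpec,
                      aggregate, ecdf, split_sub_windows, summarize_profile,
                      window_average)
from dripmeta.metaprofile import ProfileError
from dripmeta.tracks import TrackError


def random_track(rng, genome):
    return track_from_counts(
        genome,
        {c: rng.random(-(-genome.length_of(c) // 100)) * 10
         for c in genome.chrom_names})


def test_aggregate_matches_loop_oracle(rng, toy_genome, toy_regions, small_spec):
    track = random_track(rng, toy_genome)
    prof = aggregate(track, toy_regions, small_spec)
    expected = brute_aggregate(track.counts, toy_regions,
                               small_spec.half_width, small_spec.bin_width)
    assert np.array_equal(prof.matrix, expected)
    assert prof.matrix.shape == (3, small_spec.n_bins)
    assert np.all(np.diff(prof.offsets) > 0)


def test_aggregate_constant_track(toy_genome, toy_regions, small_spec):
    track = track_from_counts(
        toy_genome, {c: np.full(-(-toy_genome.length_of(c) // 100), 7.5)
                     for c in toy_genome.chrom_names})
    prof = aggregate(track, toy_regions, small_spec)
    assert np.all(prof.matrix == 7.5)  # constant field, any strand


def test_aggregate_minus_strand_row_is_reversed(rng, toy_genome, small_spec):
    track = random_track(rng, toy_genome)
    plus = AnchoredRegion("chr1", 50_000, 90_000, 62_000, "+", "origin_in_gene_body")
    minus = AnchoredRegion("chr1", 50_000, 90_000, 62_000, "-", "origin_in_gene_body")
    rows = aggregate(track, [plus, minus], small_spec).matrix
    assert np.array_equal(rows[1], rows[0][::-1])


def test_aggregate_drops_edge_regions_and_requires_normalized(toy_genome, small_spec):
    track = track_from_counts(toy_genome, {})
    edge = AnchoredRegion("chr1", 0, 20_000, 500, "+", "origin_in_gene_body")
    ok = AnchoredRegion("chr1", 10_000, 40_000, 25_000, "+", "origin_in_gene_body")
    prof = aggregate(track, [edge, ok], small_spec)
    assert prof.n_dropped == 1 and len(prof.region_ids) == 1
    with pytest.raises(ProfileError):
        aggregate(track, [], small_spec)
    raw = track_from_counts(toy_genome, {}, normalized=False)
    with pytest.raises(TrackError):
        aggregate(raw, [ok], small_spec)


def test_mirror_symmetric_signal_is_strand_flip_invariant(toy_genome, small_spec):
    """Signal that is palindromic about each anchor gives the same mean
    profile whichever strand the genes carry."""
    sym = np.zeros(1000)
    anchor_bin = 250  # anchor 25_000
    for d in range(10):
        sym[anchor_bin - 1 - d] = sym[anchor_bin + d] = 10 - d
    track = track_from_counts(toy_genome, {"chr1": sym})
    mk = lambda s: AnchoredRegion("chr1", 10_000, 40_000, 25_000, s,
                                  "origin_in_gene_body")
    p_plus = aggregate(track, [mk("+")], small_spec)
    p_minus = aggregate(track, [mk("-")], small_spec)
    assert np.array_equal(p_plus.matrix.mean(axis=0),
                          p_minus.matrix.mean(axis=0))


def make_profile(matrix):
    n_bins = matrix.shape[1]
    return MetaProfile(sample_id="s", region_ids=[f"r{i}" for i in
                                                  range(matrix.shape[0])],
                       offsets=np.arange(n_bins) * 100 - n_bins * 50,
                       matrix=np.asarray(matrix, dtype=float), n_dropped=0)


@pytest.mark.parametrize("statistic", ["mean", "median"])
def test_summary_identical_rows_zero_width_band(statistic):
    prof = make_profile(np.tile([1.0, 2.0, 3.0, 4.0], (20, 1)))
    s = summarize_profile(prof, statistic, n_boot=200, seed=1)
    assert np.array_equal(s.point, [1.0, 2.0, 3.0, 4.0])
    assert np.array_equal(s.ci_low, s.point)
    assert np.array_equal(s.ci_high, s.point)


def test_summary_seeded_determinism(rng):
    prof = make_profile(rng.random((30, 12)))
    a = summarize_profile(prof, "mean", n_boot=300, seed=9)
    b = summarize_profile(prof, "mean", n_boot=300, seed=9)
    assert np.array_equal(a.ci_low, b.ci_low)
    assert np.array_equal(a.ci_high, b.ci_high)
    assert np.all(a.ci_low <= a.point) and np.all(a.point <= a.ci_high)


def test_summary_single_region_warns(rng):
    prof = make_profile(rng.random((1, 8)))
    with pytest.warns(UserWarning, match="degenerate"):
        s = summarize_profile(prof, "mean", n_boot=50, seed=0)
    assert np.array_equal(s.ci_low, s.point)


def test_bootstrap_band_covers_truth_at_nominal_rate(rng):
    """95% bands over 50 iid standard-normal regions cover the true mean 0
    at roughly the nominal rate across 240 bins."""
    prof = make_profile(rng.standard_normal((50, 240)))
    s = summarize_profile(prof, "mean", n_boot=1_000, seed=4)
    covered = np.mean((s.ci_low <= 0) & (0 <= s.ci_high))
    assert 0.85 <= covered <= 1.0


def test_bootstrap_band_shrinks_with_regions(rng):
    wide = make_profile(rng.standard_normal((40, 60)))
    narrow = make_profile(rng.standard_normal((160, 60)))
    w1 = summarize_profile(wide, "mean", 500, seed=2)
    w2 = summarize_profile(narrow, "mean", 500, seed=2)
    assert (w1.ci_high - w1.ci_low).mean() > (w2.ci_high - w2.ci_low).mean()


def test_window_average_matches_slice_oracle(rng, toy_genome, toy_regions,
                                             small_spec):
    track = random_track(rng, toy_genome)
    prof = aggregate(track, toy_regions, small_spec)
    subs = split_sub_windows(small_spec, sub_half_width=500)
    for sub in subs.values():
        got = window_average(prof, sub).values
        expected = brute_window_average(prof.matrix, prof.offsets,
                                        sub.offset_start, sub.offset_end)
        assert np.allclose(got, expected, rtol=1e-14)


def test_window_average_partition_arithmetic(rng, toy_genome, toy_regions,
                                             small_spec):
    track = random_track(rng, toy_genome)
    prof = aggregate(track, toy_regions, small_spec)
    subs = split_sub_windows(small_spec, sub_half_width=500)
    ho = window_average(prof, subs["HO"]).values
    cd = window_average(prof, subs["CD"]).values
    full = window_average(prof, subs["full_quant"]).values
    assert np.allclose(full, (ho + cd) / 2, rtol=1e-12)


def test_window_average_constant_and_empty(small_spec):
    prof = make_profile(np.full((5, 20), 3.25))
    subs = split_sub_windows(small_spec, sub_half_width=500)
    assert np.all(window_average(prof, subs["HO"]).values == 3.25)
    from dripmeta import SubWindow
    with pytest.raises(ProfileError):
        window_average(prof, SubWindow("off", 10_000, 10_100))


def test_ecdf_basic_values():
    f = ecdf([1.0, 2.0, 3.0])
    assert f(2.0) == pytest.approx(2 / 3)
    assert f(0.99) == 0.0
    assert f(3.0) == 1.0
    g = ecdf([5.0, 5.0, 5.0])  # ties merge into one step
    assert len(g.x) == 1 and g(4.999) == 0.0 and g(5.0) == 1.0
    with pytest.raises(ProfileError):
        ecdf([])


def test_ecdf_matches_statsmodels(rng):
    values = rng.random(500)
    ours = ecdf(values)
    theirs = SmECDF(values)
    grid = rng.random(100)
    assert np.allclose(ours(grid), theirs(grid))


def test_ecdf_uniform_kolmogorov_distance(rng):
    values = rng.random(1_000)
    f = ecdf(values)
    grid = np.linspace(0, 1, 2_001)
    dist = np.abs(f(grid) - grid).max()
    assert dist < 1.63 / np.sqrt(1_000)  # 1% critical value
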