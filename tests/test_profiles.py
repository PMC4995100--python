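"""Track building and dyad-centered profile aggregation."""

import numpy as np
import pytest

from qznorm.genome_io import Track, ValidationError
from qznorm.profiles import (
    compile_meta,
    coverage_track,
    midpoint_track,
    profile_matrix,
    window_signal,
)

from conftest import make_dyads, make_fragments, random_fragments, random_track


def brute_force_coverage(frags, genome):
    """Per-fragment loop oracle for coverage."""
    arrs = {c: np.zeros(n) for c, n in genome.lengths.items()}
    for _, r in frags.frame.iterrows():
        arrs[r["chrom"]][r["start"] : r["end"]] += r["count"]
    return arrs


class TestCoverageTrack:
    def test_single_fragment_extent(self, toy_genome):
        track = coverage_track(make_fragments([("chrI", 100, 103)]), toy_genome)
        arr = track.data["chrI"]
        assert arr[99] == 0 and list(arr[100:103]) == [1, 1, 1] and arr[103] == 0

    def test_duplicate_fragments_stack(self, toy_genome):
        track = coverage_track(
            make_fragments([("chrI", 10, 60), ("chrI", 10, 60)]), toy_genome
        )
        assert set(track.data["chrI"][10:60]) == {2.0}

    def test_matches_per_fragment_loop_oracle(self, toy_genome, rng):
        frags = random_fragments(toy_genome, 200, rng)
        track = coverage_track(frags, toy_genome)
        oracle = brute_force_coverage(frags, toy_genome)
        for c in toy_genome.chroms:
            np.testing.assert_array_equal(track.data[c], oracle[c])

    def test_total_equals_sum_of_lengths(self, toy_genome, rng):
        frags = random_fragments(toy_genome, 150, rng)
        lengths = (frags.frame["end"] - frags.frame["start"]) * frags.frame["count"]
        assert coverage_track(frags, toy_genome).total() == pytest.approx(lengths.sum())


class TestMidpointTrack:
    @pytest.mark.parametrize(
        "start,end,mid", [(100, 250, 175), (100, 103, 101), (0, 147, 73)]
    )
    def test_floor_midpoint(self, toy_genome, start, end, mid):
        track = midpoint_track(make_fragments([("chrI", start, end)]), toy_genome)
        assert track.data["chrI"][mid] == 1 and track.total() == 1

    def test_total_equals_fragment_count(self, toy_genome, rng):
        frags = random_fragments(toy_genome, 300, rng)
        assert midpoint_track(frags, toy_genome).total() == frags.total_count

    def test_additive_over_fragment_subsets(self, toy_genome, rng):
        a = random_fragments(toy_genome, 80, rng)
        b = random_fragments(toy_genome, 120, rng)
        both = make_fragments(
            list(zip(a.frame["chrom"], a.frame["start"], a.frame["end"]))
            + list(zip(b.frame["chrom"], b.frame["start"], b.frame["end"]))
        )
        t_both = midpoint_track(both, toy_genome)
        t_a = midpoint_track(a, toy_genome)
        t_b = midpoint_track(b, toy_genome)
        for c in toy_genome.chroms:
            np.testing.assert_array_equal(t_both.data[c], t_a.data[c] + t_b.data[c])


class TestCompileMeta:
    def test_delta_maps_to_offset(self, toy_genome):
        track = Track.zeros(toy_genome)
        track.data["chrI"][510] = 2.0
        dyads = make_dyads([("chrI", 500, "+", "plus_one")])
        meta = compile_meta(track, dyads, flank=50)
        assert meta.values[np.flatnonzero(meta.offsets == 10)[0]] == 2.0

    def test_minus_strand_mirrors_offset(self, toy_genome):
        track = Track.zeros(toy_genome)
        track.data["chrI"][510] = 2.0
        dyads = make_dyads([("chrI", 500, "-", "plus_one")])
        meta = compile_meta(track, dyads, flank=50, orient_by_strand=True)
        assert meta.values[np.flatnonzero(meta.offsets == -10)[0]] == 2.0

    def test_matches_naive_per_dyad_loop(self, toy_genome, rng):
        track = random_track(toy_genome, rng)
        rows = [("chrI", int(d), s, "plus_one") for d, s in
                zip(rng.integers(100, 1900, 12), rng.choice(["+", "-"], 12))]
        dyads = make_dyads(rows)
        flank = 60
        meta = compile_meta(track, dyads, flank=flank)
        expected = np.zeros(2 * flank + 1)
        for chrom, d, s, _ in rows:
            sl = track.data[chrom][d - flank : d + flank + 1]
            expected += sl[::-1] if s == "-" else sl
        np.testing.assert_allclose(meta.values, expected)

    def test_empty_dyads_error(self, toy_genome):
        import pandas as pd
        from qznorm.genome_io import DyadAnnotation
        empty = DyadAnnotation(pd.DataFrame(columns=["chrom", "dyad", "strand", "role"]))
        with pytest.raises(ValidationError):
            compile_meta(Track.zeros(toy_genome), empty, flank=10)

    def test_edge_clipped_dyads_dropped_not_padded(self, toy_genome):
        track = Track.zeros(toy_genome)
        track.data["chrI"][:] = 1.0
        dyads = make_dyads(
            [("chrI", 5, "+", "plus_one"), ("chrI", 1000, "+", "plus_one")]
        )
        meta = compile_meta(track, dyads, flank=50)
        assert meta.n_dyads == 1 and meta.n_dropped == 1
        assert np.all(meta.values == 1.0)  # no zero-padded tail dilution


class TestWindowSignal:
    def test_uniform_track_gives_window_width(self, toy_genome):
        track = Track({c: np.ones(n) for c, n in toy_genome.lengths.items()})
        dyads = make_dyads([("chrI", 500, "+", "plus_one")])
        assert window_signal(track, dyads, halfwidth=60)[0] == 120.0

    def test_half_open_boundary(self, toy_genome):
        track = Track.zeros(toy_genome)
        track.data["chrI"][440] = 5.0  # dyad - 60: included
        track.data["chrI"][560] = 7.0  # dyad + 60: excluded
        dyads = make_dyads([("chrI", 500, "+", "plus_one")])
        assert window_signal(track, dyads, halfwidth=60)[0] == 5.0

    def test_matches_slice_sum_oracle(self, toy_genome, rng):
        track = random_track(toy_genome, rng)
        positions = rng.integers(100, 1400, 15)
        dyads = make_dyads([("chrII", int(p), ".", "generic") for p in positions])
        got = window_signal(track, dyads, halfwidth=60)
        want = [track.data["chrII"][p - 60 : p + 60].sum() for p in positions]
        np.testing.assert_allclose(got, want)

    def test_edge_dyad_flagged_missing(self, toy_genome):
        track = Track({c: np.ones(n) for c, n in toy_genome.lengths.items()})
        dyads = make_dyads([("chrI", 10, "+", "plus_one")])
        assert np.isnan(window_signal(track, dyads, halfwidth=60)[0])


class TestProfileMatrix:
    def test_rows_sorted_by_descending_key(self, toy_genome):
        track = Track({c: np.ones(n) for c, n in toy_genome.lengths.items()})
        dyads = make_dyads(
            [("chrI", 300, "+", "plus_one"), ("chrI", 600, "+", "plus_one"),
             ("chrI", 900, "+", "plus_one")]
        )
        mat = profile_matrix(track, dyads, flank=50, sort_key=np.array([1.0, 2.0, 3.0]))
        assert list(mat.dyads["dyad"]) == [900, 600, 300]

    def test_ties_break_in_genomic_order(self, toy_genome):
        track = Track({c: np.ones(n) for c, n in toy_genome.lengths.items()})
        dyads = make_dyads(
            [("chrI", 900, "+", "plus_one"), ("chrI", 300, "+", "plus_one")]
        )
        mat = profile_matrix(track, dyads, flank=50, sort_key=np.array([1.0, 1.0]))
        assert list(mat.dyads["dyad"]) == [300, 900]

    def test_missing_key_dropped_and_counted(self, toy_genome):
        track = Track({c: np.ones(n) for c, n in toy_genome.lengths.items()})
        dyads = make_dyads(
            [("chrI", 300, "+", "plus_one"), ("chrI", 600, "+", "plus_one")]
        )
        mat = profile_matrix(track, dyads, flank=50, sort_key=np.array([1.0, np.nan]))
        assert len(mat) == 1 and mat.n_dropped == 1

    def test_row_equals_singleton_compile_meta(self, toy_genome, rng):
        track = random_track(toy_genome, rng)
        dyads = make_dyads(
            [("chrI", 400, "+", "plus_one"), ("chrI", 800, "-", "plus_one")]
        )
        mat = profile_matrix(track, dyads, flank=40)
        for i in range(len(mat)):
            single = make_dyads([tuple(mat.dyads.iloc[i][["chrom", "dyad", "strand", "role"]])])
            meta = compile_meta(track, single, flank=40)
            np.testing.assert_allclose(mat.matrix[i], meta.values)

    def test_column_mean_matches_meta_mean(self, toy_genome, rng):
        track = random_track(toy_genome, rng)
        dyads = make_dyads(
            [("chrI", 400, "+", "plus_one"), ("chrI", 800, "+", "plus_one"),
             ("chrII", 700, "+", "plus_one")]
        )
        mat = profile_matrix(track, dyads, flank=30)
        meta = compile_meta(track, dyads, flank=30)
        np.testing.assert_allclose(mat.column_mean(), meta.mean)
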