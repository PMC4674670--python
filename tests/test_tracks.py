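"""Cytosine-report parsing, strand collapse, and level summaries."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methcanyon.tracks import (genomewide_level_histogram, pool_tracks,
                               read_cytosine_report, region_level, site_level,
                               write_cytosine_report)

from conftest import make_track


def test_plus_minus_records_collapse_to_one_dyad(tmp_path):
    path = tmp_path / "r.tsv"
    path.write_text("chr1\t100\t+\t3\t1\tCpG\tCGA\n"
                    "chr1\t101\t-\t1\t3\tCpG\tCGT\n")
    track = read_cytosine_report(path)
    c = track.chroms["chr1"]
    assert list(c.pos) == [99]          # 0-based C of the dyad
    assert list(c.m) == [4] and list(c.u) == [4]


def test_empty_report_yields_empty_track(tmp_path):
    path = tmp_path / "empty.tsv"
    path.write_text("")
    assert read_cytosine_report(path).n_sites == 0


def test_non_cpg_context_rows_are_skipped(tmp_path):
    path = tmp_path / "r.tsv"
    path.write_text("chr1\t10\t+\t1\t1\tCHH\tCAA\nchr1\t50\t+\t2\t2\tCpG\tCGG\n")
    track = read_cytosine_report(path)
    assert track.n_sites == 1


@pytest.mark.parametrize("line,err", [
    ("chr1\t10\t+\t1.5\t1\tCpG\tCGA", "non-integer"),
    ("chr1\t10\t*\t1\t1\tCpG\tCGA", "strand"),
    ("chr1\t10\t+\t1", "columns"),
])
def test_malformed_lines_raise_with_line_number(tmp_path, line, err):
    path = tmp_path / "bad.tsv"
    path.write_text(line + "\n")
    with pytest.raises(ValueError, match=err):
        read_cytosine_report(path)


def test_duplicate_same_strand_record_rejected(tmp_path):
    path = tmp_path / "dup.tsv"
    path.write_text("chr1\t10\t+\t1\t1\tCpG\tCGA\nchr1\t10\t+\t2\t2\tCpG\tCGA\n")
    with pytest.raises(ValueError, match="duplicate"):
        read_cytosine_report(path)


def test_track_round_trips_through_report(tmp_path, sim_small):
    track = sim_small.tracks_wt[0]
    path = tmp_path / "rt.tsv"
    write_cytosine_report(track, path)
    back = read_cytosine_report(path)
    for chrom, c in track.chroms.items():
        b = back.chroms[chrom]
        assert np.array_equal(c.pos, b.pos)
        assert np.array_equal(c.m, b.m) and np.array_equal(c.u, b.u)


@pytest.mark.parametrize("m,u,minc,expected", [
    (0, 5, 1, 0.0),
    (7, 0, 1, 1.0),
    (2, 1, 5, math.nan),
    (2, 2, 5, math.nan),
    (3, 2, 5, 0.6),
])
def test_site_level_applies_coverage_floor(m, u, minc, expected):
    got = site_level(m, u, minc)
    if math.isnan(expected):
        assert math.isnan(got)
    else:
        assert got == pytest.approx(expected)


def test_region_level_is_count_weighted():
    track = make_track({"chr1": [(10, 3, 1), (20, 1, 3)]})
    assert region_level(track, "chr1", 0, 100) == pytest.approx(4 / 8)


def test_region_level_matches_direct_summation_on_random_intervals():
    rng = np.random.default_rng(0)
    pos = np.sort(rng.choice(100_000, size=200, replace=False))
    m = rng.integers(0, 30, size=200)
    u = rng.integers(0, 30, size=200)
    track = make_track({"chr1": list(zip(pos.tolist(), m.tolist(), u.tolist()))})
    for _ in range(200):
        a, b = sorted(rng.integers(0, 100_000, size=2))
        inside = (pos >= a) & (pos < b) & (m + u > 0)
        expected = (m[inside].sum() / (m + u)[inside].sum()
                    if (m + u)[inside].sum() else math.nan)
        got = region_level(track, "chr1", int(a), int(b))
        if math.isnan(expected):
            assert math.isnan(got)
        else:
            assert got == pytest.approx(expected)


def test_region_level_unknown_chromosome_errors():
    track = make_track({"chr1": [(10, 1, 1)]})
    with pytest.raises(KeyError):
        region_level(track, "chrX", 0, 100)


def test_cpg_free_interval_is_missing():
    track = make_track({"chr1": [(10, 1, 1)]})
    assert math.isnan(region_level(track, "chr1", 500, 600))


@given(st.lists(st.tuples(st.integers(0, 20), st.integers(0, 20)),
                min_size=1, max_size=20))
@settings(deadline=None, max_examples=50)
def test_weighted_level_invariant_to_splitting_reads_across_replicates(counts):
    """Pooling replicates that split a site's reads leaves the level unchanged."""
    if sum(a + b for a, b in counts) == 0:
        return
    whole = make_track({"chr1": [(100, sum(a for a, _ in counts),
                                  sum(b for _, b in counts))]})
    parts = [make_track({"chr1": [(100, a, b)]}, sample=f"r{i}")
             for i, (a, b) in enumerate(counts)]
    pooled = pool_tracks(parts)
    assert region_level(pooled, "chr1", 0, 200) == pytest.approx(
        region_level(whole, "chr1", 0, 200))


def test_histogram_counts_every_covered_site():
    track = make_track({"chr1": [(10, 5, 0), (20, 5, 0), (30, 0, 0)]})
    counts, edges = genomewide_level_histogram(track, 0.1)
    assert counts.sum() == 2            # zero-coverage site excluded
    assert counts[-1] == 2              # level 1.0 mass lands in the top bin


def test_histogram_rejects_non_divisor_bin_width():
    track = make_track({"chr1": [(10, 1, 1)]})
    with pytest.raises(ValueError):
        genomewide_level_histogram(track, 0.3)
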