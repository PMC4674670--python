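"""Region-promoter links, contingency statistics, enhancer density maps."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methcanyon.annotation import make_genes
from methcanyon.integration import (central_region_level_shift,
                                    chi_square_test, delta_vs_expression_table,
                                    direction_contingency,
                                    enhancer_density_map, fraction_report,
                                    interval_point_distance,
                                    link_regions_to_promoters)

from conftest import make_track


# --- promoter links ---------------------------------------------------------

def _genes_at(tss_list):
    return make_genes([f"g{i}" for i in range(len(tss_list))],
                      ["chr1"] * len(tss_list), tss_list,
                      [t + 5_000 for t in tss_list], ["+"] * len(tss_list))


def test_overlapping_region_links_at_distance_zero():
    genes = _genes_at([30_000])
    regions = pd.DataFrame({"chrom": ["chr1"], "start": [28_000],
                            "end": [32_000]})
    links = link_regions_to_promoters(regions, genes)
    assert len(links) == 1 and links.iloc[0]["distance"] == 0


def test_two_kb_link_rule_is_strict():
    genes = _genes_at([30_000])
    near = pd.DataFrame({"chrom": ["chr1"], "start": [26_000], "end": [28_002]})
    far = pd.DataFrame({"chrom": ["chr1"], "start": [26_000], "end": [28_001]})
    assert interval_point_distance(26_000, 28_002, 30_000) == 1_999
    assert len(link_regions_to_promoters(near, genes)) == 1
    assert interval_point_distance(26_000, 28_001, 30_000) == 2_000
    assert len(link_regions_to_promoters(far, genes)) == 0


def test_region_spanning_two_promoters_links_twice():
    genes = _genes_at([30_000, 33_000])
    region = pd.DataFrame({"chrom": ["chr1"], "start": [29_000],
                           "end": [34_000]})
    links = link_regions_to_promoters(region, genes)
    assert sorted(links["gene_id"]) == ["g0", "g1"]
    assert (links["distance"] == 0).all()


# --- contingency ------------------------------------------------------------

def test_balanced_table_has_zero_chi2():
    res = chi_square_test([[10, 10], [10, 10]])
    assert res.chi2 == 0.0 and res.p == 1.0


def test_doubling_cells_doubles_chi2():
    a = chi_square_test([[30, 10], [15, 25]])
    b = chi_square_test([[60, 20], [30, 50]])
    assert b.chi2 == pytest.approx(2 * a.chi2)


def test_chi2_matches_independent_implementation_on_random_tables():
    rng = np.random.default_rng(0)
    for _ in range(100):
        table = rng.integers(1, 200, size=(2, 2))
        res = chi_square_test(table)
        chi2, p, dof, exp = stats.chi2_contingency(table, correction=False)
        assert res.chi2 == pytest.approx(chi2)
        assert res.p == pytest.approx(p)
        assert np.allclose(res.expected, exp)
        assert np.isclose(res.observed.sum(), res.expected.sum())


def test_shrinking_canyon_direction_table():
    """86 DE genes at shrinking canyons (67 down / 19 up) against the
    remaining DE genes from the 1,406-up / 732-down genome-wide split."""
    res = direction_contingency((67, 19), (732 - 67, 1_406 - 19))
    obs = np.array([[67, 19], [665, 1_387]], dtype=float)
    expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
    assert res.chi2 == pytest.approx(((obs - expected) ** 2 / expected).sum())
    assert res.chi2 == pytest.approx(75.893, abs=0.01)
    assert res.p < 1e-10


def test_zero_margin_table_is_degenerate():
    with pytest.raises(ValueError, match="margin"):
        chi_square_test([[0, 0], [5, 7]])


@pytest.mark.parametrize("num,den,dec,expected", [
    (3_864, 5_555, 0, 70.0),
    (465, 1_135, 0, 41.0),
    (93, 524, 1, 17.7),
    (105, 846, 1, 12.4),
    (1_539, 12_005, 1, 12.8),
    (1, 8, 0, 13.0),            # 12.5 rounds half-away-from-zero
])
def test_fraction_report_rounding(num, den, dec, expected):
    assert fraction_report(num, den, dec) == expected


def test_fraction_report_zero_denominator():
    with pytest.raises(ValueError):
        fraction_report(1, 0)


# --- scatter table ----------------------------------------------------------

def test_scatter_is_empty_without_de_genes():
    de = pd.DataFrame({"gene_id": ["a"], "log2_fold_change": [0.1],
                       "status": ["ns"]})
    deltas = pd.DataFrame({"gene_id": ["a"], "delta_body": [0.0],
                           "delta_promoter": [0.0]})
    assert delta_vs_expression_table(deltas, de).empty


def test_scatter_flags_missing_deltas():
    de = pd.DataFrame({"gene_id": ["a", "b"], "log2_fold_change": [1.0, -1.0],
                       "status": ["up", "down"]})
    deltas = pd.DataFrame({"gene_id": ["a"], "delta_body": [0.02],
                           "delta_promoter": [0.01]})
    table = delta_vs_expression_table(deltas, de)
    assert len(table) == 2
    assert table.set_index("gene_id").loc["b", "delta_missing"]


# --- enhancer density maps --------------------------------------------------

def _enhancers():
    return pd.DataFrame({"chrom": ["chr1"], "start": [10_000],
                         "end": [12_000], "name": ["e0"]})


def test_fully_methylated_cpgs_fill_top_level_row():
    track = make_track({"chr1": [(p, 10, 0) for p in range(10_000, 12_000, 40)]})
    dmap = enhancer_density_map(track, _enhancers())
    assert dmap.counts[-1].sum() == dmap.total == 50
    assert dmap.counts[:-1].sum() == 0


def test_density_map_conserves_covered_cpgs(sim_small):
    from methcanyon.tracks import pool_tracks
    track = pool_tracks(sim_small.tracks_wt)
    enh = sim_small.annotation.enhancers
    dmap = enhancer_density_map(track, enh)
    covered = 0
    for _, e in enh.iterrows():
        s = track.chroms[e["chrom"]].slice(int(e["start"]), int(e["end"]))
        covered += int((s.coverage > 0).sum())
    assert dmap.total == covered


def test_uniform_levels_spread_evenly_over_rows():
    rng = np.random.default_rng(3)
    pos = np.arange(10_000, 12_000, 2)
    levels = rng.uniform(0, 1, size=len(pos))
    cov = 1_000
    recs = [(int(p), int(round(lv * cov)), cov - int(round(lv * cov)))
            for p, lv in zip(pos, levels)]
    dmap = enhancer_density_map(make_track({"chr1": recs}), _enhancers())
    row_totals = dmap.counts.sum(axis=1)
    assert stats.chisquare(row_totals).pvalue > 0.01


def test_low_center_pattern_peaks_in_central_bins(sim_small):
    """WT enhancer centres are undermethylated: the bottom level rows
    concentrate in central position bins."""
    from methcanyon.tracks import pool_tracks
    track = pool_tracks(sim_small.tracks_wt)
    dmap = enhancer_density_map(track, sim_small.annotation.enhancers)
    bottom = dmap.counts[0] + dmap.counts[1]           # levels < 0.2
    n = dmap.n_position_bins
    central = bottom[n // 3: 2 * n // 3].mean()
    outer = np.concatenate([bottom[: n // 3], bottom[2 * n // 3:]]).mean()
    assert central > outer


def test_central_shift_recovers_planted_gain():
    pos = list(range(10_000, 12_000, 5))
    cov = 500
    wt = make_track({"chr1": [(p, int(0.20 * cov), cov - int(0.20 * cov))
                              for p in pos]}, sample="wt")
    dko_recs = []
    for p in pos:
        level = 0.35 if 10_667 <= p < 11_333 else 0.20
        dko_recs.append((p, int(level * cov), cov - int(level * cov)))
    dko = make_track({"chr1": dko_recs}, sample="dko", genotype="DKO")
    res = central_region_level_shift(wt, dko, _enhancers())
    assert res["median_shift"] == pytest.approx(0.15, abs=0.01)


def test_identical_tracks_have_zero_central_shift():
    track = make_track({"chr1": [(p, 5, 5) for p in range(10_000, 12_000, 20)]})
    res = central_region_level_shift(track, track, _enhancers())
    assert res["median_shift"] == 0.0


def test_empty_enhancer_set_is_an_error():
    track = make_track({"chr1": [(10, 1, 1)]})
    with pytest.raises(ValueError, match="empty"):
        central_region_level_shift(track, track, pd.DataFrame(
            columns=["chrom", "start", "end"]))
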