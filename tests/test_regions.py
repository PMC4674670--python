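"""UMR/canyon calling, edge dynamics, DMRs, annotation, shores."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from methcanyon.annotation import make_genes
from methcanyon.regions import (Umr, annotate_interval, build_shores,
                                call_canyons, call_dmrs, call_umrs,
                                classify_canyon_dynamics, edge_windows)
from methcanyon.tracks import pool_tracks

from conftest import make_track, uniform_track


def _block_track(low_blocks, chrom_end=100_000, spacing=50, cov=100,
                 low=0.02, high=0.90, sample="t"):
    """Deterministic track: `high` background with `low` blocks planted."""
    recs = []
    for p in range(0, chrom_end, spacing):
        level = low if any(s <= p < e for s, e in low_blocks) else high
        m = int(round(level * cov))
        recs.append((p, m, cov - m))
    return make_track({"chr1": recs}, sample=sample)


# --- UMR / canyon calling ---------------------------------------------------

def test_uniformly_methylated_track_has_no_umrs():
    assert call_umrs(uniform_track("chr1", 0, 50_000, 50, 0.9)) == []


def test_planted_low_block_is_called_as_single_umr():
    track = _block_track([(20_000, 24_000)])
    umrs = call_umrs(track)
    assert len(umrs) == 1
    u = umrs[0]
    assert u.start == 20_000 and u.end == 23_950 + 1
    assert u.level < 0.10


def test_gap_merge_rule_boundary():
    far = call_umrs(_block_track([(10_000, 13_000), (13_600, 16_600)]))
    near = call_umrs(_block_track([(10_000, 13_000), (13_400, 16_400)]))
    assert len(far) == 2
    assert len(near) == 1


def test_canyon_length_threshold_is_inclusive():
    short = Umr("chr1", 0, 3_499, 50, 0.02)
    exact = Umr("chr1", 0, 3_500, 50, 0.02)
    assert call_canyons([short]) == []
    assert len(call_canyons([exact])) == 1


def test_no_umrs_from_empty_input():
    assert call_canyons([]) == []


def test_umr_intervals_are_pairwise_disjoint(sim_small):
    umrs = call_umrs(pool_tracks(sim_small.tracks_wt))
    assert len(umrs) > 1
    by_chrom = {}
    for u in umrs:
        by_chrom.setdefault(u.chrom, []).append((u.start, u.end))
    for ivs in by_chrom.values():
        ivs.sort()
        assert all(a[1] <= b[0] for a, b in zip(ivs, ivs[1:]))


# --- edge dynamics ----------------------------------------------------------

def test_edge_window_is_capped_and_proportional():
    assert edge_windows(0, 10_000) == ((0, 1_000), (9_000, 10_000))
    assert edge_windows(0, 2_000) == ((0, 500), (1_500, 2_000))


def _canyon_pair(edge_delta):
    """WT canyon at 0.02; DKO shifted by edge_delta on both 1 kb edges."""
    wt = _block_track([(20_000, 26_000)], sample="wt")
    recs = []
    cov = 100
    for p in range(0, 100_000, 50):
        if 20_000 <= p < 26_000:
            level = 0.02 + (edge_delta if (p < 21_000 or p >= 25_000) else 0.0)
        else:
            level = 0.90
        level = min(max(level, 0.0), 1.0)
        m = int(round(level * cov))
        recs.append((p, m, cov - m))
    dko = make_track({"chr1": recs}, sample="dko", genotype="DKO")
    canyons = call_canyons(call_umrs(wt))
    assert len(canyons) == 1
    return classify_canyon_dynamics(canyons, wt, dko)[0]


def test_identical_tracks_give_stable_canyons():
    wt = _block_track([(20_000, 26_000)])
    canyon = classify_canyon_dynamics(call_canyons(call_umrs(wt)), wt, wt)[0]
    assert canyon.dynamics == "stable"
    assert canyon.delta_edge == pytest.approx(0.0)


def test_edge_gain_labels_canyon_shrinking():
    canyon = _canyon_pair(+0.30)
    assert canyon.dynamics == "shrinking"
    assert canyon.delta_edge == pytest.approx(0.30, abs=0.02)


def test_edge_loss_labels_canyon_expanding():
    """Sign-flipped oracle on a supplied canyon whose edges have headroom."""
    from methcanyon.regions import Canyon
    cov = 100

    def tr(edge_level, sample):
        recs = []
        for p in range(0, 100_000, 50):
            if 20_000 <= p < 26_000:
                level = edge_level if (p < 21_000 or p >= 25_000) else 0.02
            else:
                level = 0.90
            m = int(round(level * cov))
            recs.append((p, m, cov - m))
        return make_track({"chr1": recs}, sample=sample)

    wt, dko = tr(0.35, "wt"), tr(0.05, "dko")
    canyon = Canyon("chr1", 20_000, 26_000, 120, 0.05)
    out = classify_canyon_dynamics([canyon], wt, dko)[0]
    assert out.dynamics == "expanding"
    assert out.delta_edge == pytest.approx(-0.30, abs=0.02)


def test_uncovered_edges_are_labeled_missing():
    from methcanyon.regions import Canyon
    wt = _block_track([(20_000, 26_000)])
    empty = make_track({"chr1": [(90_000, 1, 1)]}, sample="sparse")
    canyon = Canyon("chr1", 20_000, 26_000, 120, 0.02)
    out = classify_canyon_dynamics([canyon], wt, empty)[0]
    assert out.dynamics == "missing"


# --- DMRs -------------------------------------------------------------------

def test_identical_tracks_yield_no_dmrs():
    track = _block_track([(20_000, 24_000)])
    assert call_dmrs(track, track) == []


def test_planted_gain_block_becomes_one_dmr_matching_window_oracle():
    """Oracle: exhaustive window Fisher tests + BH + hand merge."""
    spacing, cov = 50, 30
    pos = np.arange(0, 60_000, spacing)
    block = (30_000, 32_000)            # 40 CpGs at delta 0.5
    m_wt = np.full(len(pos), int(round(0.3 * cov)))
    m_dko = m_wt.copy()
    in_block = (pos >= block[0]) & (pos < block[1])
    assert in_block.sum() == 40
    m_dko[in_block] = int(round(0.8 * cov))
    wt = make_track({"chr1": list(zip(pos.tolist(), m_wt.tolist(),
                                      (cov - m_wt).tolist()))}, sample="wt")
    dko = make_track({"chr1": list(zip(pos.tolist(), m_dko.tolist(),
                                       (cov - m_dko).tolist()))}, sample="dko")
    dmrs = call_dmrs(wt, dko)
    assert len(dmrs) == 1
    d = dmrs[0]
    assert d.direction == "gain"
    assert d.start <= block[0] and d.end >= block[1] - spacing
    assert d.delta >= 0.10 and d.q <= 0.05

    # independent oracle over all windows
    w, s = 25, 5
    pvals, metas = [], []
    for i in range(0, len(pos) - w + 1, s):
        mw, md = m_wt[i:i + w].sum(), m_dko[i:i + w].sum()
        tw = td = w * cov
        pvals.append(stats.fisher_exact([[mw, tw - mw], [md, td - md]])[1])
        metas.append((i, i + w, md / td - mw / tw))
    q = multipletests(pvals, method="fdr_bh")[1]
    sig = [(i, j) for (i, j, delta), qq in zip(metas, q)
           if qq <= 0.05 and abs(delta) >= 0.10]
    lo = min(i for i, _ in sig)
    hi = max(j for _, j in sig)
    assert d.start == pos[lo] and d.end == pos[hi - 1] + 1


def test_subthreshold_delta_is_gated_regardless_of_p():
    spacing, cov = 50, 400             # huge coverage: p tiny, delta 0.05
    pos = np.arange(0, 60_000, spacing)
    m_wt = np.full(len(pos), int(round(0.30 * cov)))
    m_dko = m_wt.copy()
    in_block = (pos >= 30_000) & (pos < 32_000)
    m_dko[in_block] = int(round(0.35 * cov))
    wt = make_track({"chr1": list(zip(pos.tolist(), m_wt.tolist(),
                                      (cov - m_wt).tolist()))})
    dko = make_track({"chr1": list(zip(pos.tolist(), m_dko.tolist(),
                                       (cov - m_dko).tolist()))})
    assert call_dmrs(wt, dko) == []


def test_dmr_invariants_hold_when_recomputed_from_counts(sim_small):
    pw = pool_tracks(sim_small.tracks_wt)
    pdk = pool_tracks(sim_small.tracks_dko)
    dmrs = call_dmrs(pw, pdk)
    assert dmrs
    for d in dmrs:
        sw = pw.chroms[d.chrom].slice(d.start, d.end)
        sd = pdk.chroms[d.chrom].slice(d.start, d.end)
        lv_wt = sw.m.sum() / sw.coverage.sum()
        lv_dko = sd.m.sum() / sd.coverage.sum()
        assert lv_wt == pytest.approx(d.level_wt)
        assert lv_dko == pytest.approx(d.level_dko)
        assert abs(d.delta) >= 0.10
        assert d.q <= 0.05
        assert d.direction == ("gain" if d.delta > 0 else "loss")


# --- genomic annotation -----------------------------------------------------

@pytest.fixture(scope="module")
def two_genes():
    return make_genes(["gA", "gB"], ["chr1", "chr1"], [50_000, 57_000],
                      [56_000, 90_000], ["+", "+"])


def test_interval_on_tss_is_promoter(two_genes):
    assert annotate_interval("chr1", 49_900, 50_100, two_genes) == "promoter/TSS"


def test_interval_deep_in_gene_is_body(two_genes):
    assert annotate_interval("chr1", 70_000, 71_000, two_genes) == "gene body"


def test_promoter_beats_body_on_overlap(two_genes):
    # promoter window of gB ([55000,59000)) intersects the body of gA
    assert annotate_interval("chr1", 55_500, 55_900, two_genes) == "promoter/TSS"


def test_far_interval_is_intergenic(two_genes):
    assert annotate_interval("chr1", 95_000, 96_000, two_genes) == "intergenic"


# --- CGI shores -------------------------------------------------------------

def test_isolated_cgi_gets_full_flank_shores():
    cgis = pd.DataFrame({"chrom": ["chr1"], "start": [10_000],
                         "end": [11_000], "name": ["c0"]})
    shores = build_shores(cgis)
    ivs = {(s.side, s.start, s.end) for s in shores}
    assert ivs == {("upstream", 8_000, 10_000), ("downstream", 11_000, 13_000)}
    assert all(s.width <= 2_000 for s in shores)


def test_close_cgis_truncate_each_others_shores():
    cgis = pd.DataFrame({"chrom": ["chr1", "chr1"],
                         "start": [10_000, 12_000], "end": [11_000, 13_000],
                         "name": ["a", "b"]})
    shores = build_shores(cgis)
    by = {(s.cgi_id, s.side): (s.start, s.end) for s in shores}
    assert by[("a", "downstream")] == (11_000, 12_000)
    assert by[("b", "upstream")] == (11_000, 12_000)
    for s in shores:
        for _, c in cgis.iterrows():
            assert s.end <= c["start"] or s.start >= c["end"]


def test_shore_clipped_at_chromosome_start_and_end():
    cgis = pd.DataFrame({"chrom": ["chr1"], "start": [500], "end": [1_500],
                         "name": ["c"]})
    shores = build_shores(cgis, chrom_lengths={"chr1": 2_000})
    by = {s.side: (s.start, s.end) for s in shores}
    assert by["upstream"] == (0, 500)
    assert by["downstream"] == (1_500, 2_000)


def test_promoter_overlap_flag_set_from_gene_models(two_genes):
    cgis = pd.DataFrame({"chrom": ["chr1", "chr1"],
                         "start": [49_500, 95_000], "end": [50_500, 96_000],
                         "name": ["p", "q"]})
    shores = build_shores(cgis, genes=two_genes)
    flags = {s.cgi_id: s.promoter_overlap for s in shores if s.side == "upstream"}
    assert flags["p"] is True
    assert flags["q"] is False
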