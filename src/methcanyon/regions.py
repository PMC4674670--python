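"""Undermethylated regions, canyons, edge dynamics, DMRs, and CGI shores.

Canyons are long (>= 3.5 kb) undermethylated regions; in haematopoietic
stem/progenitor cells they sit at promoters of developmental regulators.
Losing the TET demethylation machinery lets methylation creep in from the
canyon edges, so canyons called in WT are re-measured in the knockout and
classified as shrinking (edges gain), expanding (edges lose) or stable.

The differential-modification caller slides fixed-CpG-count windows along
each chromosome, tests pooled counts with Fisher's exact test, controls
FDR by Benjamini-Hochberg, gates on effect size, and merges touching
significant windows of the same direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import PROMOTER_FLANK, promoter_windows
from .tracks import MethTrack

logger = logging.getLogger(__name__)

CANYON_MIN_LENGTH = 3_500


@dataclass
class Umr:
    """Undermethylated region: maximal run of low-methylation CpGs."""

    chrom: str
    start: int            # first member CpG (0-based)
    end: int              # last member CpG + 1 (half-open)
    n_cpgs: int
    level: float          # count-weighted level over member CpGs

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Canyon(Umr):
    """A UMR of length >= 3.5 kb, with optional edge-dynamics annotation."""

    dynamics: str | None = None          # shrinking | expanding | stable | missing
    delta_edge: float = float("nan")     # mean over both edges of DKO-WT level
    edge_left: tuple[int, int] | None = None
    edge_right: tuple[int, int] | None = None


@dataclass
class Dmr:
    chrom: str
    start: int
    end: int
    n_cpgs: int
    level_wt: float
    level_dko: float
    delta: float
    direction: str        # gain | loss
    p: float
    q: float
    annotation: str | None = None   # promoter/TSS | gene body | intergenic


@dataclass
class CgiShore:
    cgi_id: str
    chrom: str
    start: int
    end: int
    side: str             # upstream | downstream
    promoter_overlap: bool = False

    @property
    def width(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# UMR / canyon calling
# ---------------------------------------------------------------------------

def _smooth3(x: np.ndarray) -> np.ndarray:
    """Rolling mean over 3 consecutive values; ends use the available 2."""
    if len(x) == 0:
        return x
    s = np.convolve(x, np.ones(3), mode="same")
    n = np.convolve(np.ones(len(x)), np.ones(3), mode="same")
    return s / n


def call_umrs(track: MethTrack, umr_max_level: float = 0.10,
              umr_min_cpgs: int = 5, max_gap_bp: int = 500,
              min_coverage: int = 1) -> list[Umr]:
    """Call undermethylated regions on a (pooled) track.

    Membership is seeded by a 3-CpG rolling mean of site levels below
    ``umr_max_level``; each run is then extended outward over adjacent
    CpGs whose raw level is below the threshold (the smoother borrows
    from high neighbours at region borders, which would otherwise trim
    one boundary CpG per side); runs are merged across gaps up to
    ``max_gap_bp``, then filtered on member-CpG count and count-weighted
    level.  Intervals span first to last member CpG (half-open).
    """
    umrs: list[Umr] = []
    for chrom in sorted(track.chroms):
        c = track.chroms[chrom]
        cov = c.coverage
        keep = cov >= max(min_coverage, 1)
        pos = c.pos[keep]
        m = c.m[keep]
        t = cov[keep]
        if len(pos) == 0:
            continue
        levels = m / t
        member = _smooth3(levels) < umr_max_level
        raw_low = levels < umr_max_level
        # maximal runs of member CpGs
        runs: list[tuple[int, int]] = []   # index ranges [i, j)
        i = 0
        n = len(member)
        while i < n:
            if member[i]:
                j = i
                while j < n and member[j]:
                    j += 1
                runs.append((i, j))
                i = j
            else:
                i += 1
        # boundary refinement: extend runs over adjacent raw-low CpGs
        # (bounded by max_gap_bp so extension cannot jump across deserts)
        refined = []
        for i, j in runs:
            while i > 0 and raw_low[i - 1] and pos[i] - pos[i - 1] <= max_gap_bp:
                i -= 1
                member[i] = True
            while j < n and raw_low[j] and pos[j] - pos[j - 1] <= max_gap_bp:
                member[j] = True
                j += 1
            refined.append((i, j))
        runs = refined
        # merge runs whose bp gap between member CpGs is <= max_gap_bp
        merged: list[list[int]] = []
        for i, j in runs:
            if merged and pos[i] - pos[merged[-1][1] - 1] - 1 <= max_gap_bp:
                merged[-1][1] = j
            else:
                merged.append([i, j])
        for i, j in merged:
            members = np.arange(i, j)[member[i:j]]
            n_cpgs = len(members)
            if n_cpgs < umr_min_cpgs:
                continue
            total = int(t[members].sum())
            level = int(m[members].sum()) / total if total else float("nan")
            if not level < umr_max_level:
                continue
            umrs.append(Umr(chrom=chrom, start=int(pos[members[0]]),
                            end=int(pos[members[-1]]) + 1,
                            n_cpgs=n_cpgs, level=level))
    return umrs


def call_canyons(umrs: list[Umr],
                 min_length: int = CANYON_MIN_LENGTH) -> list[Canyon]:
    """Filter UMRs to canyons: length >= min_length (inclusive)."""
    return [Canyon(chrom=u.chrom, start=u.start, end=u.end,
                   n_cpgs=u.n_cpgs, level=u.level)
            for u in umrs if u.length >= min_length]


def edge_windows(start: int, end: int, edge_fraction: float = 0.25,
                 edge_cap_bp: int = 1_000) -> tuple[tuple[int, int], tuple[int, int]]:
    """Left and right edge windows: min(cap, fraction*length) bp inward."""
    length = end - start
    w = int(min(edge_cap_bp, edge_fraction * length))
    return (start, start + w), (end - w, end)


def _window_level(track: MethTrack, chrom: str, start: int, end: int) -> float:
    sites = track.chroms[chrom].slice(start, end)
    total = int(sites.coverage.sum())
    return int(sites.m.sum()) / total if total else float("nan")


def classify_canyon_dynamics(canyons: list[Canyon], track_wt: MethTrack,
                             track_dko: MethTrack, edge_fraction: float = 0.25,
                             edge_cap_bp: int = 1_000,
                             delta_threshold: float = 0.10) -> list[Canyon]:
    """Label WT-called canyons by edge behaviour in the knockout.

    delta_edge = mean over both edge windows of (DKO - WT) weighted level;
    shrinking if >= delta_threshold, expanding if <= -delta_threshold,
    else stable.  A canyon with zero covered edge CpGs in either genotype
    on either side is labelled "missing" and excluded from denominators.
    """
    out = []
    for canyon in canyons:
        left, right = edge_windows(canyon.start, canyon.end,
                                   edge_fraction, edge_cap_bp)
        deltas = []
        ok = True
        for win in (left, right):
            lv_wt = _window_level(track_wt, canyon.chrom, *win)
            lv_dko = _window_level(track_dko, canyon.chrom, *win)
            if np.isnan(lv_wt) or np.isnan(lv_dko):
                ok = False
                break
            deltas.append(lv_dko - lv_wt)
        c = Canyon(chrom=canyon.chrom, start=canyon.start, end=canyon.end,
                   n_cpgs=canyon.n_cpgs, level=canyon.level,
                   edge_left=left, edge_right=right)
        if not ok:
            logger.warning("canyon %s:%d-%d has uncovered edge; label=missing",
                           canyon.chrom, canyon.start, canyon.end)
            c.dynamics = "missing"
        else:
            c.delta_edge = float(np.mean(deltas))
            if c.delta_edge >= delta_threshold:
                c.dynamics = "shrinking"
            elif c.delta_edge <= -delta_threshold:
                c.dynamics = "expanding"
            else:
                c.dynamics = "stable"
        out.append(c)
    return out


# ---------------------------------------------------------------------------
# DMR calling
# ---------------------------------------------------------------------------

def _sliding_window_tests(pos, m_wt, t_wt, m_dko, t_dko,
                          window_cpgs: int, step_cpgs: int):
    """Fisher's exact test per window of window_cpgs CpGs, stepped by step_cpgs."""
    n = len(pos)
    windows = []
    for i in range(0, n - window_cpgs + 1, step_cpgs):
        j = i + window_cpgs
        mw, tw = int(m_wt[i:j].sum()), int(t_wt[i:j].sum())
        md, td = int(m_dko[i:j].sum()), int(t_dko[i:j].sum())
        lv_wt = mw / tw
        lv_dko = md / td
        p = stats.fisher_exact([[mw, tw - mw], [md, td - md]])[1]
        windows.append((i, j, lv_wt, lv_dko, p))
    return windows


def call_dmrs(track_wt: MethTrack, track_dko: MethTrack,
              window_cpgs: int = 25, step_cpgs: int = 5,
              dmr_min_delta: float = 0.10, dmr_max_q: float = 0.05,
              return_windows: bool = False):
    """Call differentially modified regions between pooled WT and DKO tracks.

    Windows run over CpGs covered in both tracks.  Per window a Fisher
    exact test compares pooled counts; BH-adjusted q <= dmr_max_q AND
    |delta weighted level| >= dmr_min_delta makes a window significant.
    Touching significant windows of one direction merge into a DMR whose
    level/delta/p are recomputed on the merged span (q = min member q).

    With ``return_windows`` also returns the per-window table (for FDR
    diagnostics).
    """
    all_windows = []   # (chrom, i, j, pos_slice arrays, lv_wt, lv_dko, p)
    per_chrom = {}
    for chrom in sorted(set(track_wt.chroms) & set(track_dko.chroms)):
        cw, cd = track_wt.chroms[chrom], track_dko.chroms[chrom]
        common = np.intersect1d(cw.pos[cw.coverage > 0], cd.pos[cd.coverage > 0])
        if len(common) < window_cpgs:
            logger.warning("chromosome %s: %d covered CpGs < window size %d; "
                           "no DMR calls", chrom, len(common), window_cpgs)
            continue
        iw = np.searchsorted(cw.pos, common)
        idd = np.searchsorted(cd.pos, common)
        m_wt, t_wt = cw.m[iw], cw.coverage[iw]
        m_dko, t_dko = cd.m[idd], cd.coverage[idd]
        per_chrom[chrom] = (common, m_wt, t_wt, m_dko, t_dko)
        for (i, j, lv_wt, lv_dko, p) in _sliding_window_tests(
                common, m_wt, t_wt, m_dko, t_dko, window_cpgs, step_cpgs):
            all_windows.append([chrom, i, j, lv_wt, lv_dko, p])

    win_df = pd.DataFrame(all_windows,
                          columns=["chrom", "i", "j", "level_wt", "level_dko", "p"])
    if len(win_df):
        win_df["q"] = multipletests(win_df["p"], method="fdr_bh")[1]
        win_df["delta"] = win_df["level_dko"] - win_df["level_wt"]
        win_df["significant"] = ((win_df["q"] <= dmr_max_q)
                                 & (win_df["delta"].abs() >= dmr_min_delta))
    else:
        win_df["q"] = win_df["delta"] = pd.Series(dtype=float)
        win_df["significant"] = pd.Series(dtype=bool)

    dmrs: list[Dmr] = []
    sig_df = win_df[win_df["significant"]] if len(win_df) else win_df
    for chrom, g in sig_df.groupby("chrom"):
        common, m_wt, t_wt, m_dko, t_dko = per_chrom[chrom]
        g = g.copy()
        g["direction"] = np.sign(g["delta"])
        g = g.sort_values("i")
        # merge windows whose CpG index ranges touch and share direction
        cur = None
        groups = []
        for _, row in g.iterrows():
            if cur is not None and row["i"] <= cur["j"] and \
                    row["direction"] == cur["direction"]:
                cur["j"] = max(cur["j"], row["j"])
                cur["q"] = min(cur["q"], row["q"])
            else:
                if cur is not None:
                    groups.append(cur)
                cur = {"i": row["i"], "j": row["j"], "q": row["q"],
                       "direction": row["direction"]}
        if cur is not None:
            groups.append(cur)
        for grp in groups:
            i, j = int(grp["i"]), int(grp["j"])
            mw, tw = int(m_wt[i:j].sum()), int(t_wt[i:j].sum())
            md, td = int(m_dko[i:j].sum()), int(t_dko[i:j].sum())
            lv_wt, lv_dko = mw / tw, md / td
            delta = lv_dko - lv_wt
            if abs(delta) < dmr_min_delta:
                continue   # merged span diluted below the effect-size gate
            p = stats.fisher_exact([[mw, tw - mw], [md, td - md]])[1]
            dmrs.append(Dmr(chrom=chrom, start=int(common[i]),
                            end=int(common[j - 1]) + 1, n_cpgs=j - i,
                            level_wt=lv_wt, level_dko=lv_dko, delta=delta,
                            direction="gain" if delta > 0 else "loss",
                            p=p, q=float(grp["q"])))
    if return_windows:
        return dmrs, win_df
    return dmrs


# ---------------------------------------------------------------------------
# genomic annotation
# ---------------------------------------------------------------------------

def annotate_interval(chrom: str, start: int, end: int,
                      genes: pd.DataFrame) -> str:
    """Classify an interval as promoter/TSS, gene body, or intergenic.

    Precedence: promoter/TSS (intersects any TSS +/- 2 kb) beats gene body
    (intersects any gene span) beats intergenic.
    """
    g = genes[genes["chrom"] == chrom]
    if len(g):
        tss = g["tss"].to_numpy()
        if np.any((start < tss + PROMOTER_FLANK) & (end > tss - PROMOTER_FLANK)):
            return "promoter/TSS"
        if np.any((start < g["end"].to_numpy()) & (end > g["start"].to_numpy())):
            return "gene body"
    return "intergenic"


def annotate_dmrs(dmrs: list[Dmr], genes: pd.DataFrame) -> list[Dmr]:
    for d in dmrs:
        d.annotation = annotate_interval(d.chrom, d.start, d.end, genes)
    return dmrs


# ---------------------------------------------------------------------------
# CGI shores
# ---------------------------------------------------------------------------

def build_shores(cgis: pd.DataFrame, flank: int = 2_000,
                 chrom_lengths: dict[str, int] | None = None,
                 genes: pd.DataFrame | None = None) -> list[CgiShore]:
    """2 kb flanks of each CGI, clipped at chromosome ends, CGI-free.

    The shore extends outward from the island edge until it hits another
    island (or the flank limit / chromosome end), so shores never
    intersect any CGI.  ``promoter_overlap`` flags shores intersecting any
    TSS +/- 2 kb window.
    """
    shores: list[CgiShore] = []
    cgis = cgis.reset_index(drop=True)
    names = cgis["name"] if "name" in cgis else pd.Series(
        [f"cgi_{i}" for i in range(len(cgis))])
    proms = promoter_windows(genes) if genes is not None else None
    for chrom, g in cgis.groupby("chrom"):
        starts = g["start"].to_numpy()
        ends = g["end"].to_numpy()
        chrom_len = (chrom_lengths or {}).get(chrom)
        for idx, row in g.iterrows():
            s, e = int(row["start"]), int(row["end"])
            if e <= s:
                raise ValueError(f"degenerate CGI {chrom}:{s}-{e}")
            # upstream: extend left until previous CGI end or flank limit
            lo = s - flank
            left_ends = ends[ends <= s]
            up_start = max(lo, int(left_ends.max()) if len(left_ends) else lo, 0)
            # downstream: extend right until next CGI start or flank limit
            hi = e + flank
            right_starts = starts[starts >= e]
            down_end = min(hi, int(right_starts.min()) if len(right_starts) else hi)
            if chrom_len is not None:
                down_end = min(down_end, chrom_len)
            for side, (ws, we) in (("upstream", (up_start, s)),
                                   ("downstream", (e, down_end))):
                if we <= ws:
                    continue
                flag = False
                if proms is not None:
                    pr = proms[proms["chrom"] == chrom]
                    flag = bool(np.any((ws < pr["end"].to_numpy())
                                       & (we > pr["start"].to_numpy())))
                shores.append(CgiShore(cgi_id=str(names.loc[idx]), chrom=chrom,
                                       start=ws, end=we, side=side,
                                       promoter_overlap=flag))
    return shores


# ---------------------------------------------------------------------------
# tabular export
# ---------------------------------------------------------------------------

def canyons_to_frame(canyons: list[Canyon]) -> pd.DataFrame:
    return pd.DataFrame([{
        "chrom": c.chrom, "start": c.start, "end": c.end, "length": c.length,
        "n_cpgs": c.n_cpgs, "level": c.level, "dynamics": c.dynamics,
        "delta_edge": c.delta_edge} for c in canyons])


def dmrs_to_frame(dmrs: list[Dmr]) -> pd.DataFrame:
    return pd.DataFrame([{
        "chrom": d.chrom, "start": d.start, "end": d.end, "n_cpgs": d.n_cpgs,
        "level_wt": d.level_wt, "level_dko": d.level_dko, "delta": d.delta,
        "direction": d.direction, "p": d.p, "q": d.q,
        "annotation": d.annotation} for d in dmrs])


def shores_to_frame(shores: list[CgiShore]) -> pd.DataFrame:
    return pd.DataFrame([{
        "cgi_id": s.cgi_id, "chrom": s.chrom, "start": s.start, "end": s.end,
        "side": s.side, "width": s.width,
        "promoter_overlap": s.promoter_overlap} for s in shores])
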