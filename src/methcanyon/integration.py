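"""Joining methylation features to genes and expression.

Canyon/shore/DMR intervals are linked to gene promoters by a strict
< 2 kb distance rule; differential methylation is cross-tabulated against
differential-expression direction with an (uncorrected) Pearson
chi-square test; enhancer methylation is summarized as a 2-D density map
of (scaled position within the enhancer, methylation-level decile).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .tracks import MethTrack

logger = logging.getLogger(__name__)

LINK_MAX_DISTANCE = 2_000


# ---------------------------------------------------------------------------
# region -> promoter links
# ---------------------------------------------------------------------------

def interval_point_distance(start: int, end: int, point: int) -> int:
    """bp between a half-open interval and a point; 0 when the point is inside."""
    if start <= point < end:
        return 0
    if point < start:
        return start - point
    return point - (end - 1)


def link_regions_to_promoters(regions: pd.DataFrame, genes: pd.DataFrame,
                              region_kind: str = "canyon",
                              max_distance: int = LINK_MAX_DISTANCE) -> pd.DataFrame:
    """Link regions to gene promoters within a strict ``max_distance`` of the TSS.

    ``regions`` needs columns chrom/start/end (and optionally ``name``).
    Many-to-many: a region spanning two promoters emits two links.
    """
    regions = regions.reset_index(drop=True)
    names = (regions["name"] if "name" in regions
             else pd.Series([f"{region_kind}_{i}" for i in range(len(regions))]))
    rows = []
    for chrom, g in genes.groupby("chrom"):
        sub = regions[regions["chrom"] == chrom]
        for idx, r in sub.iterrows():
            for _, gene in g.iterrows():
                d = interval_point_distance(int(r["start"]), int(r["end"]),
                                            int(gene["tss"]))
                if d < max_distance:
                    rows.append({"gene_id": gene["gene_id"],
                                 "region_id": names.loc[idx],
                                 "region_kind": region_kind, "distance": d})
    return pd.DataFrame(rows, columns=["gene_id", "region_id",
                                       "region_kind", "distance"])


# ---------------------------------------------------------------------------
# delta-methylation vs expression scatter
# ---------------------------------------------------------------------------

def delta_vs_expression_table(deltas: pd.DataFrame,
                              de_records: pd.DataFrame) -> pd.DataFrame:
    """One row per differentially expressed gene: log2FC vs methylation deltas.

    ``deltas`` carries gene_id/delta_body/delta_promoter; genes with a
    missing delta are retained and flagged, so the scatter's denominator
    is the full DE set.
    """
    de = de_records[de_records["status"] != "ns"]
    merged = de.merge(deltas, on="gene_id", how="left")
    merged["delta_missing"] = (merged["delta_body"].isna()
                               | merged["delta_promoter"].isna())
    return merged[["gene_id", "log2_fold_change", "status",
                   "delta_body", "delta_promoter", "delta_missing"]]


# ---------------------------------------------------------------------------
# contingency statistics
# ---------------------------------------------------------------------------

@dataclass
class ContingencyResult:
    observed: np.ndarray
    expected: np.ndarray
    chi2: float
    dof: int
    p: float


def chi_square_test(observed) -> ContingencyResult:
    """Pearson chi-square on a 2xk table, no continuity correction.

    Expected counts come from the margins; the statistic is
    sum((O-E)^2/E) with (r-1)(k-1) degrees of freedom.  A zero row or
    column margin makes the table degenerate and raises ``ValueError``.
    """
    obs = np.asarray(observed, dtype=float)
    if obs.ndim != 2:
        raise ValueError("observed must be 2-D")
    if (obs < 0).any():
        raise ValueError("negative cell count")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ValueError("degenerate table: zero margin")
    expected = np.outer(row, col) / obs.sum()
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    dof = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(stats.chi2.sf(chi2, dof))
    return ContingencyResult(obs, expected, chi2, dof, p)


def direction_contingency(group_down_up: tuple[int, int],
                          background_down_up: tuple[int, int]) -> ContingencyResult:
    """Chi-square of DE direction in a gene group against a background set.

    Rows are (group, background), columns (down, up) counts.
    """
    table = np.array([list(group_down_up), list(background_down_up)])
    return chi_square_test(table)


def fraction_report(numerator: int, denominator: int, decimals: int = 0) -> float:
    """Percentage 100*num/den, rounded half-away-from-zero to ``decimals``."""
    if denominator == 0:
        raise ValueError("denominator must be nonzero")
    pct = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    quant = Decimal(1).scaleb(-decimals)
    return float(pct.quantize(quant, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# enhancer methylation-density maps
# ---------------------------------------------------------------------------

@dataclass
class EnhancerDensityMap:
    counts: np.ndarray          # [level bin, position bin]
    level_edges: np.ndarray
    n_position_bins: int
    n_enhancers_used: int
    n_enhancers_skipped: int

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def column_normalized(self) -> np.ndarray:
        col = self.counts.sum(axis=0, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(col > 0, self.counts / col, 0.0)


def enhancer_density_map(track: MethTrack, enhancers: pd.DataFrame,
                         n_position_bins: int = 20, level_bins: int = 10,
                         min_coverage: int = 1) -> EnhancerDensityMap:
    """CpG counts binned by scaled enhancer position and methylation decile.

    Every enhancer is scaled to [0, 1) and split into ``n_position_bins``;
    each covered CpG contributes one count at (its level bin, its position
    bin), accumulated over the whole enhancer set.  Level 1.0 falls in the
    top bin.  Enhancers without covered CpGs are skipped and counted.
    """
    counts = np.zeros((level_bins, n_position_bins), dtype=np.int64)
    edges = np.linspace(0.0, 1.0, level_bins + 1)
    used = skipped = 0
    for _, enh in enhancers.iterrows():
        s, e = int(enh["start"]), int(enh["end"])
        if e <= s:
            raise ValueError(f"degenerate enhancer {enh['chrom']}:{s}-{e}")
        sites = track.sites(enh["chrom"], s, e)
        cov = sites.coverage
        keep = cov >= max(min_coverage, 1)
        if not keep.any():
            skipped += 1
            continue
        used += 1
        pos = sites.pos[keep]
        levels = sites.m[keep] / cov[keep]
        pbin = ((pos - s) * n_position_bins // (e - s)).astype(int)
        pbin = np.minimum(pbin, n_position_bins - 1)
        lbin = np.minimum((levels * level_bins).astype(int), level_bins - 1)
        np.add.at(counts, (lbin, pbin), 1)
    if skipped:
        logger.info("%d enhancers had no covered CpGs", skipped)
    return EnhancerDensityMap(counts, edges, n_position_bins, used, skipped)


def central_region_level_shift(track_wt: MethTrack, track_dko: MethTrack,
                               enhancers: pd.DataFrame,
                               central_fraction: float = 0.33,
                               min_coverage: int = 1) -> dict:
    """Per-CpG level distributions over enhancer centres, per genotype.

    The central ``central_fraction`` of each enhancer is pooled over the
    set; the summary is the DKO-WT shift in median (and mean) CpG level.
    """
    if not 0 < central_fraction < 1:
        raise ValueError("central_fraction must be in (0, 1)")
    if len(enhancers) == 0:
        raise ValueError("empty enhancer set")
    levels = {"WT": [], "DKO": []}
    for name, track in (("WT", track_wt), ("DKO", track_dko)):
        for _, enh in enhancers.iterrows():
            s, e = int(enh["start"]), int(enh["end"])
            w = e - s
            cs = s + int(round(w * (1 - central_fraction) / 2))
            ce = s + int(round(w * (1 + central_fraction) / 2))
            sites = track.sites(enh["chrom"], cs, ce)
            cov = sites.coverage
            keep = cov >= max(min_coverage, 1)
            levels[name].append(sites.m[keep] / cov[keep])
        levels[name] = (np.concatenate(levels[name]) if levels[name]
                        else np.array([]))
    med_shift = float(np.median(levels["DKO"]) - np.median(levels["WT"]))
    mean_shift = float(np.mean(levels["DKO"]) - np.mean(levels["WT"]))
    return {"levels_wt": levels["WT"], "levels_dko": levels["DKO"],
            "median_shift": med_shift, "mean_shift": mean_shift}
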