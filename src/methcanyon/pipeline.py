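"""End-to-end driver: simulate -> methylation -> regions -> expression ->
integration, with a tabular report bundle."""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import SimConfig
from .expression import de_summary, de_test
from .integration import (central_region_level_shift, delta_vs_expression_table,
                          direction_contingency, enhancer_density_map,
                          fraction_report, link_regions_to_promoters)
from .metagene import delta_table, profile_genes
from .regions import (annotate_dmrs, build_shores, call_canyons, call_dmrs,
                      call_umrs, canyons_to_frame, classify_canyon_dynamics,
                      dmrs_to_frame, shores_to_frame)
from .simulate import SimResult, simulate_all, write_outputs
from .tracks import pool_tracks

logger = logging.getLogger(__name__)


@dataclass
class PipelineReport:
    summary: dict
    canyons: pd.DataFrame
    dmrs: pd.DataFrame
    shores: pd.DataFrame
    de_records: pd.DataFrame
    scatter: pd.DataFrame
    density_wt: np.ndarray
    density_dko: np.ndarray


def run_pipeline(config: SimConfig, outdir: str | Path | None = None,
                 sim: SimResult | None = None) -> PipelineReport:
    """Run every analysis stage on a (fresh or supplied) simulated dataset.

    Stage failures propagate with the stage name prefixed, so a broken
    input is attributable.  With ``outdir`` all stage outputs are written
    as TSV/JSON.
    """
    stage = "simulate"
    try:
        if sim is None:
            sim = simulate_all(config)
        ann = sim.annotation
        genes = ann.genes

        stage = "methylation_core"
        pooled_wt = pool_tracks(sim.tracks_wt, sample="WT_pooled")
        pooled_dko = pool_tracks(sim.tracks_dko, sample="DKO_pooled")

        stage = "region_detection"
        umrs = call_umrs(pooled_wt)
        canyons = classify_canyon_dynamics(call_canyons(umrs), pooled_wt,
                                           pooled_dko)
        dmrs = annotate_dmrs(call_dmrs(pooled_wt, pooled_dko), genes)
        shores = build_shores(ann.cgis, chrom_lengths=ann.chrom_lengths,
                              genes=genes)

        stage = "expression"
        wt_s = [t.sample for t in sim.tracks_wt]
        dko_s = [t.sample for t in sim.tracks_dko]
        de = de_test(sim.counts, wt_s, dko_s)
        summary_de = de_summary(de)

        stage = "integration_stats"
        de_gene_ids = set(de[de["status"] != "ns"]["gene_id"])
        de_genes = genes[genes["gene_id"].isin(de_gene_ids)]
        profiles_wt = {g: [] for g in de_genes["gene_id"]}
        profiles_dko = {g: [] for g in de_genes["gene_id"]}
        for t in sim.tracks_wt:
            for gid, prof in profile_genes(t, de_genes).items():
                profiles_wt[gid].append(prof)
        for t in sim.tracks_dko:
            for gid, prof in profile_genes(t, de_genes).items():
                profiles_dko[gid].append(prof)
        deltas = delta_table(profiles_wt, profiles_dko, de_genes)
        scatter = delta_vs_expression_table(deltas, de)

        canyon_df = canyons_to_frame(canyons)
        if len(canyon_df):
            canyon_df["name"] = [f"canyon_{i}" for i in range(len(canyon_df))]
        links = link_regions_to_promoters(canyon_df, genes) \
            if len(canyon_df) else pd.DataFrame(
                columns=["gene_id", "region_id", "region_kind", "distance"])

        # DE direction at shrinking canyons vs all other DE genes
        contingency = None
        if len(canyon_df):
            shrink_ids = set(
                canyon_df.loc[canyon_df["dynamics"] == "shrinking", "name"])
            shrink_regions = set(
                links[links["region_id"].isin(shrink_ids)]["gene_id"])
            group = de[de["gene_id"].isin(shrink_regions)
                       & (de["status"] != "ns")]
            rest = de[~de["gene_id"].isin(shrink_regions)
                      & (de["status"] != "ns")]
            g_down, g_up = int((group["status"] == "down").sum()), \
                int((group["status"] == "up").sum())
            b_down, b_up = int((rest["status"] == "down").sum()), \
                int((rest["status"] == "up").sum())
            if min(g_down + g_up, b_down + b_up, g_down + b_down,
                   g_up + b_up) > 0:
                res = direction_contingency((g_down, g_up), (b_down, b_up))
                contingency = {"observed": res.observed.tolist(),
                               "chi2": res.chi2, "p": res.p}

        dmap_wt = enhancer_density_map(pooled_wt, ann.enhancers)
        dmap_dko = enhancer_density_map(pooled_dko, ann.enhancers)
        central = central_region_level_shift(pooled_wt, pooled_dko,
                                             ann.enhancers)

        dmr_df = dmrs_to_frame(dmrs)
        n_gain = int((dmr_df["direction"] == "gain").sum()) if len(dmr_df) else 0
        labeled = canyon_df[canyon_df["dynamics"] != "missing"] \
            if len(canyon_df) else canyon_df
        n_shrink = int((labeled["dynamics"] == "shrinking").sum()) \
            if len(labeled) else 0
        summary = {
            "version": __version__,
            "python": platform.python_version(),
            "seed": config.seed,
            "n_umrs": len(umrs),
            "n_canyons": len(canyon_df),
            "n_canyons_shrinking": n_shrink,
            "pct_canyons_shrinking": fraction_report(n_shrink, len(labeled))
            if len(labeled) else None,
            "n_dmrs": len(dmr_df),
            "n_dmrs_gain": n_gain,
            "pct_dmrs_gain": fraction_report(n_gain, len(dmr_df))
            if len(dmr_df) else None,
            "dmr_annotation_counts": dmr_df["annotation"].value_counts()
            .to_dict() if len(dmr_df) else {},
            "n_shores": len(shores),
            "de": summary_de,
            "canyon_promoter_links": len(links),
            "shrinking_canyon_contingency": contingency,
            "enhancer_central_median_shift": central["median_shift"],
        }

        if outdir is not None:
            outdir = Path(outdir)
            outdir.mkdir(parents=True, exist_ok=True)
            write_outputs(sim, outdir / "simulated")
            canyon_df.to_csv(outdir / "canyons.tsv", sep="\t", index=False)
            dmr_df.to_csv(outdir / "dmrs.tsv", sep="\t", index=False)
            shores_to_frame(shores).to_csv(outdir / "shores.tsv", sep="\t",
                                           index=False)
            de.to_csv(outdir / "de_records.tsv", sep="\t", index=False)
            scatter.to_csv(outdir / "delta_vs_expression.tsv", sep="\t",
                           index=False)
            links.to_csv(outdir / "canyon_promoter_links.tsv", sep="\t",
                         index=False)
            np.savetxt(outdir / "enhancer_density_wt.tsv", dmap_wt.counts,
                       fmt="%d", delimiter="\t")
            np.savetxt(outdir / "enhancer_density_dko.tsv", dmap_dko.counts,
                       fmt="%d", delimiter="\t")
            (outdir / "report.json").write_text(json.dumps(summary, indent=2,
                                                           default=str))
        return PipelineReport(summary=summary, canyons=canyon_df, dmrs=dmr_df,
                              shores=shores_to_frame(shores), de_records=de,
                              scatter=scatter, density_wt=dmap_wt.counts,
                              density_dko=dmap_dko.counts)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
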