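#!/usr/bin/env python
"""Region detection: UMRs, canyons with edge dynamics, DMRs, CGI shores.

Prints the category counts and the shrinking/expanding percentages;
writes results/canyons.tsv, results/dmrs.tsv, results/shores.tsv.
"""

import sys
from pathlib import Path

from methcanyon.config import SimConfig
from methcanyon.integration import fraction_report
from methcanyon.regions import (annotate_dmrs, build_shores, call_canyons,
                                call_dmrs, call_umrs, canyons_to_frame,
                                classify_canyon_dynamics, dmrs_to_frame,
                                shores_to_frame)
from methcanyon.simulate import simulate_all
from methcanyon.tracks import pool_tracks

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 101


def main() -> None:
    sim = simulate_all(SimConfig(seed=SEED))
    pw = pool_tracks(sim.tracks_wt, sample="WT_pooled")
    pdk = pool_tracks(sim.tracks_dko, sample="DKO_pooled")

    umrs = call_umrs(pw)
    canyons = classify_canyon_dynamics(call_canyons(umrs), pw, pdk)
    labeled = [c for c in canyons if c.dynamics != "missing"]
    n_shrink = sum(c.dynamics == "shrinking" for c in labeled)
    n_expand = sum(c.dynamics == "expanding" for c in labeled)
    print(f"{len(umrs)} UMRs; {len(canyons)} canyons (>=3.5 kb)")
    print(f"shrinking: {n_shrink} "
          f"({fraction_report(n_shrink, len(labeled))}%), "
          f"expanding: {n_expand}, "
          f"stable: {len(labeled) - n_shrink - n_expand}")

    dmrs = annotate_dmrs(call_dmrs(pw, pdk), sim.annotation.genes)
    n_gain = sum(d.direction == "gain" for d in dmrs)
    if dmrs:
        print(f"{len(dmrs)} DMRs, {n_gain} gained "
              f"({fraction_report(n_gain, len(dmrs))}%)")
        by_class = dmrs_to_frame(dmrs)["annotation"].value_counts()
        print("DMR annotation:", by_class.to_dict())

    shores = build_shores(sim.annotation.cgis,
                          chrom_lengths=sim.annotation.chrom_lengths,
                          genes=sim.annotation.genes)
    n_prom = sum(s.promoter_overlap for s in shores)
    print(f"{len(shores)} CGI shores, {n_prom} at promoters")

    Path("results").mkdir(exist_ok=True)
    canyons_to_frame(canyons).to_csv("results/canyons.tsv", sep="\t",
                                     index=False)
    dmrs_to_frame(dmrs).to_csv("results/dmrs.tsv", sep="\t", index=False)
    shores_to_frame(shores).to_csv("results/shores.tsv", sep="\t", index=False)
    print("wrote results/{canyons,dmrs,shores}.tsv")


if __name__ == "__main__":
    main()
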