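#!/usr/bin/env python
"""Generate the synthetic WT/DKO methylome + transcriptome dataset.

Writes the full plain-text dataset (cytosine reports, annotations, RNA
counts, truth tables) under results/simulated/ and prints what was
planted.  Later analysis steps re-derive everything from the same seed,
so this step is for inspection and for feeding external tools.
"""

import sys

from methcanyon.config import SimConfig
from methcanyon.simulate import simulate_all, write_outputs

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 101


def main() -> None:
    cfg = SimConfig(seed=SEED)
    sim = simulate_all(cfg)
    write_outputs(sim, "results/simulated")
    truth = sim.annotation.truth
    print(f"seed {SEED}: {cfg.n_chroms} chromosomes x {cfg.chrom_length:,} bp, "
          f"{sim.tracks_wt[0].n_sites:,} CpGs per track")
    print(f"planted: {len(sim.annotation.genes)} genes, "
          f"{len(sim.annotation.cgis)} CGIs, "
          f"{len(sim.annotation.enhancers)} enhancers, "
          f"{len(truth.canyons)} canyons "
          f"({(truth.canyons['dynamics'] == 'shrinking').sum()} shrinking)")
    de = truth.de_genes["direction"].value_counts().to_dict()
    print(f"planted DE genes: {de}")
    print("wrote results/simulated/")


if __name__ == "__main__":
    main()
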