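"""Recovery and calibration scoring against the generator's truth sets.

Every function here re-runs the relevant pipeline stage on freshly
simulated data and scores it against the planted truth, so the numbers
are always produced by computation, never stored.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import SimConfig
from .expression import de_summary, de_test
from .regions import call_canyons, call_dmrs, call_umrs, classify_canyon_dynamics
from .simulate import (SimResult, null_config, simulate_all, simulate_counts)
from .tracks import MethTrack, pool_tracks


def _match_truth(canyons, truth_row):
    return [c for c in canyons
            if c.chrom == truth_row["chrom"]
            and c.start < truth_row["cpg_end"]
            and c.end > truth_row["cpg_start"]]


def canyon_recovery(sim: SimResult, track: MethTrack) -> dict:
    """Fraction of planted canyons recovered with both boundaries within
    two median inter-CpG spacings of the planted (CpG-snapped) interval."""
    canyons = call_canyons(call_umrs(track))
    truth = sim.annotation.truth.canyons
    gaps = np.concatenate([np.diff(c.pos) for c in track.chroms.values()])
    tol = 2.0 * float(np.median(gaps))
    recovered = 0
    for _, t in truth.iterrows():
        hits = _match_truth(canyons, t)
        if hits and max(abs(hits[0].start - t["cpg_start"]),
                        abs(hits[0].end - t["cpg_end"])) <= tol:
            recovered += 1
    return {"recovered": recovered, "n_planted": len(truth),
            "fraction": recovered / len(truth) if len(truth) else float("nan"),
            "boundary_tolerance_bp": tol, "n_called": len(canyons)}


def dynamics_scores(sim: SimResult, pooled_wt: MethTrack,
                    pooled_dko: MethTrack) -> dict:
    """Sensitivity for planted shrinking canyons and the false-shrinking
    rate among planted stable canyons."""
    canyons = classify_canyon_dynamics(
        call_canyons(call_umrs(pooled_wt)), pooled_wt, pooled_dko)
    truth = sim.annotation.truth.canyons
    tp = fn = fp = n_stable = 0
    for _, t in truth.iterrows():
        hits = _match_truth(canyons, t)
        if not hits or hits[0].dynamics == "missing":
            if t["dynamics"] == "shrinking":
                fn += 1
            continue
        label = hits[0].dynamics
        if t["dynamics"] == "shrinking":
            tp += label == "shrinking"
            fn += label != "shrinking"
        else:
            n_stable += 1
            fp += label == "shrinking"
    return {"sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
            "false_shrinking_rate": fp / n_stable if n_stable else 0.0,
            "n_shrinking_truth": tp + fn, "n_stable_truth": n_stable}


def dmr_null_false_window_rate(base_config: SimConfig, n_seeds: int = 20,
                               dmr_max_q: float = 0.05) -> dict:
    """Fraction of sliding windows called significant on effect-free
    simulations (empirical FDR of the windowed Fisher + BH caller)."""
    tot = sig = 0
    for i in range(n_seeds):
        cfg = null_config(base_config.replace(seed=base_config.seed + i))
        sim = simulate_all(cfg)
        _, win = call_dmrs(pool_tracks(sim.tracks_wt),
                           pool_tracks(sim.tracks_dko),
                           dmr_max_q=dmr_max_q, return_windows=True)
        tot += len(win)
        sig += int(win["significant"].sum())
    return {"rate": sig / tot if tot else float("nan"),
            "n_windows": tot, "n_significant": sig, "n_seeds": n_seeds}


def _sample_names(n_replicates: int) -> tuple[list[str], list[str]]:
    return ([f"WT_rep{i + 1}" for i in range(n_replicates)],
            [f"DKO_rep{i + 1}" for i in range(n_replicates)])


def de_null_calibration(n_seeds: int = 20, n_genes: int = 500,
                        base_seed: int = 0) -> dict:
    """p <= 0.05 fraction with no planted DE, under the test's sampling
    model (Poisson counts; the exact binomial is calibrated there)."""
    tot = sig = called = 0
    for i in range(n_seeds):
        cfg = SimConfig(seed=base_seed + i, n_genes=n_genes, de_fraction=0.0,
                        nb_dispersion=0.0)
        genes = pd.DataFrame({"gene_id": [f"g{k}" for k in range(n_genes)]})
        counts, _ = simulate_counts(genes, cfg)
        wt, dko = _sample_names(cfg.n_replicates)
        de = de_test(counts, wt, dko)
        sig += int((de["p"] <= 0.05).sum())
        called += int((de["status"] != "ns").sum())
        tot += len(de)
    return {"p05_fraction": sig / tot, "both_gates_fraction": called / tot,
            "n_genes_total": tot, "n_seeds": n_seeds}


def de_skew_recovery(seed: int = 0, n_genes: int = 1_000) -> dict:
    """Recovered up:down ratio for a planted 2:1 skew at large effect."""
    cfg = SimConfig(seed=seed, n_genes=n_genes, de_fraction=0.1,
                    de_up_to_down_ratio=2.0)
    genes = pd.DataFrame({"gene_id": [f"g{k}" for k in range(n_genes)]})
    counts, truth = simulate_counts(genes, cfg)
    wt, dko = _sample_names(cfg.n_replicates)
    summary = de_summary(de_test(counts, wt, dko))
    summary["planted_up"] = int((truth["direction"] == "up").sum())
    summary["planted_down"] = int((truth["direction"] == "down").sum())
    return summary
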