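"""RNA count normalization and differential-expression classification.

Genes are called up or down between WT and the TET-knockout condition
using the thresholds of the source analysis: p <= 0.05 together with a
linear fold change strictly above 1.5 (up) or strictly below 0.67 (down).
The p-value comes from a two-sided exact binomial test on pooled raw
counts (the gene's pooled knockout count against the knockout share of
the total library), with an optional BH-adjusted gating mode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

FC_UP = 1.5
FC_DOWN = 0.67
P_MAX = 0.05


def normalize_counts(counts: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Counts-per-million normalization.

    Returns (CPM matrix, per-sample library sizes).  A sample whose
    column sums to zero cannot be normalized and raises ``ValueError``.
    """
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    lib = counts.sum(axis=0)
    zero = lib[lib == 0]
    if len(zero):
        raise ValueError(f"all-zero sample column(s): {list(zero.index)}")
    cpm = counts / lib * 1e6
    return cpm, lib


def de_test(counts: pd.DataFrame, wt_samples: list[str],
            dko_samples: list[str], pseudocount: float = 0.5,
            adjust: bool = False) -> pd.DataFrame:
    """Per-gene differential-expression records between WT and knockout.

    Fold change = (mean CPM_DKO + pseudocount)/(mean CPM_WT + pseudocount).
    p is a two-sided exact binomial test of the pooled knockout count
    against the knockout library share.  Status: up if FC > 1.5 and
    p <= 0.05; down if FC < 0.67 and p <= 0.05; else ns.  Inequalities on
    the fold change are strict; p = 0.05 is inclusive.  With ``adjust``
    the gate uses BH-adjusted q instead of raw p.
    """
    if len(wt_samples) < 2 or len(dko_samples) < 2:
        raise ValueError("need >= 2 replicates per genotype")
    cpm, lib = normalize_counts(counts)
    mean_wt = cpm[wt_samples].mean(axis=1)
    mean_dko = cpm[dko_samples].mean(axis=1)
    fc = (mean_dko + pseudocount) / (mean_wt + pseudocount)

    pooled_wt = counts[wt_samples].sum(axis=1).to_numpy()
    pooled_dko = counts[dko_samples].sum(axis=1).to_numpy()
    share_dko = float(lib[dko_samples].sum() / lib.sum())

    pvals = np.ones(len(counts))
    for i, (k, nwt) in enumerate(zip(pooled_dko, pooled_wt)):
        n = int(k + nwt)
        if n > 0:
            pvals[i] = stats.binomtest(int(k), n, share_dko,
                                       alternative="two-sided").pvalue
    gate_p = multipletests(pvals, method="fdr_bh")[1] if adjust else pvals

    status = np.where((fc > FC_UP) & (gate_p <= P_MAX), "up",
                      np.where((fc < FC_DOWN) & (gate_p <= P_MAX), "down", "ns"))
    return pd.DataFrame({
        "gene_id": counts.index,
        "mean_cpm_wt": mean_wt.to_numpy(),
        "mean_cpm_dko": mean_dko.to_numpy(),
        "fold_change": fc.to_numpy(),
        "log2_fold_change": np.log2(fc.to_numpy()),
        "p": pvals,
        "status": status,
    }).set_index("gene_id", drop=False).rename_axis(None)


def de_summary(records: pd.DataFrame) -> dict:
    """Counts of up/down/ns genes and the up:down ratio."""
    n_up = int((records["status"] == "up").sum())
    n_down = int((records["status"] == "down").sum())
    n_ns = int((records["status"] == "ns").sum())
    ratio = n_up / n_down if n_down else math.nan
    return {"up": n_up, "down": n_down, "ns": n_ns, "up_down_ratio": ratio}
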