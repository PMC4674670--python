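"""Seeded generator of matched WT/knockout bisulfite tracks, annotations
and RNA counts.

The generator plants the genomic structure the downstream analysis
assumes — a mostly methylated genome with unmethylated CpG islands, long
(>= 3.5 kb) promoter canyons, intermediate-methylation enhancers — and a
knockout (DKO) condition that adds a slight global methylation gain,
hypermethylation at the edge windows of a planted "shrinking" canyon
subset, hypermethylation at enhancer flanks, and differentially expressed
genes with a configurable (default ~2:1) up:down skew.  Reads are sampled
per replicate: coverage ~ Poisson, methylated reads ~ Binomial from a
true per-CpG level shared across replicates.  Every planted feature is
recorded in a truth set so recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import make_genes, write_bed, write_gene_models
from .config import SimConfig
from .regions import edge_windows
from .tracks import ChromSites, MethTrack, write_cytosine_report

_CGI_HALF = 500           # promoter CGI = TSS +/- 500 bp
_SLOT_MARGIN = 600        # keeps promoter CGIs inside their gene slot
_PLACEMENT_TRIES = 2000
_CANYON_SNAP_MARGIN = 300  # planted length margin: the observable extent
                           # (first to last CpG) must stay >= 3.5 kb
_FEATURE_CLEARANCE = 600   # bp between low-methylation features, beyond the
                           # 500 bp gap-merge range of the region caller

# rng stream ids (spawn keys off the master seed)
_S_ANNOT, _S_CPG, _S_TRUEP, _S_READS, _S_COUNTS = 0, 1, 2, 3, 4


def _rng(config: SimConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=key))


@dataclass
class TruthSet:
    """Planted features: the oracle for recovery scoring."""

    canyons: pd.DataFrame          # chrom,start,end,name,dynamics,gene_id
    dmrs: pd.DataFrame             # chrom,start,end,name,direction,kind
    de_genes: pd.DataFrame         # gene_id,direction
    enhancer_gain: pd.DataFrame    # chrom,start,end,name


@dataclass
class Annotation:
    chrom_lengths: dict[str, int]
    genes: pd.DataFrame
    cgis: pd.DataFrame
    enhancers: pd.DataFrame
    truth: TruthSet


@dataclass
class SimResult:
    config: SimConfig
    annotation: Annotation
    tracks_wt: list[MethTrack]
    tracks_dko: list[MethTrack]
    counts: pd.DataFrame
    de_truth: pd.DataFrame


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def simulate_annotation(config: SimConfig) -> Annotation:
    """Place genes, promoter CGIs, canyons and enhancers on the genome.

    Genes occupy disjoint slots; canyons are planted at promoter-CGI
    genes on alternating slots so planted canyons never touch; enhancers
    are rejection-placed clear of CGIs, canyons and one another.  Raises
    ``ValueError`` naming the violated constraint when the requested
    feature counts cannot be placed.
    """
    rng = _rng(config, _S_ANNOT)
    L = config.chrom_length
    chroms = config.chrom_names
    lengths = {c: L for c in chroms}

    per_chrom = [config.n_genes // config.n_chroms] * config.n_chroms
    for i in range(config.n_genes % config.n_chroms):
        per_chrom[i] += 1

    gene_rows = []
    slot_of_gene = []    # (chrom index, slot index)
    for ci, chrom in enumerate(chroms):
        n = per_chrom[ci]
        if n == 0:
            continue
        slot = L // n
        if slot < config.gene_length_max + 2 * _SLOT_MARGIN + 100:
            raise ValueError(
                "config infeasible: gene slots too small — reduce n_genes, "
                "gene_length_max, or increase chrom_length")
        for si in range(n):
            slot_start = si * slot
            glen = int(rng.integers(config.gene_length_min,
                                    config.gene_length_max + 1))
            lo = slot_start + _SLOT_MARGIN
            hi = slot_start + slot - _SLOT_MARGIN - glen
            start = int(rng.integers(lo, hi + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            gene_rows.append((f"gene_{len(gene_rows):05d}", chrom,
                              start, start + glen, strand))
            slot_of_gene.append((ci, si))
    genes = make_genes(*zip(*gene_rows)) if gene_rows else make_genes([], [], [], [], [])

    # canyon hosts: promoter-CGI genes on even slots (=> pairwise clear)
    even_idx = [i for i, (_, si) in enumerate(slot_of_gene) if si % 2 == 0]
    if config.n_canyons > len(even_idx):
        raise ValueError(
            "config infeasible: n_canyons exceeds available spaced gene slots")
    canyon_hosts = sorted(rng.choice(even_idx, size=config.n_canyons,
                                     replace=False).tolist())

    # CGIs: every canyon host gets a promoter CGI; remaining CGIs go to
    # other random genes' promoters
    if config.n_cgis < config.n_canyons:
        raise ValueError("config infeasible: n_cgis < n_canyons "
                         "(canyons are planted at CGI promoters)")
    # extra CGIs go only to genes with slot clearance from every canyon
    # host, so a neighbouring promoter CGI can never sit within the
    # gap-merge range of a planted canyon
    host_set = set(canyon_hosts)
    host_slots = {slot_of_gene[i] for i in canyon_hosts}
    eligible = []
    for i, (ci, si) in enumerate(slot_of_gene):
        if i in host_set:
            continue
        if any((ci, si + d) in host_slots for d in (-1, 0, 1)):
            continue
        eligible.append(i)
    if config.n_cgis - config.n_canyons > len(eligible):
        raise ValueError("config infeasible: not enough genes clear of "
                         "canyons to host the requested n_cgis")
    extra = sorted(rng.choice(eligible, size=config.n_cgis - config.n_canyons,
                              replace=False).tolist())
    cgi_rows = []
    for gi in sorted(canyon_hosts + extra):
        g = genes.iloc[gi]
        tss = int(g["tss"])
        cgi_rows.append({"chrom": g["chrom"],
                         "start": max(tss - _CGI_HALF, 0),
                         "end": min(tss + _CGI_HALF, L),
                         "name": f"cgi_{len(cgi_rows):04d}"})
    cgis = pd.DataFrame(cgi_rows, columns=["chrom", "start", "end", "name"])

    # canyons: centred on the host TSS, length >= 3.5 kb, clipped inside
    # the chromosome without shortening
    n_shrink = int(round(config.edge_gain_fraction * config.n_canyons))
    canyon_rows = []
    for k, gi in enumerate(canyon_hosts):
        g = genes.iloc[gi]
        clen = int(rng.integers(config.canyon_length_min + _CANYON_SNAP_MARGIN,
                                config.canyon_length_max + 1))
        start = max(0, int(g["tss"]) - clen // 2)
        end = start + clen
        if end > L:
            end, start = L, L - clen
        canyon_rows.append({"chrom": g["chrom"], "start": start, "end": end,
                            "name": f"canyon_{k:03d}", "dynamics": "stable",
                            "gene_id": g["gene_id"]})
    canyons = pd.DataFrame(canyon_rows, columns=["chrom", "start", "end",
                                                 "name", "dynamics", "gene_id"])
    if len(canyons):
        shrink_idx = rng.choice(len(canyons), size=n_shrink, replace=False)
        canyons.loc[canyons.index[shrink_idx], "dynamics"] = "shrinking"

    # enhancers: rejection-placed clear of CGIs, canyons, other enhancers
    avoid = {c: [] for c in chroms}
    for df in (cgis, canyons):
        for _, r in df.iterrows():
            avoid[r["chrom"]].append((int(r["start"]) - _FEATURE_CLEARANCE,
                                      int(r["end"]) + _FEATURE_CLEARANCE))
    enh_rows = []
    elen = config.enhancer_length
    for k in range(config.n_enhancers):
        placed = False
        for _ in range(_PLACEMENT_TRIES):
            chrom = chroms[int(rng.integers(config.n_chroms))]
            start = int(rng.integers(0, L - elen))
            end = start + elen
            if any(start < ae and end > as_ for as_, ae in avoid[chrom]):
                continue
            enh_rows.append({"chrom": chrom, "start": start, "end": end,
                             "name": f"enh_{k:04d}"})
            avoid[chrom].append((start - 200, end + 200))
            placed = True
            break
        if not placed:
            raise ValueError(
                "config infeasible: could not place enhancers clear of "
                "CGIs/canyons — reduce n_enhancers or feature sizes")
    enhancers = pd.DataFrame(enh_rows, columns=["chrom", "start", "end", "name"])

    truth = TruthSet(canyons=canyons,
                     dmrs=_truth_dmrs(canyons, enhancers, config),
                     de_genes=pd.DataFrame(columns=["gene_id", "direction"]),
                     enhancer_gain=_enhancer_flanks(enhancers))
    return Annotation(chrom_lengths=lengths, genes=genes, cgis=cgis,
                      enhancers=enhancers, truth=truth)


def _enhancer_flanks(enhancers: pd.DataFrame) -> pd.DataFrame:
    """Outer thirds of each enhancer (the planted DKO hypermethylation zone)."""
    rows = []
    for _, e in enhancers.iterrows():
        s, en = int(e["start"]), int(e["end"])
        third = (en - s) // 3
        rows.append({"chrom": e["chrom"], "start": s, "end": s + third,
                     "name": f"{e['name']}_left"})
        rows.append({"chrom": e["chrom"], "start": en - third, "end": en,
                     "name": f"{e['name']}_right"})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def _truth_dmrs(canyons: pd.DataFrame, enhancers: pd.DataFrame,
                config: SimConfig) -> pd.DataFrame:
    """Intervals where the knockout truly differs: shrinking-canyon edge
    windows and enhancer flanks, all methylation gains."""
    rows = []
    if config.edge_gain_delta > 0:
        for _, c in canyons[canyons["dynamics"] == "shrinking"].iterrows():
            left, right = edge_windows(int(c["start"]), int(c["end"]))
            for side, (s, e) in (("left", left), ("right", right)):
                rows.append({"chrom": c["chrom"], "start": s, "end": e,
                             "name": f"{c['name']}_{side}", "direction": "gain",
                             "kind": "canyon_edge"})
    if config.enhancer_gain_delta > 0:
        for _, f in _enhancer_flanks(enhancers).iterrows():
            rows.append({"chrom": f["chrom"], "start": int(f["start"]),
                         "end": int(f["end"]), "name": f["name"],
                         "direction": "gain", "kind": "enhancer_flank"})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name",
                                       "direction", "kind"])


# ---------------------------------------------------------------------------
# methylation tracks
# ---------------------------------------------------------------------------

def _interval_mask(pos: np.ndarray, intervals: pd.DataFrame,
                   chrom: str) -> np.ndarray:
    """Boolean mask of positions falling in any interval on this chromosome."""
    mask = np.zeros(len(pos), dtype=bool)
    sub = intervals[intervals["chrom"] == chrom] if len(intervals) else intervals
    for _, r in sub.iterrows():
        i = np.searchsorted(pos, int(r["start"]), side="left")
        j = np.searchsorted(pos, int(r["end"]), side="left")
        mask[i:j] = True
    return mask


def _cpg_positions(ann: Annotation, config: SimConfig) -> dict[str, np.ndarray]:
    """CpG dyad positions per chromosome: background Poisson process plus
    extra density inside CGIs/canyons (CpG-rich) and enhancers (2x)."""
    rng = _rng(config, _S_CPG)
    out = {}
    for chrom, L in ann.chrom_lengths.items():
        n_bg = rng.poisson(config.cpg_background_rate * L)
        pos = [rng.integers(0, L, size=n_bg)]
        dense = pd.concat([ann.cgis, ann.truth.canyons[["chrom", "start", "end"]]],
                          ignore_index=True) if len(ann.cgis) or \
            len(ann.truth.canyons) else pd.DataFrame(columns=["chrom", "start", "end"])
        extra_rate = max(config.cgi_cpg_rate - config.cpg_background_rate, 0.0)
        for _, r in dense[dense["chrom"] == chrom].iterrows():
            w = int(r["end"]) - int(r["start"])
            n = rng.poisson(extra_rate * w)
            pos.append(rng.integers(int(r["start"]), int(r["end"]), size=n))
        for _, r in ann.enhancers[ann.enhancers["chrom"] == chrom].iterrows():
            w = int(r["end"]) - int(r["start"])
            n = rng.poisson(config.cpg_background_rate * w)   # 2x background
            pos.append(rng.integers(int(r["start"]), int(r["end"]), size=n))
        out[chrom] = np.unique(np.concatenate(pos)).astype(np.int64)
    return out


def _true_levels(ann: Annotation, config: SimConfig,
                 positions: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Shared true per-CpG WT methylation from the feature layout."""
    rng = _rng(config, _S_TRUEP)
    k = config.beta_concentration

    def beta(mean: float, n: int) -> np.ndarray:
        mean = min(max(mean, 1e-4), 1 - 1e-4)
        return rng.beta(mean * k, (1 - mean) * k, size=n)

    out = {}
    low = pd.concat([ann.cgis[["chrom", "start", "end"]],
                     ann.truth.canyons[["chrom", "start", "end"]]],
                    ignore_index=True)
    enh = ann.enhancers
    centers = []
    for _, e in enh.iterrows():
        s, en = int(e["start"]), int(e["end"])
        third = (en - s) // 3
        centers.append({"chrom": e["chrom"], "start": s + third, "end": en - third})
    centers = pd.DataFrame(centers, columns=["chrom", "start", "end"])
    for chrom, pos in positions.items():
        p = beta(config.baseline_beta_high, len(pos))
        in_enh = _interval_mask(pos, enh, chrom)
        p[in_enh] = beta(config.enhancer_flank_beta, int(in_enh.sum()))
        in_center = _interval_mask(pos, centers, chrom)
        p[in_center] = beta(config.enhancer_center_beta, int(in_center.sum()))
        in_low = _interval_mask(pos, low, chrom)
        p[in_low] = beta(config.baseline_beta_low, int(in_low.sum()))
        out[chrom] = p
    return out


def _dko_levels(ann: Annotation, config: SimConfig,
                positions: dict[str, np.ndarray],
                wt_levels: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    shrink = ann.truth.canyons[ann.truth.canyons["dynamics"] == "shrinking"]
    edge_rows = []
    for _, c in shrink.iterrows():
        left, right = edge_windows(int(c["start"]), int(c["end"]))
        edge_rows.append({"chrom": c["chrom"], "start": left[0], "end": left[1]})
        edge_rows.append({"chrom": c["chrom"], "start": right[0], "end": right[1]})
    edges = pd.DataFrame(edge_rows, columns=["chrom", "start", "end"])
    flanks = ann.truth.enhancer_gain
    out = {}
    for chrom, pos in positions.items():
        p = wt_levels[chrom] + config.dko_global_gain
        p = p + config.edge_gain_delta * _interval_mask(pos, edges, chrom)
        p = p + config.enhancer_gain_delta * _interval_mask(pos, flanks, chrom)
        out[chrom] = np.clip(p, 0.0, 1.0)
    return out


def snap_canyon_truth(ann: Annotation, config: SimConfig,
                      positions: dict[str, np.ndarray] | None = None) -> None:
    """Snap planted canyon truth intervals to their first/last CpG.

    A planted low-methylation region is only observable from its first to
    its last CpG, which is also how called intervals are delimited; the
    snapped columns make truth and call directly comparable.
    """
    if positions is None:
        positions = _cpg_positions(ann, config)
    starts, ends = [], []
    for _, c in ann.truth.canyons.iterrows():
        pos = positions[c["chrom"]]
        i = np.searchsorted(pos, int(c["start"]), side="left")
        j = np.searchsorted(pos, int(c["end"]), side="left")
        if j > i:
            starts.append(int(pos[i]))
            ends.append(int(pos[j - 1]) + 1)
        else:                       # no CpG fell inside (tiny/empty region)
            starts.append(int(c["start"]))
            ends.append(int(c["end"]))
    ann.truth.canyons["cpg_start"] = pd.Series(starts, dtype=int) \
        if starts else pd.Series(dtype=int)
    ann.truth.canyons["cpg_end"] = pd.Series(ends, dtype=int) \
        if ends else pd.Series(dtype=int)


def simulate_methylation(ann: Annotation, config: SimConfig,
                         genotype: str,
                         positions: dict[str, np.ndarray] | None = None
                         ) -> list[MethTrack]:
    """Per-replicate read sampling from the genotype's true levels.

    Coverage ~ Poisson(coverage_mean) per CpG per replicate (zero-coverage
    sites are emitted with counts 0,0); methylated reads ~ Binomial from
    the shared true level.  The same seed yields the same CpG positions
    and true levels for both genotypes, so the only WT/DKO differences are
    the planted effects.
    """
    if genotype not in ("WT", "DKO"):
        raise ValueError(f"genotype must be WT or DKO, got {genotype!r}")
    if positions is None:
        positions = _cpg_positions(ann, config)
    p_wt = _true_levels(ann, config, positions)
    levels = p_wt if genotype == "WT" else _dko_levels(ann, config, positions, p_wt)
    gi = 0 if genotype == "WT" else 1
    tracks = []
    for rep in range(config.n_replicates):
        rng = _rng(config, _S_READS, gi, rep)
        chroms = {}
        for chrom, pos in positions.items():
            cov = rng.poisson(config.coverage_mean, size=len(pos))
            m = rng.binomial(cov, levels[chrom])
            chroms[chrom] = ChromSites(pos, m, cov - m)
        tracks.append(MethTrack(sample=f"{genotype}_rep{rep + 1}",
                                genotype=genotype, chroms=chroms))
    return tracks


# ---------------------------------------------------------------------------
# RNA counts
# ---------------------------------------------------------------------------

def simulate_counts(genes: pd.DataFrame,
                    config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene x sample negative-binomial count matrix with planted DE genes.

    Baseline means are log-uniform; planted DE genes have their knockout
    mean scaled by 2^(+/- de_log2fc) with up:down ratio
    ``de_up_to_down_ratio``.  Returns (counts, DE truth table).
    """
    rng = _rng(config, _S_COUNTS)
    n = len(genes)
    gene_ids = genes["gene_id"].to_numpy()
    base = 10 ** rng.uniform(np.log10(5), np.log10(5000), size=n)

    n_de = int(round(config.de_fraction * n))
    r = config.de_up_to_down_ratio
    n_up = int(round(n_de * r / (r + 1.0)))
    n_down = n_de - n_up
    de_idx = rng.choice(n, size=n_de, replace=False) if n_de else np.array([], int)
    lfc = np.zeros(n)
    lfc[de_idx[:n_up]] = config.de_log2fc
    lfc[de_idx[n_up:]] = -config.de_log2fc

    samples = ([f"WT_rep{i + 1}" for i in range(config.n_replicates)]
               + [f"DKO_rep{i + 1}" for i in range(config.n_replicates)])
    data = {}
    for s in samples:
        mu = base * (2.0 ** lfc) if s.startswith("DKO") else base
        if config.nb_dispersion > 0:
            shape = 1.0 / config.nb_dispersion
            data[s] = rng.negative_binomial(shape, shape / (shape + mu))
        else:
            data[s] = rng.poisson(mu)
    counts = pd.DataFrame(data, index=pd.Index(gene_ids, name="gene_id"))
    direction = np.where(lfc > 0, "up", np.where(lfc < 0, "down", None))
    de_truth = pd.DataFrame({"gene_id": gene_ids[de_idx],
                             "direction": direction[de_idx]})
    return counts, de_truth


# ---------------------------------------------------------------------------
# orchestration + file output
# ---------------------------------------------------------------------------

def simulate_all(config: SimConfig) -> SimResult:
    ann = simulate_annotation(config)
    positions = _cpg_positions(ann, config)
    snap_canyon_truth(ann, config, positions)
    tracks_wt = simulate_methylation(ann, config, "WT", positions)
    tracks_dko = simulate_methylation(ann, config, "DKO", positions)
    counts, de_truth = simulate_counts(ann.genes, config)
    ann.truth.de_genes = de_truth
    return SimResult(config=config, annotation=ann, tracks_wt=tracks_wt,
                     tracks_dko=tracks_dko, counts=counts, de_truth=de_truth)


def write_outputs(result: SimResult, outdir: str | Path) -> None:
    """Write the full synthetic dataset as plain-text files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ann = result.annotation
    write_gene_models(ann.genes, outdir / "genes.tsv")
    write_bed(ann.cgis, outdir / "cgis.bed")
    write_bed(ann.enhancers, outdir / "enhancers.bed")
    for track in result.tracks_wt + result.tracks_dko:
        write_cytosine_report(track, outdir / f"{track.sample}.cytosine.tsv")
    result.counts.to_csv(outdir / "counts.tsv", sep="\t")
    ann.truth.canyons.to_csv(outdir / "truth_canyons.tsv", sep="\t", index=False)
    ann.truth.dmrs.to_csv(outdir / "truth_dmrs.tsv", sep="\t", index=False)
    result.de_truth.to_csv(outdir / "truth_de.tsv", sep="\t", index=False)
    ann.truth.enhancer_gain.to_csv(outdir / "truth_enhancer_gain.tsv",
                                   sep="\t", index=False)
    result.config.to_yaml(outdir / "config.yaml")


def null_config(config: SimConfig) -> SimConfig:
    """The same genome with every knockout effect switched off."""
    return config.replace(dko_global_gain=0.0, edge_gain_delta=0.0,
                          enhancer_gain_delta=0.0, de_fraction=0.0)
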