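"""Per-CpG methylation tracks and cytosine-report I/O.

A :class:`MethTrack` stores strand-collapsed per-CpG read counts: one
record per CpG dyad, keyed by the 0-based position of the C on the +
strand.  Bisulfite sequencing reads 5mC and 5hmC together, so a track
measures total DNA modification, not 5mC alone.

Coordinates are 0-based half-open everywhere inside the package; the
1-based convention of the cytosine-report dialect applies only at I/O.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_MIN_COVERAGE = 5


@dataclass
class ChromSites:
    """Sorted per-chromosome CpG arrays: positions (0-based), meth/unmeth counts."""

    pos: np.ndarray
    m: np.ndarray
    u: np.ndarray

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.m = np.asarray(self.m, dtype=np.int64)
        self.u = np.asarray(self.u, dtype=np.int64)
        if not (len(self.pos) == len(self.m) == len(self.u)):
            raise ValueError("pos/m/u length mismatch")
        if np.any(self.m < 0) or np.any(self.u < 0):
            raise ValueError("negative read counts")
        if len(self.pos) > 1 and np.any(np.diff(self.pos) <= 0):
            raise ValueError("positions not strictly increasing")

    @property
    def coverage(self) -> np.ndarray:
        return self.m + self.u

    def slice(self, start: int, end: int) -> "ChromSites":
        """Sites with start <= pos < end."""
        i = np.searchsorted(self.pos, start, side="left")
        j = np.searchsorted(self.pos, end, side="left")
        return ChromSites(self.pos[i:j], self.m[i:j], self.u[i:j])


@dataclass
class MethTrack:
    """A sample's methylation track: per-chromosome sorted CpG count arrays."""

    sample: str
    genotype: str
    chroms: dict[str, ChromSites] = field(default_factory=dict)

    @property
    def n_sites(self) -> int:
        return sum(len(c.pos) for c in self.chroms.values())

    def sites(self, chrom: str, start: int | None = None,
              end: int | None = None) -> ChromSites:
        if chrom not in self.chroms:
            raise KeyError(f"unknown chromosome {chrom!r}")
        c = self.chroms[chrom]
        if start is None and end is None:
            return c
        s = 0 if start is None else start
        if end is None:
            e = int(c.pos[-1]) + 1 if len(c.pos) else 0
        else:
            e = end
        return c.slice(s, e)

    def to_frame(self) -> pd.DataFrame:
        parts = []
        for chrom in self.chroms:
            c = self.chroms[chrom]
            parts.append(pd.DataFrame({"chrom": chrom, "pos": c.pos,
                                       "m": c.m, "u": c.u}))
        if not parts:
            return pd.DataFrame(columns=["chrom", "pos", "m", "u"])
        return pd.concat(parts, ignore_index=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, sample: str = "track",
                   genotype: str = "WT") -> "MethTrack":
        chroms = {}
        for chrom, g in df.groupby("chrom", sort=True):
            g = g.sort_values("pos")
            chroms[str(chrom)] = ChromSites(g["pos"].to_numpy(),
                                            g["m"].to_numpy(),
                                            g["u"].to_numpy())
        return cls(sample=sample, genotype=genotype, chroms=chroms)


def pool_tracks(tracks: list[MethTrack], sample: str = "pooled") -> MethTrack:
    """Sum read counts across replicate tracks site-by-site.

    Replicates of one genotype share a methylome, so pooling counts is the
    maximum-information estimate of the shared per-CpG level.
    """
    if not tracks:
        raise ValueError("no tracks to pool")
    genotype = tracks[0].genotype
    chrom_names = sorted({c for t in tracks for c in t.chroms})
    chroms: dict[str, ChromSites] = {}
    for chrom in chrom_names:
        parts = [t.chroms[chrom] for t in tracks if chrom in t.chroms]
        all_pos = np.unique(np.concatenate([p.pos for p in parts]))
        m = np.zeros(len(all_pos), dtype=np.int64)
        u = np.zeros(len(all_pos), dtype=np.int64)
        for p in parts:
            idx = np.searchsorted(all_pos, p.pos)
            np.add.at(m, idx, p.m)
            np.add.at(u, idx, p.u)
        chroms[chrom] = ChromSites(all_pos, m, u)
    return MethTrack(sample=sample, genotype=genotype, chroms=chroms)


# ---------------------------------------------------------------------------
# cytosine-report I/O (Bismark dialect)
# ---------------------------------------------------------------------------

def read_cytosine_report(path: str | Path, sample: str | None = None,
                         genotype: str = "WT",
                         context: str = "CpG") -> MethTrack:
    """Parse a cytosine report into a strand-collapsed :class:`MethTrack`.

    Expected columns (tab-separated): chrom, 1-based position, strand,
    methylated count, unmethylated count, context[, trinucleotide].  A "-"
    strand record at position p is the G of the dyad whose + strand C sits
    at p-1; the two records are summed into one site.  Records whose
    context differs from ``context`` are skipped.

    Raises ``ValueError`` (with the line number) on malformed lines,
    non-integer counts, or duplicate post-collapse sites.
    """
    path = Path(path)
    records: dict[str, dict[int, list[int]]] = {}
    n_lines = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: expected >=6 columns, "
                                 f"got {len(fields)}")
            chrom, pos_s, strand, m_s, u_s, ctx = fields[:6]
            if ctx != context:
                continue
            try:
                pos1 = int(pos_s)
                m = int(m_s)
                u = int(u_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer field: {exc}")
            if pos1 < 1:
                raise ValueError(f"{path}:{lineno}: position must be >= 1")
            if m < 0 or u < 0:
                raise ValueError(f"{path}:{lineno}: negative count")
            if strand == "+":
                dyad = pos1 - 1              # to 0-based C position
            elif strand == "-":
                dyad = pos1 - 2              # G record: dyad C one bp left
            else:
                raise ValueError(f"{path}:{lineno}: bad strand {strand!r}")
            sites = records.setdefault(chrom, {})
            if dyad in sites:
                prev = sites[dyad]
                if prev[2] == strand:
                    raise ValueError(
                        f"{path}:{lineno}: duplicate {strand} record for "
                        f"{chrom}:{dyad + 1} after strand collapse")
                prev[0] += m
                prev[1] += u
                prev[2] = "*"
            else:
                sites[dyad] = [m, u, strand]
            n_lines += 1
    if n_lines == 0:
        logger.warning("cytosine report %s contained no %s records", path, context)
    chroms = {}
    for chrom in sorted(records):
        pos = np.array(sorted(records[chrom]), dtype=np.int64)
        m = np.array([records[chrom][p][0] for p in pos], dtype=np.int64)
        u = np.array([records[chrom][p][1] for p in pos], dtype=np.int64)
        chroms[chrom] = ChromSites(pos, m, u)
    return MethTrack(sample=sample or path.stem, genotype=genotype, chroms=chroms)


def write_cytosine_report(track: MethTrack, path: str | Path) -> None:
    """Write a strand-collapsed track as a + strand CpG cytosine report."""
    with open(path, "w") as fh:
        for chrom in sorted(track.chroms):
            c = track.chroms[chrom]
            for pos, m, u in zip(c.pos, c.m, c.u):
                fh.write(f"{chrom}\t{pos + 1}\t+\t{m}\t{u}\tCpG\tCGN\n")


def write_bedgraph(track: MethTrack, path: str | Path,
                   min_coverage: int = 1) -> None:
    """Export per-CpG levels as bedGraph for genome-browser inspection."""
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{track.sample}"\n')
        for chrom in sorted(track.chroms):
            c = track.chroms[chrom]
            cov = c.coverage
            keep = cov >= min_coverage
            levels = np.divide(c.m, cov, out=np.zeros(len(cov)), where=cov > 0)
            for pos, lev in zip(c.pos[keep], levels[keep]):
                fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{lev:.4f}\n")


# ---------------------------------------------------------------------------
# level summaries
# ---------------------------------------------------------------------------

def site_level(m: int, u: int, min_coverage: int = DEFAULT_MIN_COVERAGE) -> float:
    """Methylation level m/(m+u), or NaN below the coverage floor."""
    if m < 0 or u < 0:
        raise ValueError("negative counts")
    cov = m + u
    if cov < max(min_coverage, 1):
        return math.nan
    return m / cov


def region_level(track: MethTrack, chrom: str, start: int, end: int,
                 min_coverage: int = 1) -> float:
    """Count-weighted level sum(m)/sum(m+u) over covered CpGs in [start, end).

    Weighting by reads rather than averaging per-site levels keeps the
    estimate stable under uneven coverage.  NaN if no covered CpG.
    """
    if chrom not in track.chroms:
        raise KeyError(f"unknown chromosome {chrom!r}")
    sites = track.chroms[chrom].slice(start, end)
    cov = sites.coverage
    keep = cov >= max(min_coverage, 1)
    total = int(cov[keep].sum())
    if total == 0:
        return math.nan
    return int(sites.m[keep].sum()) / total


def genomewide_level_histogram(track: MethTrack, bin_width: float = 0.1,
                               min_coverage: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of per-CpG levels over [0, 1] for all covered sites.

    ``bin_width`` must divide 1 evenly.  Returns (counts, bin_edges); the
    top bin is closed so level 1.0 is counted.
    """
    n_bins = round(1.0 / bin_width)
    if abs(n_bins * bin_width - 1.0) > 1e-9:
        raise ValueError("bin_width must divide 1 evenly")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts = np.zeros(n_bins, dtype=np.int64)
    for c in track.chroms.values():
        cov = c.coverage
        keep = cov >= max(min_coverage, 1)
        levels = c.m[keep] / cov[keep]
        counts += np.histogram(levels, bins=edges)[0]
    return counts, edges
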