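"""Binned genomes and karyotypes.

A genome is represented as an ordered set of fixed-width bins (BED
convention: 0-based, half-open).  A sample's karyotype is a vector of
integer copy numbers over those bins.  These containers, together with
per-sample summaries (baseline ploidy, PGA, segment counts, three-state
gain/loss calls) and consensus-region construction, underpin every other
module in the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BinGrid",
    "CopyNumberProfile",
    "StateProfile",
    "RegionSet",
    "baseline_ploidy",
    "pga",
    "count_segments",
    "call_states",
    "consensus_regions",
    "read_cn_table",
    "write_cn_table",
    "read_logr_table",
    "LOSS",
    "BASELINE",
    "GAIN",
]

# three-state call codes
LOSS, BASELINE, GAIN = -1, 0, 1


@dataclass(frozen=True)
class BinGrid:
    """Ordered, non-overlapping genomic bins shared by a set of profiles.

    Parameters
    ----------
    chroms : per-bin chromosome labels, grouped (all bins of a chromosome
        contiguous) and sorted by position within each chromosome.
    starts, ends : 0-based half-open bin coordinates in bp.
    """

    chroms: tuple
    starts: np.ndarray
    ends: np.ndarray

    def __post_init__(self):
        starts = np.asarray(self.starts, dtype=np.int64)
        ends = np.asarray(self.ends, dtype=np.int64)
        object.__setattr__(self, "chroms", tuple(self.chroms))
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "ends", ends)
        if not (len(self.chroms) == len(starts) == len(ends)):
            raise ValueError("chroms/starts/ends length mismatch")
        if len(starts) == 0:
            raise ValueError("empty bin grid")
        if np.any(starts >= ends):
            raise ValueError("bins must satisfy start < end")
        # within-chromosome: sorted and non-overlapping
        for sl in self.chrom_slices().values():
            s, e = starts[sl], ends[sl]
            if np.any(s[1:] < e[:-1]):
                raise ValueError("bins overlap or are unsorted within a chromosome")
        # chromosomes must form contiguous blocks
        seen = set()
        prev = None
        for c in self.chroms:
            if c != prev:
                if c in seen:
                    raise ValueError(f"chromosome {c} bins are not contiguous")
                seen.add(c)
                prev = c

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def n_bins(self) -> int:
        return len(self.starts)

    def chrom_slices(self) -> dict:
        """Mapping chromosome -> slice of bin indices, in grid order."""
        out = {}
        chroms = self.chroms
        i = 0
        n = len(chroms)
        while i < n:
            j = i
            while j < n and chroms[j] == chroms[i]:
                j += 1
            out[chroms[i]] = slice(i, j)
            i = j
        return out

    def chrom_boundaries(self) -> np.ndarray:
        """Bin indices at which a new chromosome starts (excluding 0)."""
        chroms = np.asarray(self.chroms, dtype=object)
        return np.flatnonzero(chroms[1:] != chroms[:-1]) + 1

    @classmethod
    def uniform(cls, chrom_sizes: dict, bin_width: int) -> "BinGrid":
        """Tile each chromosome with fixed-width bins (last bin truncated)."""
        chroms, starts, ends = [], [], []
        for chrom, size in chrom_sizes.items():
            edges = list(range(0, size, bin_width))
            for s in edges:
                chroms.append(chrom)
                starts.append(s)
                ends.append(min(s + bin_width, size))
        return cls(tuple(chroms), np.array(starts), np.array(ends))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": list(self.chroms), "start": self.starts, "end": self.ends}
        )


@dataclass(frozen=True)
class CopyNumberProfile:
    """Integer copy number per bin for one sample."""

    grid: BinGrid
    cn: np.ndarray
    sample_id: str = "sample"

    def __post_init__(self):
        cn = np.asarray(self.cn, dtype=np.int64)
        object.__setattr__(self, "cn", cn)
        if len(cn) != self.grid.n_bins:
            raise ValueError("copy-number vector length does not match grid")
        if np.any(cn < 0):
            raise ValueError("copy numbers must be >= 0")

    def baseline_ploidy(self) -> int:
        return baseline_ploidy(self)

    def pga(self, baseline: int | None = None) -> float:
        if baseline is None:
            baseline = baseline_ploidy(self)
        return pga(self, baseline)


@dataclass(frozen=True)
class StateProfile:
    """Three-state (loss/baseline/gain) calls per bin for one sample."""

    grid: BinGrid
    states: np.ndarray
    sample_id: str = "sample"

    def __post_init__(self):
        st = np.asarray(self.states, dtype=np.int8)
        object.__setattr__(self, "states", st)
        if len(st) != self.grid.n_bins:
            raise ValueError("state vector length does not match grid")
        if not np.all(np.isin(st, (LOSS, BASELINE, GAIN))):
            raise ValueError("states must be in {-1, 0, +1}")


@dataclass(frozen=True)
class RegionSet:
    """Contiguous bin-index regions retained for region-level analyses.

    ``regions`` holds (chrom, start_bin, end_bin) with half-open bin-index
    ranges that never cross a chromosome boundary; regions shorter than
    ``min_bins`` were dropped at construction.
    """

    grid: BinGrid
    regions: tuple
    min_bins: int

    def n_retained_bins(self) -> int:
        return sum(e - s for _, s, e in self.regions)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom, s, e in self.regions:
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(self.grid.starts[s]),
                    "end": int(self.grid.ends[e - 1]),
                    "n_bins": e - s,
                }
            )
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_bins"])


def baseline_ploidy(profile: CopyNumberProfile) -> int:
    """Median per-bin integer copy number; even-count ties go to the lower
    middle value so the baseline is always an attained copy number."""
    cn = profile.cn
    if len(cn) == 0:
        raise ValueError("empty profile")
    return int(np.partition(cn, (len(cn) - 1) // 2)[(len(cn) - 1) // 2])


def pga(profile: CopyNumberProfile, baseline: int) -> float:
    """Fraction of bins whose copy number differs from the baseline ploidy."""
    if baseline < 0:
        raise ValueError("baseline must be >= 0")
    return float(np.mean(profile.cn != baseline))


def count_segments(profile: CopyNumberProfile, chrom_breaks: bool = True) -> int:
    """Number of maximal runs of constant copy number.

    With ``chrom_breaks`` (default) adjacency never crosses chromosomes, so a
    fully constant genome yields one segment per chromosome.
    """
    cn = profile.cn
    changes = int(np.count_nonzero(np.diff(cn)))
    if chrom_breaks:
        n_chrom = len(profile.grid.chrom_slices())
        # changes falling exactly on a chromosome boundary should not count
        bounds = profile.grid.chrom_boundaries()
        at_bounds = int(np.count_nonzero(cn[bounds] != cn[bounds - 1])) if len(bounds) else 0
        return n_chrom + changes - at_bounds
    return 1 + changes


def call_states(profile: CopyNumberProfile, baseline: int) -> StateProfile:
    """Per-bin gain/loss/baseline calls relative to a baseline ploidy."""
    if baseline < 1:
        raise ValueError("baseline must be >= 1")
    st = np.sign(profile.cn - baseline).astype(np.int8)
    return StateProfile(profile.grid, st, profile.sample_id)


def _check_shared_grid(profiles: Sequence[CopyNumberProfile]) -> BinGrid:
    grid = profiles[0].grid
    for p in profiles[1:]:
        if p.grid is not grid and (
            p.grid.chroms != grid.chroms
            or not np.array_equal(p.grid.starts, grid.starts)
            or not np.array_equal(p.grid.ends, grid.ends)
        ):
            raise ValueError("profiles do not share one bin grid")
    return grid


def consensus_regions(
    profiles: Sequence[CopyNumberProfile],
    min_bins: int = 4,
    chrom_breaks: bool = True,
) -> RegionSet:
    """Split the genome at breakpoints seen in at least one sample.

    A breakpoint is a copy-number difference between two consecutive bins in
    any sample (chromosome boundaries always break).  Regions spanning fewer
    than ``min_bins`` bins are dropped (default 4; use 2 for single-cell
    data).
    """
    if not profiles:
        raise ValueError("need at least one profile")
    grid = _check_shared_grid(list(profiles))
    cn = np.stack([p.cn for p in profiles])
    internal = np.flatnonzero(np.any(cn[:, 1:] != cn[:, :-1], axis=0)) + 1
    breaks = set(internal.tolist())
    if chrom_breaks:
        breaks.update(grid.chrom_boundaries().tolist())
    cuts = [0] + sorted(breaks) + [grid.n_bins]
    regions = []
    for s, e in zip(cuts[:-1], cuts[1:]):
        if e - s >= min_bins:
            regions.append((grid.chroms[s], s, e))
    return RegionSet(grid, tuple(regions), min_bins)


# ---------------------------------------------------------------------------
# TSV interfaces (BED-like: chrom, start, end, one column per sample)

def read_cn_table(path) -> tuple[BinGrid, dict]:
    df = pd.read_csv(path, sep="\t")
    grid = BinGrid(tuple(df["chrom"]), df["start"].to_numpy(), df["end"].to_numpy())
    samples = {}
    for col in df.columns[3:]:
        samples[col] = CopyNumberProfile(grid, df[col].to_numpy(dtype=np.int64), col)
    return grid, samples


def write_cn_table(path, profiles: Iterable[CopyNumberProfile]) -> None:
    profiles = list(profiles)
    grid = _check_shared_grid(profiles)
    df = grid.to_frame()
    for p in profiles:
        df[p.sample_id] = p.cn
    df.to_csv(path, sep="\t", index=False)


def read_logr_table(path) -> tuple[BinGrid, dict]:
    """Read a BED-like table of per-bin log2 ratios (float columns)."""
    df = pd.read_csv(path, sep="\t")
    grid = BinGrid(tuple(df["chrom"]), df["start"].to_numpy(), df["end"].to_numpy())
    return grid, {c: df[c].to_numpy(dtype=float) for c in df.columns[3:]}
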