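"""Pairwise CNA divergence statistics for multi-region / multi-timepoint data.

Six statistics quantify how different two binned copy-number profiles are.
State-based metrics compare three-state (gain/baseline/loss) calls made
against each sample's own baseline ploidy, so a clonally genome-doubled
pair is not maximally divergent:

* ``FracDiffBins`` — bins with discordant state / all bins.
* ``FracDiffAltBins`` — bins with discordant state / bins that are
  non-baseline in at least one of the pair (the "proportion of aberrant
  genome subclonal", PoAGS; 0 when nothing is altered).
* ``GeneDoseFDB`` / ``GeneDoseFDAB`` — the same two ratios with each bin
  weighted by its gene content.
* ``GeneticDistance`` — mean per-bin absolute integer copy-number
  difference.
* ``BreakpointDivergence`` — breakpoints private to one sample / breakpoints
  present in either (breakpoint = bin boundary where the state changes).

Cohort-level summaries: ``divergence`` (mean PoAGS over sample pairs),
``proportion_subclonal`` (altered bins with non-uniform states across all
samples), and ``mean_pga_difference`` (percentage points).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product
from typing import Sequence

import numpy as np
import pandas as pd

from .grid import (
    BASELINE,
    CopyNumberProfile,
    _check_shared_grid,
    baseline_ploidy,
    call_states,
    pga,
)

METRICS = (
    "FracDiffBins",
    "FracDiffAltBins",
    "GeneDoseFDB",
    "GeneDoseFDAB",
    "GeneticDistance",
    "BreakpointDivergence",
)

__all__ = [
    "METRICS",
    "DivergenceResult",
    "pairwise_divergence",
    "divergence",
    "proportion_subclonal",
    "mean_pga_difference",
    "pairwise_matrix",
]


@dataclass(frozen=True)
class DivergenceResult:
    metric: str
    value: float
    pair: tuple


def _states(p: CopyNumberProfile, baseline: int | None) -> np.ndarray:
    b = baseline_ploidy(p) if baseline is None else baseline
    return call_states(p, b).states


def _breakpoints(states: np.ndarray, boundaries: np.ndarray) -> set:
    """Bin-boundary indices (between i-1 and i) where the state changes,
    never crossing chromosomes."""
    pos = np.flatnonzero(states[1:] != states[:-1]) + 1
    return set(pos.tolist()) - set(boundaries.tolist())


def pairwise_divergence(
    a: CopyNumberProfile,
    b: CopyNumberProfile,
    metric: str,
    weights: np.ndarray | None = None,
    baseline_a: int | None = None,
    baseline_b: int | None = None,
) -> DivergenceResult:
    """One divergence statistic for a pair of profiles on a shared grid.

    ``weights`` (gene counts per bin) are required for the GeneDose metrics.
    Baselines default to each sample's own median ploidy; pass explicit
    values to compare against a patient-shared baseline.
    """
    grid = _check_shared_grid([a, b])
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    pair = (a.sample_id, b.sample_id)

    if metric == "GeneticDistance":
        value = float(np.abs(a.cn - b.cn).sum() / grid.n_bins)
        return DivergenceResult(metric, value, pair)

    sa = _states(a, baseline_a)
    sb = _states(b, baseline_b)

    if metric == "BreakpointDivergence":
        bounds = grid.chrom_boundaries()
        bp_a = _breakpoints(sa, bounds)
        bp_b = _breakpoints(sb, bounds)
        union = bp_a | bp_b
        value = len(bp_a ^ bp_b) / len(union) if union else 0.0
        return DivergenceResult(metric, value, pair)

    diff = sa != sb
    altered = (sa != BASELINE) | (sb != BASELINE)
    if metric in ("GeneDoseFDB", "GeneDoseFDAB"):
        if weights is None:
            raise ValueError("GeneDose metrics require per-bin gene weights")
        w = np.asarray(weights, dtype=float)
        if len(w) != grid.n_bins or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("invalid gene weights")
        if metric == "GeneDoseFDB":
            value = float(w[diff].sum() / w.sum())
        else:
            denom = w[altered].sum()
            value = float(w[diff].sum() / denom) if denom > 0 else 0.0
    elif metric == "FracDiffBins":
        value = float(diff.mean())
    else:  # FracDiffAltBins
        n_alt = int(altered.sum())
        value = float(diff.sum() / n_alt) if n_alt else 0.0
    return DivergenceResult(metric, value, pair)


def _pairs(profiles_a, profiles_b):
    if profiles_a is profiles_b or [p.sample_id for p in profiles_a] == [
        p.sample_id for p in profiles_b
    ]:
        return list(combinations(profiles_a, 2))
    return list(product(profiles_a, profiles_b))


def divergence(
    profiles_a: Sequence[CopyNumberProfile],
    profiles_b: Sequence[CopyNumberProfile] | None = None,
    metric: str = "FracDiffAltBins",
    weights: np.ndarray | None = None,
) -> dict:
    """Mean (and range) of a pairwise metric over a comparison group.

    With one set: unordered within-set pairs (self-pairs excluded).  With
    two sets (e.g. consecutive timepoints): all cross pairs.
    """
    profiles_a = list(profiles_a)
    same = profiles_b is None
    profiles_b = profiles_a if same else list(profiles_b)
    if not profiles_a or not profiles_b:
        raise ValueError("empty profile set")
    pairs = _pairs(profiles_a, profiles_b)
    if not pairs:
        raise ValueError("no pairs to compare (need >=2 samples within a set)")
    vals = np.array(
        [pairwise_divergence(x, y, metric, weights).value for x, y in pairs]
    )
    return {
        "metric": metric,
        "mean": float(vals.mean()),
        "min": float(vals.min()),
        "max": float(vals.max()),
        "n_pairs": len(vals),
        "values": vals,
    }


def pairwise_matrix(
    profiles: Sequence[CopyNumberProfile],
    metric: str = "FracDiffAltBins",
    weights: np.ndarray | None = None,
) -> pd.DataFrame:
    """Symmetric matrix of pairwise divergence values (zero diagonal)."""
    profiles = list(profiles)
    ids = [p.sample_id for p in profiles]
    n = len(profiles)
    m = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        v = pairwise_divergence(profiles[i], profiles[j], metric, weights).value
        m[i, j] = m[j, i] = v
    return pd.DataFrame(m, index=ids, columns=ids)


def proportion_subclonal(profiles: Sequence[CopyNumberProfile]) -> float:
    """Among bins altered in >=1 sample, the fraction whose state vector is
    not identical across all samples."""
    profiles = list(profiles)
    if len(profiles) < 2:
        raise ValueError("need >=2 profiles")
    _check_shared_grid(profiles)
    states = np.stack([_states(p, None) for p in profiles])
    altered = np.any(states != BASELINE, axis=0)
    if not altered.any():
        return 0.0
    uniform = np.all(states == states[0], axis=0)
    return float(np.sum(altered & ~uniform) / np.sum(altered))


def mean_pga_difference(
    profiles_a: Sequence[CopyNumberProfile],
    profiles_b: Sequence[CopyNumberProfile] | None = None,
) -> float:
    """Mean absolute PGA difference over pairs, in percentage points."""
    profiles_a = list(profiles_a)
    profiles_b = profiles_a if profiles_b is None else list(profiles_b)
    if not profiles_a or not profiles_b:
        raise ValueError("empty profile set")
    pairs = _pairs(profiles_a, profiles_b)
    if not pairs:
        raise ValueError("no pairs to compare")
    diffs = [
        abs(pga(x, baseline_ploidy(x)) - pga(y, baseline_ploidy(y))) for x, y in pairs
    ]
    return float(np.mean(diffs) * 100.0)
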