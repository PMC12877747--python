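"""Multi-sample absolute copy number from shallow-WGS log2 ratios.

Shallow WGS yields only a per-bin log2 ratio per sample.  Following the
ASCAT transformation, a log2 ratio maps to an absolute copy number given a
tumor purity rho and tumor ploidy psi:

    cn = (2^logr * (2(1 - rho) + rho * psi) - 2(1 - rho)) / rho

A grid search over ploidy (1.5-4) and purity (class-dependent floor: 0.5
for microdissected "region" samples, 0.2 for "bulk" samples) scores each
candidate ploidy by (a) the mean per-sample fit error -- mean squared
deviation of implied copy numbers from integers at the best purity -- and
(b) the mean pairwise distance between samples' ploidy-normalized rounded
copy numbers (bins with log2 ratio > 1 excluded to keep amplifications
from dominating).  Both scores are min-max scaled over the ploidy grid and
candidates are ranked by distance from the (0, 0) corner, so the chosen
ploidy fits well within every sample and is consistent across samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

from .grid import BinGrid, CopyNumberProfile

MIN_PURITY = {"region": 0.5, "bulk": 0.2}

__all__ = [
    "Log2Profile",
    "PloidyFit",
    "logr_to_cn",
    "cn_to_logr",
    "fit_sample",
    "rank_ploidies",
    "integer_profiles",
    "estimate_logr_noise",
    "default_ploidy_grid",
    "default_purity_grid",
]


@dataclass(frozen=True)
class Log2Profile:
    """Per-bin log2 ratio for one sample (median-centered)."""

    grid: BinGrid
    logr: np.ndarray
    sample_id: str = "sample"
    sample_class: str = "region"  # "region" (microdissected) or "bulk"

    def __post_init__(self):
        lr = np.asarray(self.logr, dtype=float)
        object.__setattr__(self, "logr", lr)
        if len(lr) != self.grid.n_bins:
            raise ValueError("logr length does not match grid")
        if not np.all(np.isfinite(lr)):
            raise ValueError("log2 ratios must be finite")
        if self.sample_class not in MIN_PURITY:
            raise ValueError("sample_class must be 'region' or 'bulk'")


@dataclass(frozen=True)
class PloidyFit:
    psi: float
    purities: dict  # sample_id -> best purity
    fit_errors: dict  # sample_id -> per-sample fit error
    mean_fit_error: float
    cross_distance: float
    scaled_fit: float
    scaled_cross: float
    score: float
    rank: int


def logr_to_cn(logr, rho: float, psi: float):
    """ASCAT-style log2-ratio -> real-valued copy number (may be negative
    for noisy bins; clip at 0 when rounding to integers)."""
    if not 0.0 < rho <= 1.0:
        raise ValueError("purity must be in (0, 1]")
    if psi <= 0:
        raise ValueError("ploidy must be positive")
    logr = np.asarray(logr, dtype=float)
    tot = 2.0 * (1.0 - rho) + rho * psi
    return (np.exp2(logr) * tot - 2.0 * (1.0 - rho)) / rho


def cn_to_logr(cn, rho: float, psi: float, min_ratio: float = 2.0**-8):
    """Inverse of :func:`logr_to_cn` (noise-free expectation).

    The ratio is floored at ``min_ratio`` so homozygous deletions at purity
    1 give a large negative log ratio instead of -inf, mirroring the read-
    count floor of real binning pipelines.
    """
    if not 0.0 < rho <= 1.0:
        raise ValueError("purity must be in (0, 1]")
    cn = np.asarray(cn, dtype=float)
    tot = 2.0 * (1.0 - rho) + rho * psi
    ratio = np.maximum((rho * cn + 2.0 * (1.0 - rho)) / tot, min_ratio)
    return np.log2(ratio)


def estimate_logr_noise(profile: Log2Profile) -> float:
    """Robust per-bin noise estimate: MAD of adjacent-bin log2-ratio
    differences within chromosomes, scaled to a Gaussian sd."""
    d = np.diff(profile.logr)
    bounds = profile.grid.chrom_boundaries()
    if len(bounds):
        d = np.delete(d, bounds - 1)
    mad = np.median(np.abs(d - np.median(d)))
    return float(1.4826 * mad / np.sqrt(2.0))


def default_ploidy_grid(step: float = 0.05) -> np.ndarray:
    return np.round(np.arange(1.5, 4.0 + step / 2, step), 10)


def default_purity_grid(sample_class: str, step: float = 0.01) -> np.ndarray:
    lo = MIN_PURITY[sample_class]
    return np.round(np.arange(lo, 1.0 + step / 2, step), 10)


def fit_sample(
    profile: Log2Profile,
    psi: float,
    purity_grid: np.ndarray | None = None,
) -> tuple[float, float]:
    """Best purity for a sample at a fixed ploidy.

    Returns ``(rho, error)`` where the error is the mean squared deviation
    of the implied copy numbers from their nearest integer (>= 0).
    """
    if purity_grid is None:
        purity_grid = default_purity_grid(profile.sample_class)
    purity_grid = np.asarray(purity_grid, dtype=float)
    if len(purity_grid) == 0:
        raise ValueError("empty purity grid")
    best_rho, best_err = None, np.inf
    for rho in purity_grid:
        cn = logr_to_cn(profile.logr, float(rho), psi)
        err = float(np.mean((cn - np.maximum(np.round(cn), 0.0)) ** 2))
        if err < best_err:
            best_rho, best_err = float(rho), err
    return best_rho, best_err


def integer_profiles(
    profiles: Sequence[Log2Profile], fit: PloidyFit, psi_offsets: dict | None = None
) -> list:
    """Integer copy-number profiles at a chosen solution.

    ``psi_offsets`` maps sample_id -> ploidy adjustment (e.g. +-0.4) for
    manually curated outlier samples; offsets are never applied
    automatically.
    """
    psi_offsets = psi_offsets or {}
    out = []
    for p in profiles:
        psi = fit.psi + psi_offsets.get(p.sample_id, 0.0)
        rho, _ = fit_sample(p, psi)
        cn = np.maximum(np.round(logr_to_cn(p.logr, rho, psi)), 0).astype(np.int64)
        out.append(CopyNumberProfile(p.grid, cn, p.sample_id))
    return out


def rank_ploidies(
    profiles: Sequence[Log2Profile],
    ploidy_grid: np.ndarray | None = None,
    purity_grids: dict | None = None,
    logr_cutoff: float = 1.0,
    parsimony_margin: float | str = "auto",
) -> list:
    """Score and rank candidate ploidies for a multi-sample patient.

    Returns PloidyFit objects sorted by rank (rank 1 = chosen solution).

    Ploidy solutions related by a one-copy genome-wide shift (with purities
    rescaled as rho' = 2 rho / (2 - rho)) fit integer profiles exactly as
    well as the truth, so the score curve can have near-degenerate local
    minima at higher ploidy, and measurement noise blurs the score by an
    amount that grows with the per-bin noise.  Among local minima of the
    score curve within ``parsimony_margin`` of the best, the lowest ploidy
    is therefore preferred.  ``"auto"`` sets the margin to twice the mean
    estimated log-ratio noise sd (so on noiseless data the valley choice
    follows the score alone); a numeric value fixes it.  Within the chosen
    valley (2 grid steps either side), the ploidy minimizing the per-sample
    fit error is selected, since the cross term shrinks slightly with
    ploidy even inside a valley.  Manual curation
    (taking the second-best solution, per-sample ploidy offsets) is applied
    downstream via :func:`integer_profiles`.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("need at least one sample")
    if ploidy_grid is None:
        ploidy_grid = default_ploidy_grid()
    purity_grids = purity_grids or {}

    # bins kept in the cross-sample distance: logr <= cutoff in the pair
    masks = {p.sample_id: p.logr <= logr_cutoff for p in profiles}

    rows = []
    for psi in ploidy_grid:
        purities, errors, rounded = {}, {}, {}
        for p in profiles:
            grid_rho = purity_grids.get(p.sample_id)
            rho, err = fit_sample(p, float(psi), grid_rho)
            purities[p.sample_id] = rho
            errors[p.sample_id] = err
            cn = logr_to_cn(p.logr, rho, float(psi))
            rounded[p.sample_id] = np.maximum(np.round(cn), 0.0)
        if len(profiles) >= 2:
            dists = []
            for a, b in combinations(profiles, 2):
                keep = masks[a.sample_id] & masks[b.sample_id]
                if not keep.any():
                    continue
                diff = (rounded[a.sample_id][keep] - rounded[b.sample_id][keep]) / psi
                dists.append(float(np.sqrt(np.mean(diff**2))))
            cross = float(np.mean(dists)) if dists else 0.0
        else:
            cross = 0.0  # single sample: no cross-sample constraint
        rows.append((float(psi), purities, errors, float(np.mean(list(errors.values()))), cross))

    fit_vals = np.array([r[3] for r in rows])
    cross_vals = np.array([r[4] for r in rows])

    def minmax(v):
        span = v.max() - v.min()
        return (v - v.min()) / span if span > 0 else np.zeros_like(v)

    a = minmax(fit_vals)
    b = minmax(cross_vals)
    scores = np.hypot(a, b)
    order = list(np.argsort(scores, kind="stable"))
    if parsimony_margin == "auto":
        parsimony_margin = 2.0 * float(
            np.mean([estimate_logr_noise(p) for p in profiles])
        )
    if len(scores) > 1:
        ext = np.r_[np.inf, scores, np.inf]
        minima = [
            i
            for i in range(len(scores))
            if scores[i] <= ext[i] and scores[i] <= ext[i + 2]
        ]
        near = [i for i in minima if scores[i] <= scores.min() + parsimony_margin]
        chosen = min(near, key=lambda i: rows[i][0])
        # within the chosen valley the cross term still shrinks slightly
        # with ploidy; the per-sample fit error is the sharper local signal
        lo, hi = max(0, chosen - 2), min(len(scores), chosen + 3)
        chosen = lo + int(np.argmin(fit_vals[lo:hi]))
        order.remove(chosen)
        order.insert(0, chosen)
    fits = []
    for rank, i in enumerate(order, start=1):
        psi, purities, errors, mean_err, cross = rows[i]
        fits.append(
            PloidyFit(
                psi=psi,
                purities=purities,
                fit_errors=errors,
                mean_fit_error=mean_err,
                cross_distance=cross,
                scaled_fit=float(a[i]),
                scaled_cross=float(b[i]),
                score=float(scores[i]),
                rank=rank,
            )
        )
    return fits
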