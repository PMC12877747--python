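"""Stochastic birth-death simulation of gland karyotype evolution.

The individual of the model is a tumor gland carrying a karyotype: a
vector of integer copy numbers over C genomic bins.  Fitness is shaped by
a single-peak landscape around an optimal karyotype G_o: the net growth
rate of a gland with karyotype G_i is

    b_i - d_i = (b0 - d0) / (1 + alpha * d(G_i, G_o))

where d(.,.) is the L1 distance over bins and alpha >= 0 scales the
strength of negative selection (alpha = 0 is a flat, neutral landscape).
The fitness change is absorbed either by the birth rate (death rate fixed
at d0) or by the death rate (birth fixed at b0).

Each division, both daughters independently acquire k ~ Poisson(mu) copy
number alterations; each alteration is a contiguous, chromosome-bounded
run of bins changed by +-1 copy (clipped to [0, max_cn]), with its length
drawn from a configurable size distribution.

The simulation is an exact Gillespie process run over *clones* -- groups
of glands sharing a karyotype and hence birth/death rates -- which is an
exact sampler of the individual-level process.  It starts from a single
founder gland and stops at a target population size or extinction.  The
clone ancestry (which clone mutated from which, with which events, when)
is logged, so every karyotype can be reconstructed by replaying the event
log from the founder.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .grid import BinGrid, CopyNumberProfile

__all__ = [
    "FitnessLandscape",
    "SimConfig",
    "SimResult",
    "CNAEvent",
    "CNASizeSampler",
    "net_growth",
    "draw_cnas",
    "apply_events",
    "simulate",
    "bottleneck",
    "sample_glands",
]


@dataclass(frozen=True)
class CNAEvent:
    """One copy-number alteration: bins [start, end) change by delta."""

    start: int
    end: int
    delta: int  # +1 gain, -1 loss


@dataclass(frozen=True)
class CNASizeSampler:
    """CNA length distribution (in bins).

    Default: whole-chromosome alteration with probability ``p_whole``,
    otherwise a geometric length with the given mean.  ``from_empirical``
    resamples from observed event lengths instead.
    """

    p_whole: float = 0.3
    geometric_mean: float = 20.0
    empirical: np.ndarray | None = None

    def draw(self, rng: np.random.Generator, chrom_len: int) -> int:
        """Length in bins, truncated at the chromosome length."""
        if self.empirical is not None:
            length = int(rng.choice(self.empirical))
        elif rng.random() < self.p_whole:
            length = chrom_len
        else:
            length = int(rng.geometric(1.0 / self.geometric_mean))
        return min(max(length, 1), chrom_len)

    @classmethod
    def from_empirical(cls, lengths: Sequence[int]) -> "CNASizeSampler":
        arr = np.asarray(lengths, dtype=np.int64)
        if len(arr) == 0 or np.any(arr < 1):
            raise ValueError("empirical lengths must be positive")
        return cls(empirical=arr)


@dataclass(frozen=True)
class FitnessLandscape:
    """Single-peak karyotype fitness landscape."""

    go: CopyNumberProfile  # optimal karyotype
    alpha: float = 0.0  # selection strength (0 = flat / neutral)
    b0: float = 1.0  # birth rate at the optimum, per unit time
    d0: float = 0.2  # death rate at the optimum, per unit time
    mode: str = "birth"  # which rate absorbs the fitness change

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if not self.b0 > self.d0 >= 0:
            raise ValueError("require b0 > d0 >= 0")
        if self.mode not in ("birth", "death"):
            raise ValueError("mode must be 'birth' or 'death'")


def net_growth(
    karyotype: CopyNumberProfile | np.ndarray, landscape: FitnessLandscape
) -> tuple[float, float]:
    """(birth, death) rates of a karyotype under the landscape."""
    cn = karyotype.cn if isinstance(karyotype, CopyNumberProfile) else np.asarray(karyotype)
    go = landscape.go.cn
    if cn.shape != go.shape:
        raise ValueError("karyotype and optimum are on different grids")
    dist = float(np.abs(cn - go).sum())
    net = (landscape.b0 - landscape.d0) / (1.0 + landscape.alpha * dist)
    if landscape.mode == "birth":
        return landscape.d0 + net, landscape.d0
    return landscape.b0, max(landscape.b0 - net, 0.0)


@dataclass(frozen=True)
class SimConfig:
    landscape: FitnessLandscape
    mu: float = 0.2  # CNA rate per gland division (Poisson mean)
    size_sampler: CNASizeSampler = field(default_factory=CNASizeSampler)
    founder: CopyNumberProfile | None = None  # defaults to the optimum G_o
    n_target: int = 5000
    max_cn: int = 8
    #: draw CNAs for both daughters at division, or only one
    daughters: str = "both"
    #: Gillespie step budget; None -> 150 * n_target.  A population that
    #: exhausts it (near-critical mutational meltdown under strong
    #: selection) is reported with outcome "stalled".
    max_steps: int | None = None

    def __post_init__(self):
        if self.mu < 0 or self.n_target < 1 or self.max_cn < 1:
            raise ValueError("invalid simulation config")
        if self.daughters not in ("both", "one"):
            raise ValueError("daughters must be 'both' or 'one'")

    @property
    def founder_profile(self) -> CopyNumberProfile:
        return self.founder if self.founder is not None else self.landscape.go


_CHROM_INDEX_CACHE: dict = {}


def _chrom_index(grid: BinGrid):
    """Cached (chromosome slices, per-bin chromosome index) for a grid."""
    key = grid.chroms
    hit = _CHROM_INDEX_CACHE.get(key)
    if hit is None:
        slices = list(grid.chrom_slices().values())
        chrom_of = np.empty(grid.n_bins, dtype=np.int64)
        for i, sl in enumerate(slices):
            chrom_of[sl] = i
        hit = (slices, chrom_of)
        _CHROM_INDEX_CACHE[key] = hit
    return hit


def draw_cnas(
    mu: float,
    size_sampler: CNASizeSampler,
    grid: BinGrid,
    rng: np.random.Generator,
) -> list:
    """k ~ Poisson(mu) alterations; each starts at a uniform bin, extends by
    a sampled length truncated at its chromosome end, and is a +-1 change
    with equal probability.  Never spans two chromosomes."""
    k = rng.poisson(mu)
    if k == 0:
        return []
    slices, chrom_of = _chrom_index(grid)
    events = []
    for _ in range(k):
        start = int(rng.integers(grid.n_bins))
        sl = slices[chrom_of[start]]
        length = size_sampler.draw(rng, sl.stop - sl.start)
        if length >= sl.stop - sl.start:
            start, end = sl.start, sl.stop  # whole chromosome
        else:
            end = min(start + length, sl.stop)
        delta = 1 if rng.random() < 0.5 else -1
        events.append(CNAEvent(start, end, delta))
    return events


def apply_events(cn: np.ndarray, events: Sequence[CNAEvent], max_cn: int) -> np.ndarray:
    out = cn.copy()
    for ev in events:
        seg = out[ev.start : ev.end]
        if ev.delta > 0:
            # a bin lost to 0 copies cannot be regained
            np.minimum(np.where(seg > 0, seg + 1, 0), max_cn, out=seg)
        else:
            np.maximum(seg - 1, 0, out=seg)
    return out


@dataclass
class SimResult:
    """Outcome of one simulation run, stored clone-wise.

    ``clone_cn[i]`` is the karyotype of clone i, ``counts[i]`` how many
    glands carry it at the stopping time, ``parents[i]`` the clone it
    mutated from (-1 for the founder), ``clone_events[i]`` the CNAs that
    created it, and ``times[i]`` when.  ``outcome`` is "reached_target" or
    "extinct".
    """

    grid: BinGrid
    clone_cn: list
    counts: np.ndarray
    parents: np.ndarray
    clone_events: list
    times: np.ndarray
    outcome: str
    t_end: float
    config: SimConfig

    @property
    def population_size(self) -> int:
        return int(self.counts.sum())

    def alive_clones(self) -> np.ndarray:
        return np.flatnonzero(self.counts > 0)

    def population(self, max_glands: int | None = None) -> list:
        """Expand clones to per-gland CopyNumberProfile objects."""
        profiles = []
        i = 0
        for c in self.alive_clones():
            for _ in range(int(self.counts[c])):
                profiles.append(
                    CopyNumberProfile(self.grid, self.clone_cn[c], f"gland{i:05d}")
                )
                i += 1
                if max_glands is not None and i >= max_glands:
                    return profiles
        return profiles

    def replay_clone(self, clone: int) -> np.ndarray:
        """Reconstruct a clone's karyotype by replaying the event log from
        the founder (used to verify internal consistency)."""
        path = []
        c = clone
        while c != -1:
            path.append(c)
            c = int(self.parents[c])
        cn = self.config.founder_profile.cn
        for c in reversed(path):
            cn = apply_events(cn, self.clone_events[c], self.config.max_cn)
        return cn

    def event_log(self):
        """Rows (time, clone, parent, start, end, delta), one per CNA."""
        rows = []
        for c in range(len(self.clone_cn)):
            for ev in self.clone_events[c]:
                rows.append(
                    (float(self.times[c]), c, int(self.parents[c]), ev.start, ev.end, ev.delta)
                )
        return rows


def simulate(
    config: SimConfig,
    rng: np.random.Generator | int | None = None,
    initial: list | None = None,
) -> SimResult:
    """Exact Gillespie birth-death simulation from one founder gland.

    ``initial`` optionally seeds the population with (karyotype, count)
    pairs instead of the single founder (used for bottleneck regrowth).
    Deterministic given the random generator state.
    """
    rng = np.random.default_rng(rng)
    land = config.landscape
    grid = config.founder_profile.grid

    # append-only clone registry (full genealogy, kept for the result)
    clone_cn: list = []
    clone_events: list = []
    parents: list = []
    times: list = []

    def register(cn, parent, events, t):
        clone_cn.append(cn)
        parents.append(parent)
        clone_events.append(list(events))
        times.append(t)
        return len(clone_cn) - 1, net_growth(cn, land)

    # live slots: parallel arrays over clones with count > 0; dead slots are
    # compacted away periodically so the per-step cost tracks the live
    # population, not the total number of clones ever created
    cap = 256
    slot_id = np.full(cap, -1, dtype=np.int64)
    counts_arr = np.zeros(cap, dtype=np.int64)
    b_arr = np.zeros(cap)
    d_arr = np.zeros(cap)
    n_slots = 0

    def add_slot(cid, cnt, b, d):
        nonlocal n_slots, cap, slot_id, counts_arr, b_arr, d_arr
        if n_slots == cap:
            cap *= 2
            slot_id = np.resize(slot_id, cap)
            counts_arr = np.resize(counts_arr, cap)
            b_arr = np.resize(b_arr, cap)
            d_arr = np.resize(d_arr, cap)
        slot_id[n_slots] = cid
        counts_arr[n_slots] = cnt
        b_arr[n_slots] = b
        d_arr[n_slots] = d
        n_slots += 1

    def compact():
        nonlocal n_slots, slot_id, counts_arr, b_arr, d_arr
        keep = np.flatnonzero(counts_arr[:n_slots] > 0)
        n_keep = len(keep)
        slot_id[:n_keep] = slot_id[keep]
        counts_arr[:n_keep] = counts_arr[keep]
        b_arr[:n_keep] = b_arr[keep]
        d_arr[:n_keep] = d_arr[keep]
        n_slots = n_keep

    if initial is None:
        cid, (b, d) = register(config.founder_profile.cn.copy(), -1, [], 0.0)
        add_slot(cid, 1, b, d)
    else:
        for cn, cnt in initial:
            cid, (b, d) = register(np.asarray(cn, dtype=np.int64).copy(), -1, [], 0.0)
            add_slot(cid, int(cnt), b, d)

    final_counts = np.zeros(0, dtype=np.int64)  # filled at the end
    N = int(counts_arr[:n_slots].sum())
    t = 0.0
    steps = 0
    max_steps = (
        config.max_steps if config.max_steps is not None else 150 * config.n_target
    )
    stalled = False
    n_mutating = 2 if config.daughters == "both" else 1
    while 0 < N < config.n_target:
        steps += 1
        if steps > max_steps or (steps > 25 * config.n_target and 4 * N < config.n_target):
            # no meaningful progress: near-critical meltdown, give up early
            stalled = True
            break
        if n_slots > max(256, 2 * N):
            compact()
        cb = counts_arr[:n_slots] * b_arr[:n_slots]
        cd = counts_arr[:n_slots] * d_arr[:n_slots]
        B = cb.sum()
        D = cd.sum()
        tot = B + D
        t += rng.exponential(1.0 / tot)
        if rng.random() * tot < B:
            # birth: pick dividing clone proportional to count * birth rate
            idx = int(np.searchsorted(np.cumsum(cb), rng.random() * B, side="right"))
            counts_arr[idx] -= 1
            for k in range(2):
                events = (
                    draw_cnas(config.mu, config.size_sampler, grid, rng)
                    if k < n_mutating
                    else []
                )
                if not events:
                    counts_arr[idx] += 1
                    continue
                parent_cid = int(slot_id[idx])
                cn = apply_events(clone_cn[parent_cid], events, config.max_cn)
                if np.array_equal(cn, clone_cn[parent_cid]):
                    counts_arr[idx] += 1  # events cancelled / clipped away
                    continue
                cid, (b, d) = register(cn, parent_cid, events, t)
                add_slot(cid, 1, b, d)
            N += 1
        else:
            idx = int(np.searchsorted(np.cumsum(cd), rng.random() * D, side="right"))
            counts_arr[idx] -= 1
            N -= 1

    final_counts = np.zeros(len(clone_cn), dtype=np.int64)
    np.add.at(final_counts, slot_id[:n_slots], counts_arr[:n_slots])
    return SimResult(
        grid=grid,
        clone_cn=clone_cn,
        counts=final_counts,
        parents=np.array(parents, dtype=np.int64),
        clone_events=clone_events,
        times=np.array(times),
        outcome="stalled" if stalled else ("reached_target" if N > 0 else "extinct"),
        t_end=t,
        config=config,
    )


def sample_glands(
    result: SimResult, n: int, rng: np.random.Generator | int | None = None
) -> list:
    """Uniform sample of n glands (without replacement) from the final
    population, returned as CopyNumberProfile objects."""
    rng = np.random.default_rng(rng)
    N = result.population_size
    if n > N:
        raise ValueError(f"cannot sample {n} glands from population of {N}")
    alive = result.alive_clones()
    cum = np.cumsum(result.counts[alive])
    positions = rng.choice(N, size=n, replace=False)
    clones = alive[np.searchsorted(cum, positions, side="right")]
    return [
        CopyNumberProfile(result.grid, result.clone_cn[c], f"gland{i:05d}")
        for i, c in enumerate(clones)
    ]


def sampled_clone_ids(
    result: SimResult, n: int, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Clone indices of a uniform gland sample (with clone multiplicity)."""
    rng = np.random.default_rng(rng)
    N = result.population_size
    if n > N:
        raise ValueError("sample larger than population")
    alive = result.alive_clones()
    cum = np.cumsum(result.counts[alive])
    positions = rng.choice(N, size=n, replace=False)
    return alive[np.searchsorted(cum, positions, side="right")]


def bottleneck(
    result: SimResult, k: int, rng: np.random.Generator | int | None = None
) -> list:
    """Uniform k-gland bottleneck: returns (karyotype, count) pairs suitable
    as ``initial`` for a regrowth call to :func:`simulate`."""
    rng = np.random.default_rng(rng)
    if k < 1:
        raise ValueError("k must be >= 1")
    clones = sampled_clone_ids(result, k, rng)
    uniq, cnt = np.unique(clones, return_counts=True)
    return [(result.clone_cn[c], int(n)) for c, n in zip(uniq, cnt)]
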