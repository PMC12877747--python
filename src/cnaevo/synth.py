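"""Synthetic multi-region CNA cohorts with full ground truth.

Generates every input the analysis modules consume: per-patient
multi-region integer copy-number profiles with a controlled clonal /
subclonal structure, matching noisy log2-ratio profiles at known purity
and ploidy, per-bin gene-weight tracks, and BAF tables for phasing tests.

The stage presets parameterize the observed progression regimes of
colorectal neoplasia: adenomas carry few alterations but a large
subclonal share (mean PGA ~8.5%, genome doubling essentially absent),
early cancers are intermediate (PGA ~25%, GD in about a third), and
established carcinomas combine a high alteration burden with mostly
clonal CNAs (PGA ~27%, GD in ~20%).  Every random choice flows from one
seed, so regenerating a cohort with the same seed is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .grid import BinGrid, CopyNumberProfile, baseline_ploidy
from .divergence import proportion_subclonal
from .ploidy import Log2Profile, cn_to_logr
from .phasing import expected_baf
from .simulate import CNAEvent, CNASizeSampler, apply_events

__all__ = [
    "AUTOSOME_SIZES",
    "default_grid",
    "CohortSpec",
    "STAGE_PRESETS",
    "TruthBundle",
    "gen_patient",
    "gen_cohort",
    "gen_logr",
    "gen_gene_weights",
    "gen_baf_fixture",
]

#: approximate GRCh38 autosome lengths (bp)
AUTOSOME_SIZES = {
    "chr1": 248_000_000, "chr2": 242_000_000, "chr3": 198_000_000,
    "chr4": 190_000_000, "chr5": 181_000_000, "chr6": 170_000_000,
    "chr7": 159_000_000, "chr8": 145_000_000, "chr9": 138_000_000,
    "chr10": 133_000_000, "chr11": 135_000_000, "chr12": 133_000_000,
    "chr13": 114_000_000, "chr14": 107_000_000, "chr15": 101_000_000,
    "chr16": 90_000_000, "chr17": 83_000_000, "chr18": 80_000_000,
    "chr19": 58_000_000, "chr20": 64_000_000, "chr21": 46_000_000,
    "chr22": 50_000_000,
}


def default_grid(bin_width: int = 10_000_000) -> BinGrid:
    """22 autosomes tiled at 10 Mb (~290 bins): a coarse grid that keeps
    simulations fast; pass 500_000 for a full-resolution 500 kb grid."""
    return BinGrid.uniform(AUTOSOME_SIZES, bin_width)


@dataclass(frozen=True)
class CohortSpec:
    n_patients: int = 10
    n_regions: int = 4
    stage: str = "carcinoma"  # adenoma | early | carcinoma
    target_pga: float = 0.272
    target_subclonal: float = 0.2
    gd_prob: float = 0.2
    #: fraction of trunk events occurring before a genome doubling
    gd_after_fraction: float = 0.5
    #: genome-doubled patients carry proportionally more alterations, as
    #: observed in doubled tumors; their PGA target is scaled by this factor
    gd_pga_boost: float = 2.0
    purity_range: tuple = (0.5, 1.0)
    logr_noise_sd: float = 0.05
    bin_width: int = 10_000_000
    size_sampler: CNASizeSampler = field(default_factory=CNASizeSampler)
    max_cn: int = 8

    def __post_init__(self):
        if not (0.0 <= self.target_pga <= 1.0 and 0.0 <= self.target_subclonal <= 1.0):
            raise ValueError("targets must be fractions")
        if self.target_subclonal > 0 and self.n_regions < 2:
            raise ValueError("subclonal alterations require >= 2 regions")


#: regime presets echoing the progression phase space (low PGA / high
#: subclonality in adenomas, the reverse in carcinomas)
STAGE_PRESETS = {
    "adenoma": dict(target_pga=0.085, target_subclonal=0.5, gd_prob=0.02),
    "early": dict(target_pga=0.253, target_subclonal=0.3, gd_prob=13 / 39),
    "carcinoma": dict(target_pga=0.272, target_subclonal=0.2, gd_prob=16 / 81),
}


def spec_for_stage(stage: str, **overrides) -> CohortSpec:
    if stage not in STAGE_PRESETS:
        raise ValueError(f"unknown stage {stage!r}")
    kw = dict(STAGE_PRESETS[stage])
    kw.update(overrides)
    return CohortSpec(stage=stage, **kw)


@dataclass
class TruthBundle:
    patient_id: str
    clonal_events: list
    private_events: dict  # region sample_id -> list of CNAEvent
    gd: bool
    ploidy: int
    purities: dict  # sample_id -> purity
    clonal_pga: float
    realized_subclonal: float


def _draw_event(grid: BinGrid, sampler: CNASizeSampler, rng) -> CNAEvent:
    slices = list(grid.chrom_slices().values())
    start = int(rng.integers(grid.n_bins))
    for sl in slices:
        if sl.start <= start < sl.stop:
            break
    length = sampler.draw(rng, sl.stop - sl.start)
    if length >= sl.stop - sl.start:
        start, end = sl.start, sl.stop
    else:
        end = min(start + length, sl.stop)
    delta = 1 if rng.random() < 0.5 else -1
    return CNAEvent(start, end, delta)


def gen_patient(
    spec: CohortSpec, rng: np.random.Generator, patient_id: str = "P0"
) -> tuple[list, TruthBundle]:
    """One multi-region patient: trunk events shared by all regions (to the
    target PGA), then private per-region events (to the target subclonal
    fraction), with an optional genome doubling inside the trunk."""
    grid = default_grid(spec.bin_width)
    gd = bool(rng.random() < spec.gd_prob)
    # the target is the clonal (trunk) PGA; private subclonal events add on
    # top of it, so realized per-sample PGA sits somewhat above the target
    target_pga = min(spec.target_pga * (spec.gd_pga_boost if gd else 1.0), 0.95)

    trunk: list = []
    cn = np.full(grid.n_bins, 2, dtype=np.int64)
    gd_applied = False
    # place the GD part-way through the trunk so pre-GD losses get doubled
    for _ in range(10_000):
        base = baseline_ploidy(CopyNumberProfile(grid, cn, "tmp"))
        if np.mean(cn != base) >= target_pga:
            break
        if gd and not gd_applied:
            if np.mean(cn != 2) >= target_pga * spec.gd_after_fraction:
                cn = np.minimum(cn * 2, spec.max_cn)
                gd_applied = True
                continue
        ev = _draw_event(grid, spec.size_sampler, rng)
        cn = apply_events(cn, [ev], spec.max_cn)
        trunk.append(ev)
    if gd and not gd_applied:
        cn = np.minimum(cn * 2, spec.max_cn)

    clonal = cn
    ploidy = baseline_ploidy(CopyNumberProfile(grid, clonal, "clonal"))
    clonal_pga = float(np.mean(clonal != ploidy))

    region_cn = [clonal.copy() for _ in range(spec.n_regions)]
    private: dict = {f"{patient_id}_R{i+1}": [] for i in range(spec.n_regions)}
    ids = list(private)
    profiles = [
        CopyNumberProfile(grid, region_cn[i], ids[i]) for i in range(spec.n_regions)
    ]
    realized = proportion_subclonal(profiles) if spec.n_regions >= 2 else 0.0
    for _ in range(10_000):
        if spec.n_regions < 2 or realized >= spec.target_subclonal:
            break
        i = int(rng.integers(spec.n_regions))
        ev = _draw_event(grid, spec.size_sampler, rng)
        region_cn[i] = apply_events(region_cn[i], [ev], spec.max_cn)
        private[ids[i]].append(ev)
        profiles = [
            CopyNumberProfile(grid, region_cn[j], ids[j]) for j in range(spec.n_regions)
        ]
        realized = proportion_subclonal(profiles)

    purities = {
        s: float(rng.uniform(*spec.purity_range)) for s in ids
    }
    truth = TruthBundle(
        patient_id=patient_id,
        clonal_events=trunk,
        private_events=private,
        gd=gd,
        ploidy=int(ploidy),
        purities=purities,
        clonal_pga=clonal_pga,
        realized_subclonal=float(realized),
    )
    return profiles, truth


def gen_cohort(spec: CohortSpec, seed: int) -> tuple[dict, list]:
    """n_patients patients from one seed: returns ({patient_id: [profiles]},
    [TruthBundle])."""
    rng = np.random.default_rng(seed)
    cohort, truths = {}, []
    for k in range(spec.n_patients):
        pid = f"{spec.stage[:2].upper()}{k:03d}"
        profiles, truth = gen_patient(spec, rng, pid)
        cohort[pid] = profiles
        truths.append(truth)
    return cohort, truths


def gen_logr(
    profile: CopyNumberProfile,
    rho: float,
    psi: float,
    noise_sd: float,
    rng: np.random.Generator,
    sample_class: str = "region",
    median_center: bool = False,
) -> Log2Profile:
    """Noisy log2-ratio profile at known purity/ploidy (inverse of the
    ASCAT transformation plus Gaussian noise).

    By default the ratios are centered on the supplied ploidy
    normalization, so a fitted ploidy is directly comparable with ``psi``.
    ``median_center`` instead mimics pipelines that center on the empirical
    median bin, which shifts the recoverable ploidy to the profile's
    median copy number.
    """
    logr = cn_to_logr(profile.cn, rho, psi)
    if noise_sd > 0:
        logr = logr + rng.normal(0.0, noise_sd, size=len(logr))
    if median_center:
        logr = logr - np.median(logr)
    return Log2Profile(profile.grid, logr, profile.sample_id, sample_class)


def gen_gene_weights(
    grid: BinGrid, rng: np.random.Generator, mean_genes: float = 20.0,
    dispersed: bool = True,
) -> np.ndarray:
    """Per-bin gene counts; exponential dispersion by default so that the
    gene-dose metrics differ from their unweighted counterparts."""
    if dispersed:
        w = rng.exponential(mean_genes, size=grid.n_bins)
    else:
        w = np.full(grid.n_bins, mean_genes)
    return np.maximum(np.round(w), 1.0)


def gen_baf_fixture(
    segments: pd.DataFrame,
    n_snps: int,
    depth: int,
    rho: float,
    rng: np.random.Generator,
    n_glands: int = 3,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-SNP, per-gland BAFs from binomial sampling at copy-number-implied
    means.

    ``segments`` needs columns ``segment``, ``n_maj``, ``n_min``.  Returns
    (baf_table, truth) where truth holds each SNP's haplotype.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rows, truth = [], []
    pos = 0
    for _, seg in segments.iterrows():
        p_major = expected_baf(int(seg["n_maj"]), int(seg["n_min"]), rho)
        for _ in range(n_snps):
            hap = "major" if rng.random() < 0.5 else "minor"
            p = p_major if hap == "major" else 1.0 - p_major
            bafs = rng.binomial(depth, p, size=n_glands) / depth
            rows.append([pos, seg["segment"], *bafs])
            truth.append(hap)
            pos += 1000
    cols = ["pos", "segment"] + [f"gland{i}" for i in range(n_glands)]
    table = pd.DataFrame(rows, columns=cols)
    return table, pd.Series(truth, name="haplotype")
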