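"""SNP phasing from B-allele frequencies and allelic-imbalance tests.

In a segment with allele-specific copy number (nMaj, nMin), nMaj != nMin,
heterozygous germline SNPs separate by haplotype: at purity rho the
expected B-allele frequency (BAF) of a SNP on the major haplotype is

    BAF_major = (rho * nMaj + (1 - rho)) / (rho * (nMaj + nMin) + 2 (1 - rho))

(e.g. 0.67 in a pure trisomy, with minor-haplotype SNPs at 0.33).  Deeply
sequenced glands therefore phase SNPs: mean BAF across glands above 0.5
-> major haplotype, below -> minor, with a dead zone around 0.5 left
unphased.  In shallow samples, pooled read counts over the phased SNPs of
a segment test for allelic imbalance: an exact binomial test against 0.5,
and a Fisher exact test against the imbalance expected from the inferred
(nMaj, nMin).
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy.stats import binomtest, fisher_exact

__all__ = [
    "PhasedSNP",
    "SegmentAlleleCounts",
    "expected_baf",
    "phase_snps",
    "binomial_imbalance_test",
    "segment_phase_test",
]


@dataclass(frozen=True)
class PhasedSNP:
    position: int
    segment: str
    haplotype: str  # "major" | "minor"
    mean_baf: float


@dataclass(frozen=True)
class SegmentAlleleCounts:
    segment: str
    major_reads: int
    minor_reads: int
    n_maj: int
    n_min: int

    def __post_init__(self):
        if self.major_reads < 0 or self.minor_reads < 0:
            raise ValueError("read counts must be >= 0")
        if not self.n_maj >= self.n_min >= 0:
            raise ValueError("require nMaj >= nMin >= 0")


def expected_baf(n_maj: int, n_min: int, rho: float = 1.0) -> float:
    """Expected BAF of a major-haplotype SNP at given purity (the normal
    contamination contributes one copy of each allele)."""
    if not 0.0 < rho <= 1.0:
        raise ValueError("purity must be in (0, 1]")
    return (rho * n_maj + (1.0 - rho)) / (rho * (n_maj + n_min) + 2.0 * (1.0 - rho))


def phase_snps(
    baf_table: pd.DataFrame,
    segments: pd.DataFrame,
    margin: float = 0.05,
) -> list:
    """Phase SNPs to haplotypes by their mean BAF across deep glands.

    ``baf_table`` needs columns ``pos``, ``segment`` and one BAF column per
    gland (all remaining columns).  ``segments`` needs columns ``segment``,
    ``n_maj``, ``n_min``; SNPs in balanced segments (nMaj == nMin) cannot
    be phased and are skipped with a warning.  SNPs whose mean BAF lies
    within ``margin`` of 0.5 are left unphased.
    """
    seg_info = segments.set_index("segment")
    gland_cols = [c for c in baf_table.columns if c not in ("pos", "segment")]
    if not gland_cols:
        raise ValueError("no per-gland BAF columns")
    out = []
    for _, row in baf_table.iterrows():
        seg = row["segment"]
        if seg not in seg_info.index:
            continue
        n_maj, n_min = int(seg_info.loc[seg, "n_maj"]), int(seg_info.loc[seg, "n_min"])
        if n_maj == n_min:
            warnings.warn(
                f"segment {seg} is allelically balanced; SNPs left unphased",
                stacklevel=2,
            )
            continue
        mean_baf = float(np.nanmean([row[c] for c in gland_cols]))
        if abs(mean_baf - 0.5) <= margin:
            continue
        out.append(
            PhasedSNP(
                position=int(row["pos"]),
                segment=str(seg),
                haplotype="major" if mean_baf > 0.5 else "minor",
                mean_baf=mean_baf,
            )
        )
    return out


def binomial_imbalance_test(a: int, b: int) -> float:
    """Exact two-sided binomial test of a:b read counts against 0.5."""
    if a < 0 or b < 0 or a + b == 0:
        raise ValueError("need nonnegative counts with a + b >= 1")
    return float(binomtest(a, a + b, 0.5, alternative="two-sided").pvalue)


def segment_phase_test(counts: SegmentAlleleCounts) -> float:
    """Fisher exact test of observed major/minor read counts against the
    expectation implied by the segment's allele-specific copy number.

    The expected row is (nMaj, nMin) scaled to the observed read total and
    rounded, so the test asks whether the observed allelic ratio departs
    from the copy-number-implied ratio.
    """
    total = counts.major_reads + counts.minor_reads
    if total == 0 or counts.n_maj + counts.n_min == 0:
        raise ValueError("zero totals")
    frac = counts.n_maj / (counts.n_maj + counts.n_min)
    exp_major = int(round(total * frac))
    exp_minor = total - exp_major
    table = [[counts.major_reads, counts.minor_reads], [exp_major, exp_minor]]
    return float(fisher_exact(table, alternative="two-sided").pvalue)
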