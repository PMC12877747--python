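"""Whole-genome-doubling (GD) classification from shallow-WGS summaries.

A linear rule on the number of copy-number segments (NS) and the percentage
of genome altered (PGA, as a fraction) calls a sample genome-doubled when

    0.000355 * NS + PGA - 0.432 > 0

Scores within an ambiguity margin of the decision boundary (default half
the magnitude of the intercept, 0.216) are called ``ambiguous``.  Patient-
level logic combines the confident per-sample calls into a clonal /
subclonal GD status and corrects the ambiguous samples accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from scipy.stats import fisher_exact

COEF_NS = 0.000355
INTERCEPT = -0.432

__all__ = [
    "GDClassifier",
    "GDCall",
    "gd_score",
    "classify_sample",
    "classify_patient",
    "gd_enrichment_test",
]


@dataclass(frozen=True)
class GDClassifier:
    coef_ns: float = COEF_NS
    intercept: float = INTERCEPT
    #: half-width of the ambiguous zone around score 0, in score units
    ambiguous_margin: float = 0.5 * abs(INTERCEPT)

    def __post_init__(self):
        if self.ambiguous_margin < 0:
            raise ValueError("ambiguous_margin must be >= 0")


@dataclass(frozen=True)
class GDCall:
    sample_id: str
    score: float
    call: str  # "GD" | "nonGD" | "ambiguous"
    confident: bool


def gd_score(ns: int, pga: float, classifier: GDClassifier | None = None) -> float:
    """Signed distance from the GD decision boundary (positive = GD side)."""
    if ns < 0:
        raise ValueError("ns must be >= 0")
    if not 0.0 <= pga <= 1.0:
        raise ValueError("pga must be a fraction in [0, 1]")
    c = classifier or GDClassifier()
    return c.coef_ns * ns + pga + c.intercept


def classify_sample(
    ns: int,
    pga: float,
    classifier: GDClassifier | None = None,
    sample_id: str = "sample",
) -> GDCall:
    c = classifier or GDClassifier()
    score = gd_score(ns, pga, c)
    if score > c.ambiguous_margin:
        call, confident = "GD", True
    elif score < -c.ambiguous_margin:
        call, confident = "nonGD", True
    else:
        call, confident = "ambiguous", False
    return GDCall(sample_id, score, call, confident)


def classify_patient(calls: Sequence[GDCall]) -> tuple[str, list]:
    """Combine per-sample calls into a patient GD status.

    Returns ``(status, corrected_calls)`` where status is one of
    ``clonal_GD``, ``clonal_nonGD``, ``subclonal_GD``, ``unresolved``:

    * clonal non-GD: >=1 confident non-GD and no confident GD (and vice
      versa for clonal GD); ambiguous samples are corrected to the clonal
      call.
    * subclonal GD: both confident GD and confident non-GD present;
      ambiguous samples take the majority confident call, ties -> GD.
    * unresolved: no confident call at all (all samples ambiguous).
    """
    calls = list(calls)
    if not calls:
        raise ValueError("need at least one sample call")
    n_gd = sum(1 for c in calls if c.confident and c.call == "GD")
    n_non = sum(1 for c in calls if c.confident and c.call == "nonGD")
    if n_gd and n_non:
        status = "subclonal_GD"
        fill = "GD" if n_gd >= n_non else "nonGD"
    elif n_gd:
        status, fill = "clonal_GD", "GD"
    elif n_non:
        status, fill = "clonal_nonGD", "nonGD"
    else:
        return "unresolved", calls
    corrected = [
        GDCall(c.sample_id, c.score, fill, c.confident) if not c.confident else c
        for c in calls
    ]
    return status, corrected


def gd_enrichment_test(gd_a: int, n_a: int, gd_b: int, n_b: int) -> float:
    """Two-sided Fisher exact p for a difference in GD frequency between two
    groups (counts of GD samples out of group totals)."""
    for gd, n in ((gd_a, n_a), (gd_b, n_b)):
        if not 0 <= gd <= n:
            raise ValueError("require 0 <= gd <= n")
    table = [[gd_a, n_a - gd_a], [gd_b, n_b - gd_b]]
    return float(fisher_exact(table, alternative="two-sided").pvalue)
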