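"""Reproducible study-condition harnesses.

Each function here runs one of the package's headline computations at a
fixed, documented problem size and returns plain numbers: the simulator's
divergence-versus-selection sweep, ABC model recovery over repeated
synthetic truths, multi-patient ploidy recovery, and genome-doubling
classifier accuracy on generated cohorts.  The acceptance script and the
acceptance tests both drive these, so the numbers they report are always
recomputed from scratch.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import spearmanr

from .abc import ABCConfig, model_select, observed_stats, summarize
from .gd import GDClassifier, classify_sample
from .grid import CopyNumberProfile, baseline_ploidy, count_segments, pga
from .ploidy import rank_ploidies
from .simulate import FitnessLandscape, SimConfig, sample_glands, simulate
from .synth import default_grid, gen_logr, gen_patient, spec_for_stage

__all__ = [
    "diploid_optimum",
    "alpha_divergence_sweep",
    "abc_model_recovery",
    "ploidy_recovery",
    "gd_classifier_accuracy",
]


def diploid_optimum() -> CopyNumberProfile:
    grid = default_grid()
    return CopyNumberProfile(grid, np.full(grid.n_bins, 2), "Go")


def alpha_divergence_sweep(
    seed: int,
    alphas=(0.0, 0.5, 2.0, 10.0),
    mu: float = 0.2,
    n_target: int = 5000,
    n_sampled: int = 77,
    reps: int = 10,
) -> dict:
    """Mean pairwise divergence (PoAGS) and PGA of sampled glands as a
    function of selection strength, founder at the optimum.

    Returns per-alpha means and the one-sided Spearman test of divergence
    decreasing in alpha (pooled over replicates).
    """
    go = diploid_optimum()
    ss = np.random.SeedSequence(seed)
    xs, ys, pgas = [], [], []
    per_alpha = {}
    for a, child in zip(alphas, ss.spawn(len(alphas))):
        rngs = [np.random.default_rng(s) for s in child.spawn(reps)]
        vals, pvals = [], []
        for rng in rngs:
            land = FitnessLandscape(go=go, alpha=float(a))
            cfg = SimConfig(landscape=land, mu=mu, n_target=n_target)
            # condition each replicate on survival (retry extinctions)
            for _ in range(10):
                res = simulate(cfg, rng)
                if res.outcome == "reached_target":
                    break
            else:
                continue
            glands = sample_glands(res, n_sampled, rng)
            s = summarize(glands)
            vals.append(s[0])
            pvals.append(s[2])
            xs.append(a)
            ys.append(s[0])
        per_alpha[float(a)] = {
            "mean_divergence": float(np.mean(vals)),
            "mean_pga": float(np.mean(pvals)),
            "n_reps": len(vals),
        }
        pgas.append(float(np.mean(pvals)))
    rho, p = spearmanr(xs, ys, alternative="less")
    return {
        "per_alpha": per_alpha,
        "spearman_rho": float(rho),
        "spearman_p": float(p),
    }


def abc_model_recovery(
    seed: int,
    truth: str,
    n_seeds: int = 10,
    truth_params: tuple | None = None,
    n_sims: int = 150,
    accept_quantile: float = 0.07,
    cfg: ABCConfig | None = None,
) -> dict:
    """Repeated ABC model selection on synthetic data of known truth.

    ``truth`` is "selection" (default parameters mu=0.2, alpha=5) or
    "neutral" (mu=0.5, alpha=0).  Success means picking negative_selection
    for the selection truth, and neutral-or-indistinguishable for the
    neutral truth.  Accepted (mu, alpha) draws of the selection-model fits
    are pooled for the non-identifiability ridge check.
    """
    if cfg is None:
        cfg = ABCConfig(go=diploid_optimum(), n_target=1000, n_sampled=77)
    if truth_params is None:
        truth_params = (0.2, 5.0) if truth == "selection" else (0.5, 0.0)
    mu, alpha = truth_params
    ss = np.random.SeedSequence(seed)
    obs_seeds, fit_seeds = ss.spawn(2)
    winners, deltas = [], []
    pooled_mu, pooled_alpha = [], []
    for s_obs, s_fit in zip(obs_seeds.spawn(n_seeds), fit_seeds.spawn(n_seeds)):
        obs = observed_stats(mu, alpha, cfg, np.random.default_rng(s_obs))
        sel = model_select(
            obs,
            cfg,
            n_sims=n_sims,
            accept_quantile=accept_quantile,
            seed=int(s_fit.generate_state(1)[0] % (2**31 - 1)),
        )
        winners.append(sel["winner"])
        deltas.append(sel["delta_dic"])
        acc = sel["fits"]["negative_selection"].accepted
        pooled_mu += acc[:, 0].tolist()
        pooled_alpha += acc[:, 1].tolist()
    if truth == "selection":
        n_correct = sum(w == "negative_selection" for w in winners)
    else:
        n_correct = sum(w in ("neutral", "indistinguishable") for w in winners)
    ridge_rho, ridge_p = spearmanr(pooled_mu, pooled_alpha, alternative="greater")
    return {
        "winners": winners,
        "delta_dic": deltas,
        "n_correct": int(n_correct),
        "n_seeds": n_seeds,
        "ridge_rho": float(ridge_rho),
        "ridge_p": float(ridge_p),
    }


def ploidy_recovery(
    seed: int,
    n_patients: int = 20,
    psis=(2.0, 2.8, 3.6),
    noise_sd: float = 0.05,
    n_regions: int = 3,
    bin_width: int = 4_000_000,
    purities: tuple | None = None,
) -> dict:
    """Rank-1 ploidy recovery over synthetic multi-region patients with
    random true ploidy (4 Mb bins: enough bins for the fit-error curve to
    separate the near-degenerate solutions).

    Purities default to uniform draws over the region-sample range; pass a
    fixed tuple (e.g. (0.6, 0.8, 1.0)) to include a high-purity anchor,
    without which a genome-wide one-copy-shift alias is exactly degenerate
    with the truth on noiseless data.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    errors = []
    for _ in range(n_patients):
        psi = float(rng.choice(psis))
        spec = spec_for_stage(
            "carcinoma", n_regions=n_regions, gd_prob=0.0, bin_width=bin_width
        )
        profiles, _ = gen_patient(spec, rng, "P")
        rhos = (
            purities
            if purities is not None
            else [float(rng.uniform(0.5, 1.0)) for _ in profiles]
        )
        logr = [
            gen_logr(p, rho, psi, noise_sd, rng) for p, rho in zip(profiles, rhos)
        ]
        fits = rank_ploidies(logr)
        err = abs(fits[0].psi - psi)
        errors.append(err)
        if err <= 0.05 + 1e-9:
            hits += 1
    return {
        "n_patients": n_patients,
        "n_within_one_step": hits,
        "max_abs_error": float(np.max(errors)),
    }


def gd_classifier_accuracy(
    seed: int, n_patients: int = 40, n_regions: int = 2
) -> dict:
    """Sample-level genome-doubling classification accuracy on a synthetic
    cohort with known GD truth (decision-boundary sign, no ambiguity zone).
    """
    rng = np.random.default_rng(seed)
    clf = GDClassifier(ambiguous_margin=0.0)
    n_correct = n_total = 0
    spec = spec_for_stage("carcinoma", n_regions=n_regions, gd_prob=0.5)
    for k in range(n_patients):
        profiles, truth = gen_patient(spec, rng, f"P{k}")
        for p in profiles:
            call = classify_sample(
                count_segments(p), pga(p, baseline_ploidy(p)), clf, p.sample_id
            )
            n_total += 1
            if (call.call == "GD") == truth.gd:
                n_correct += 1
    return {
        "n_samples": n_total,
        "accuracy": n_correct / n_total,
    }
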