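"""Recover absolute copy number from shallow-WGS log2 ratios.

Simulates a three-region patient at a known ploidy with region-specific
purities and Gaussian logR noise, then runs the multi-sample grid search
and prints the top-ranked solutions.
"""

import numpy as np

from cnaevo.ploidy import integer_profiles, rank_ploidies
from cnaevo.synth import gen_logr, gen_patient, spec_for_stage

rng = np.random.default_rng(11)
true_psi = 2.8
true_rho = (0.6, 0.8, 1.0)

spec = spec_for_stage("carcinoma", n_regions=3, gd_prob=0.0, bin_width=4_000_000)
profiles, truth = gen_patient(spec, rng, "P1")
logr = [gen_logr(p, r, true_psi, 0.05, rng) for p, r in zip(profiles, true_rho)]

fits = rank_ploidies(logr)
print(f"true ploidy {true_psi}, purities {true_rho}\n")
print("rank  psi   fit_error  cross_dist  purities")
for f in fits[:5]:
    rho = "/".join(f"{v:.2f}" for v in f.purities.values())
    print(f"{f.rank:4d}  {f.psi:.2f}  {f.mean_fit_error:9.5f}  {f.cross_distance:10.4f}  {rho}")

chosen = fits[0]
cn = integer_profiles(logr, chosen)
print(
    f"\nchosen psi = {chosen.psi:.2f}; first region integer CN of bins 0-9: "
    f"{cn[0].cn[:10].tolist()}"
)
print(
    "The rank-1 solution minimizes both the within-sample rounding error\n"
    "and the between-sample inconsistency; one-copy-shifted aliases are\n"
    "rejected by the parsimony tie-break."
)
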