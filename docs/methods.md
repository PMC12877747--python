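# Methods

## The birth–death model of gland karyotype evolution

The unit of selection is the gland: a crypt-like population of a few
thousand recently related cells, treated as one individual with one
karyotype `G_i` — integer copy numbers over `C` bins spanning the 22
autosomes (default grid: 10 Mb bins, `C ≈ 295`; a 500 kb grid is available
via `default_grid(500_000)`). Fitness is a single-peak landscape around an
optimal karyotype `G_o`:

    b_i − d_i = (b0 − d0) / (1 + α · d(G_i, G_o)),   d = Σ_bins |cn − cn_o|

The fitness change is absorbed by the birth rate (death fixed at `d0`,
default) or by the death rate (`mode="death"`). Defaults `b0 = 1`,
`d0 = 0.2` per unit time: only their difference and `α` are identifiable
from end-point karyotypes, so these choices matter only for time scaling.
`α = 0` is the neutral (flat) model.

At each division, both daughters independently draw `k ~ Poisson(μ)` CNAs
(a switch restricts mutation to one daughter). An event is a contiguous run
of bins within one chromosome changed by ±1 copy, clipped to `[0, max_cn]`
with `max_cn = 8`; a bin at 0 copies cannot be regained. Event lengths come
from a bundled mixture — whole chromosome with probability 0.3, otherwise
geometric with mean 20 bins — replaceable by an empirical length sample.
Whole-genome doubling is not an event type of the simulator; it exists only
in the synthetic-cohort generator.

### Exact simulation over clones

The Gillespie process is simulated exactly, but over *clones* (sets of
glands sharing one karyotype and hence one birth/death rate) rather than
individual glands: a division picks a clone proportional to `count × b`,
each mutated daughter founds a child clone, deaths decrement counts. This
is an exact sampler of the individual-level process; the clone ancestry
(parent clone, creating events, time) is the genealogy, and every karyotype
is reconstructible by replaying the event log from the founder (verified in
the tests). Dead clones are compacted out of the active arrays so a step
costs O(live population).

Runs stop at a target population size `n_target` or at extinction. Under
strong selection with high mutation rates the population can enter a
near-critical "mutational meltdown" that neither grows nor dies for a very
long time; a step budget (default `150 × n_target`) converts such runs into
a distinct `stalled` outcome. Inference treats stalled like extinct: both
mean the parameter pair cannot produce the observed tumor.

## ABC inference and model selection

Rejection ABC over `μ ~ Uniform(0.1, 1)` — the lower bound is the
empirical single-cell floor for the per-gland-division CNA rate — and
`α ~ log-Uniform(10⁻³, 10)` for the selection model (`α ≡ 0` for the
neutral model). Each simulated gland set is reduced to six summary
statistics: mean pairwise PoAGS divergence, mean pairwise genetic distance,
mean and sd of PGA, proportion of the altered genome subclonal, and mean
segment count. Distances are Euclidean after standardizing each statistic
by its median absolute deviation across the simulations; the closest
`accept_quantile` of draws is accepted.

Model choice uses the deviance information criterion with a synthetic
likelihood, and four numerical choices here are load-bearing:

* the synthetic likelihood is a **diagonal** Gaussian over MAD-standardized
  statistics — a full 6×6 covariance from ≤8 replicates is singular;
* per-statistic variances are inflated by `(1 + 1/n)` (the observed vector
  is itself one draw from the model) and floored at 0.05 in standardized
  units, so few-replicate variance estimates cannot make the likelihood
  over-resolve;
* both models' deviances are standardized by a **pooled** scale computed
  from the union of their prior simulations — per-model scales shift each
  DIC by a scale-dependent constant and bias the comparison;
* replicate simulations inside the deviance are conditioned on reaching the
  target population size, exactly as the rejection step is.

`DIC = 2·mean(D over accepted draws) − D(posterior mean)`, with the
posterior mean of `α` taken geometrically (its prior is log-uniform; an
arithmetic mean is dominated by the largest accepted draw and can land in
the meltdown region). The DICs are Monte-Carlo estimates whose noise is of
order ten at the default replicate budget, so a winner is only declared
when `|ΔDIC|` exceeds 10 — the conventional DIC scale on which smaller
differences are not decisive; smaller gaps are reported as
indistinguishable.

**Problem sizes.** The recovery harness simulates populations of 1,000
glands and samples 77, with 150 prior draws per model, the closest 7%
accepted, and 8 deviance replicates per evaluated parameter. These sizes
are the package's desk-scale defaults; they recover the generating model
reliably in the harness (see `scripts/acceptance.py` output) while keeping
a two-model, ten-seed experiment within minutes. Selection strength and
mutation rate remain jointly unidentifiable from end-point karyotypes — the
accepted draws trace a positive μ–α ridge — which is why the μ prior floor
matters.

## Divergence metrics

Three-state calls (gain/baseline/loss) are made against each sample's own
baseline ploidy — the median per-bin copy number, ties to the lower integer
so the baseline is an attained state — which keeps a clonally genome-doubled
pair from appearing maximally divergent; a patient-shared baseline can be
passed explicitly. `FracDiffBins` and `FracDiffAltBins` (PoAGS) compare
states; their GeneDose variants weight bins by gene content;
`GeneticDistance` compares integers; `BreakpointDivergence` compares the
sets of bin boundaries where the state changes (exact positions, no slack
window, chromosome boundaries excluded). "Divergence" of a comparison group
is the mean pairwise PoAGS — unordered pairs within a set, all cross pairs
between sets (e.g. consecutive timepoints).

## Genome-doubling classification

A sample is scored `0.000355·NS + PGA − 0.432` (NS = number of segments,
PGA as a fraction); positive means doubled. The coefficients are constants
of the published rule; no retraining happens here. Scores within ±0.216
(half the intercept magnitude — the reading we adopt of the "±0.5 of β0"
ambiguity zone; the margin is configurable) are ambiguous. Patients are
clonally (non-)GD when at least one confident call of one kind and none of
the other exist; both kinds make subclonal GD. Ambiguous samples inherit
the clonal call, or in subclonal patients the majority confident call with
ties going to GD. All-ambiguous patients are reported `unresolved` (a
status the rule set otherwise leaves undefined).

## Multi-sample ploidy fitting from log2 ratios

Copy number follows the ASCAT transformation
`cn = (2^logr (2(1−ρ) + ρψ) − 2(1−ρ)) / ρ`. The grid search spans
ψ ∈ [1.5, 4] (step 0.05) and purity down to 0.5 for microdissected region
samples, 0.2 for bulk (step 0.01). Per sample and candidate ψ, the best
purity minimizes the mean squared deviation of implied copy numbers from
their nearest nonnegative integer (bins, not segments). Across samples,
profiles are rounded, divided by ψ, and compared pairwise by RMS distance
over bins with logr ≤ 1 (strict >1 excluded — an amplification guard
applied to the cross term only). Both measures are min–max scaled over the
ψ grid and candidates ranked by distance from (0, 0).

Two safeguards address a structural degeneracy: a genome-wide one-copy
shift with purities rescaled as `ρ' = 2ρ/(2−ρ)` reproduces integer
profiles *exactly*, and dividing the cross term by ψ favors such
higher-ploidy aliases. (a) Among local minima of the score curve within a
tie margin of the best — the margin is twice the estimated per-bin logR
noise sd, hence zero for noiseless data — the lowest ploidy is preferred.
(b) Within ±2 grid steps of that valley the ψ minimizing the per-sample fit
error is chosen, because the fit error is the sharper local signal while
the cross term still shrinks slightly with ψ. With these rules the
recovery harness (20 patients, ψ ∈ {2, 2.8, 3.6}, purities uniform on
[0.5, 1], σ = 0.05, 4 Mb bins) recovers 19–20/20. On noiseless data
the one-copy alias is *exactly* degenerate unless some sample has purity
above 2/3 (which makes `ρ' > 1` infeasible); the zero-noise check therefore
fixes purities at (0.6, 0.8, 1.0). Manual curation — choosing the
second-ranked solution or per-sample ψ offsets (±0.4) — is supported as
explicit overrides, never applied automatically.

## Phylogenetic event classification

Trees carry a karyotype at every node (simulator truth, or an external
reconstruction such as MEDICC2 — ancestral-state reconstruction is out of
scope here). A branch event is a maximal same-direction run of changed bins
between parent and child, counted once regardless of magnitude and never
crossing chromosomes; how a later event overlapping an earlier one on the
same lineage should be split is undefined in general, so runs are counted
per branch independently. Events on the root→MRCA path are clonal, on
internal branches below the MRCA intermediate, on pendant branches tips;
the MRCA is taken over the leaves mapped to tumor samples (outgroups
excluded; a single-leaf tree has no MRCA and is an error). Cross-patient
clonal frequencies are computed against the rounded (half-up) patient
ploidy, so a triploid or tetraploid tumor does not read as having gained
every bin.

## SNP phasing and imbalance tests

In segments with allele-specific imbalance (nMaj ≠ nMin), the expected BAF
of a major-haplotype SNP at purity ρ is
`(ρ·nMaj + (1−ρ)) / (ρ(nMaj+nMin) + 2(1−ρ))` — 2/3 in a pure trisomy.
SNPs are phased by their mean BAF pooled across deep glands (above 0.5 →
major), with a ±0.05 dead zone left unphased; balanced segments cannot be
phased and warn. Pooling across glands is a choice — per-gland phasing
would also be consistent with the data model. The shallow-sample tests are
an exact two-sided binomial test of pooled major/minor read counts against
0.5, and a Fisher exact test against an expected row built by scaling
(nMaj, nMin) to the observed read total (one of several ways to encode the
copy-number null as a 2×2; isolated in one function).

## The synthetic cohort generator

`gen_patient` draws trunk events shared by all regions until the clonal
PGA reaches its target, then private per-region events until the target
subclonal fraction is reached; an optional whole-genome doubling is applied
once a configurable fraction of the trunk has accrued (so pre-doubling
losses get doubled, leaving odd states). Stage presets place cohorts in the
observed progression phase space: adenomas (PGA target 8.5%, subclonal
fraction 0.5, GD 2%), early cancers (25.3%, 0.3, 13/39), carcinomas
(27.2%, 0.2, 16/81). Genome-doubled patients receive a doubled PGA target
(`gd_pga_boost = 2`), reflecting the higher alteration burden of doubled
tumors; this is also what gives the (NS, PGA) doubling rule its signal on
synthetic data. Log2-ratio profiles invert the ASCAT transformation and add
Gaussian noise; they are centered on the known ploidy normalization rather
than the empirical median (median-centering would redefine the recoverable
ploidy as the median copy number — a flag restores that behavior). BAF
fixtures draw alt counts binomially at the copy-number-implied means.

What the generator does *not* emulate: segmentation noise and wavy GC
biases, FFPE artifacts, subclonal mixtures within one sample, focal
high-level amplifications, and realistic breakpoint reuse. Tests passing on
this generator therefore certify the statistical machinery and its
conventions, not robustness to real sWGS noise.

## Numerical conventions and degenerate inputs

Coordinates are 0-based half-open (BED) everywhere; bins are fixed-width
with the last bin of each chromosome truncated. Segment counts are runs,
not transitions: a constant genome has one segment per chromosome, and
chromosome boundaries always break adjacency (exposed as a switch).
Consensus regions drop runs shorter than 4 bins (2 for single-cell data).
Empty profiles, mismatched grids, empty sample sets, zero read totals and
oversampling are errors; extinction and stalling are outcomes, not errors.
All randomness flows through `numpy.random.Generator` objects or integer
seeds; every harness in `cnaevo.benchmarks` is reproducible from one seed.

## Known limitations

End-point karyotypes cannot separate μ from α (the posterior ridge); the
DIC construction is one defensible synthetic-likelihood variant, isolated
behind `cnaevo.abc.dic` so it can be swapped; the ploidy fitter's
parsimony tie-break resolves a genuine non-identifiability by convention
and can be disabled; gland-internal cell dynamics are not modeled, so μ is
a per-gland rate; the simulator has no spatial structure and no
whole-genome-doubling event type.
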