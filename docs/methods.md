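# Methods

This note documents the models, numerical choices and open design
decisions behind `paleoabc`, in the spirit of a simulator/inference
package's model documentation. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## The serial coalescent

Time runs backward in generations before present (BP). A sequence sampled
at age `a` enters the genealogy at time `a`; with the package's one-year
generation time, calibrated years BP and generations BP coincide. Within
deme `d` holding `k` active lineages, coalescence occurs at rate
`k(k-1) / (2 N_d(t))`, so two lineages in a deme of constant size `N` wait
`N` generations on average. `N_d(t) = N_d(t0) exp(-r_d (t - t0))`
piecewise: `r > 0` is forward-time growth (sizes shrink going backward).
Point events at fixed times multiply a deme's size by a factor, reset its
growth rate (to 0 unless specified), and/or move lineages between demes
(a fraction of 1.0 is a population join). A migration matrix of
per-lineage per-generation rates is active on a window `[t_start, t_stop]`.

Two exact simulation schemes are used per inter-breakpoint segment
(breakpoints: tip activations, events, migration-window edges):

* a competing-risks scheme that inverts the integrated coalescent hazard
  per deme in closed form, `w = log(1 + r E / c) / r` with
  `c = k(k-1)/(2N(t))` (handles exponential growth exactly), redrawing
  candidates after every event;
* a next-reaction scheme with accumulated hazards for migration-active,
  zero-growth segments, where migration events are frequent (rates up to
  1/lineage/generation under the open model's prior) and per-event cost
  must stay O(1). Exponential clocks for "any coalescence" and "any
  migration" are decremented by the hazard spent; executing an event
  updates the total rates incrementally.

Configurations that fail to reach a common ancestor within 10⁷
generations (e.g. isolated demes) raise an error; in reference-table
construction such rows are redrawn from the priors and counted.

Correctness anchors (in the test suite): E[TMRCA] = N for two
contemporaneous tips; expected total length t + 2N for a pair sampled t
generations apart; Watterson's E[S] = 2Nμ·a₍ₙ₋₁₎ at small θ; and a
two-sample Kolmogorov–Smirnov comparison of the TMRCA distribution against
msprime (ploidy 1) at 10⁴ replicates.

## Mutation model

Mutations fall on branches as a Poisson process with per-site intensity
`μ_site × g_s`, where the `g_s` are continuous mean-1 gamma multipliers
(shape α per locus; continuous rather than discretized categories). Each
mutation is a Kimura-2-parameter change: a transition with probability
κ/(κ+2), otherwise one of the two transversions equiprobably. The root
sequence is uniform over {A, C, G, T}. Defaults: κ = 10 (a typical
mammalian mtDNA transition bias; its effect on diversity is largely
absorbed by the mutation-rate posterior) and α = 8 for the 282 bp
cytochrome-b locus versus α = 0.02 for the 426 bp control region. Which
locus carries which of the two shape values is not settled by the data
the package ships with; the assignment giving the control region the
extreme heterogeneity is consistent with its lower per-site variability
in the observed table, and both assignments are configurable (we verified
that the ABC posteriors of the built-in reanalysis change little between
them).

Rate units: priors are expressed in mutations/site/myr; with one-year
generations, 1 mut/site/myr = 10⁻⁶ per site per generation, and the
per-locus rate is the per-site rate times the locus length. All
conversions go through `serialcoal.mu_per_site_per_generation`.

## Effective-size convention

The simulator itself uses the haploid convention: its size parameter *is*
the expected pairwise coalescence time. The model layer, however, maps
every fNe parameter to a coalescent size of 2·fNe (`demography.FNE_SCALE`).
This matches the effective-size convention of the classic serial-coalescent
tooling this package replaces, and two package-internal checks support it:
the published oldest-layer diversity equals 2·(2·fNe_before)·μ_locus at
the published parameter scale, and the sampling-bias test reproduces the
expected significance pattern (young layers rejected, old layers not)
only under this scaling.

## The three demographic models and their priors

* **constant** — one deme, `N ~ U(1, 50000)` females.
* **closed_bottleneck** — one deme. Free parameters: modern size
  `N_modern ~ U(1, 50000)`, event time `T_b ~ U(0, 45000)` generations,
  size on the recent side of the event `fNe_after ~ U(1, 5000)`, size on
  the ancient side `fNe_before ~ U(1, 200000)`, mutation rate
  `μ ~ U(0.01, 0.2)` mut/site/myr. The growth rate between the present
  and the event is *derived* by continuity,
  `r = ln(N_modern / fNe_after) / T_b`, and the event severity is the
  ratio of two independent uniforms, `k = fNe_before / fNe_after`
  (support (1/5000, 200000)); above the event the size is constant. The
  identities `fNe_after = N(T_b⁻)` and `fNe_before = k·N(T_b⁻)` hold
  exactly. This parameterization was chosen over a free growth-rate prior
  after the latter proved degenerate: a free `r ~ U(−10⁻³, 10⁻³)` over
  event times up to 45,000 generations makes `N(T_b⁻)` span ~40 orders of
  magnitude, ~40% of draws fail to coalesce within the horizon, and more
  than half of all reference-table rows carry zero diversity, collapsing
  the MAD-normalized distance. Sizes on both sides of the event are also
  the natural reporting scale for a bottleneck.
* **open_migration** — four demes (the sampled locality plus three
  neighbouring regions), all sampled layers in deme 1. One ancestral
  population splits at `T_s ~ U(11000, 15000)` into demes of sizes
  `N_i ~ U(1, 20000)`; a hub-and-spoke migration matrix
  (`m_high ~ U(10⁻⁴, 1)` between the focal deme and each neighbour,
  `m_low ~ U(10⁻⁶, 10⁻⁴)` among neighbours, per lineage per generation)
  is active on `[T_stop, T_s]` with `T_stop ~ U(0, 1000)` — migration
  stopped near the present. The migration-rate bounds are reconstructions
  (the exact exponents are not recoverable); they are logged with every
  run.

## Summary statistics and ABC

The summary vector concatenates per-layer statistics with layers ordered
oldest → youngest: the estimation set is (S, Π, π) × 4 layers (12
entries; note π = Π/L makes two columns exactly collinear — the
regression solver handles the rank deficiency by minimal-norm least
squares, which leaves fitted values and adjustments unchanged), and the
model-comparison set is (S, π) × 4 layers. Statistics may be computed on
the combined 708 bp alignment (default) or per locus.

Rejection: each statistic column is scaled by its median absolute
deviation over the reference table (zero-MAD columns are dropped with a
warning); the `accept_count` rows nearest in Euclidean distance are kept
with Epanechnikov weights `1 − (d/δ)²`, δ the largest accepted distance.
Tolerances are specified as accepted counts with the fraction logged
alongside (defaults 0.25% for estimation, 0.3% for model comparison).

Regression adjustment: per parameter, weighted least squares of the
(log-transformed, when strictly positive; the derived growth rate spans 0
and stays linear) parameter on the centred statistics; adjusted draws are
`φ* = φ − (s − s_obs)ᵀβ̂`, back-transformed. Singular designs fall back to
a tiny ridge penalty with a warning.

Posterior summaries: the mode is the argmax of a Gaussian weighted KDE
(Silverman bandwidth) on the transformed scale, evaluated on a 512-point
grid and back-transformed; intervals are central weighted empirical
quantiles (the weighted quantile follows numpy's linear-interpolation
rule, so integer weights equal sample expansion). Fewer than 10 effective
draws triggers an unreliability warning.

Model comparison pools all models' rows, ranks by pooled-MAD distance,
reports per-model accepted shares (corrected for unequal table sizes) and
an Epanechnikov-weighted multinomial logistic regression of the model
label on the centred statistics evaluated at the observed vector. A model
with no accepted rows gets probability zero.

Bias test: per replicate, `N ~ U(30000, 50000)` and (by default) μ drawn
from the mutation prior — the null's mutation rate is a package choice; a
fixed-rate mode exists — the full serial design is simulated and each
layer's Π recorded; the one-sided lower-tail P uses the pseudo-count form
`(1 + #{Π_sim ≤ Π_obs}) / (1 + R)`, which avoids P = 0 and differs from
the naive proportion by O(1/R).

## Parsimony networks

The connection limit is the largest step count j whose probability of a
non-homoplastic connection exceeds the confidence level (default 95%).
The probability model: with j differences over L sites, the per-site
substitution intensity is the Jukes–Cantor plug-in
`θ = −(3/4) ln(1 − 4j/3L)`; substitution counts are Poisson(θ) per site,
and a connection is parsimonious when each observed difference reflects
exactly one substitution, giving `P_j = [θe^(−θ) / ((3/4)(1 − e^(−4θ/3)))]^j`.
A Monte-Carlo implementation of the same model serves as a cross-route
oracle in the tests. For 708 bp at 95% the limit is 10 steps. Divergences
at or beyond the 75% saturation point of the correction leave the network
unconstrained (limit = L).

Networks are built agglomeratively: pairs joined in order of increasing
mutational distance (ties broken by higher combined haplotype frequency,
then input order), unsampled intermediates inserted on multi-step edges,
already-connected pairs skipped (so each component is a tree; alternative
equal-length connections are not drawn), pairs beyond the limit left in
separate components. Gaps count as a fifth character state by default
(configurable to missing); IUPAC ambiguity codes are always missing.
Cross-layer links join *identical* sequences in adjacent layers only;
near-identical matches are reported in a side table, never linked.

## Synthetic data

The built-in scenarios reproduce the study design the package targets
(4 layers at 0/11,500/15,200/25,200 generations BP with n = 10/20/20/14,
708 bp in two loci, K2P + gamma): `pymva_like_bottleneck` fixes the
closed model at a plausible generating point (T_b = 14,000,
N_modern = 11,000, fNe_after = 3,700, fNe_before = 28,000,
μ_locus = 5.6 × 10⁻⁵ — the posterior scale of the package's own headline
reanalysis, used as a generating point, not ground truth);
`constant_null` (N = 40,000) and `open_migration_demo` (T_s = 13,000,
N_i = 5,000, m_high = 0.01) use the same per-site mutation rate. The
generator emulates the coalescent/mutational structure of the real series
but none of its laboratory features — no sequencing error, no post-mortem
damage, no alignment gaps or ambiguity codes — so passing recovery tests
demonstrates statistical correctness of the inference machinery, not
robustness to real-data artifacts.

## Problem sizes and reproducibility

Default analysis scales, chosen as the package's desk scale: 200,000
reference-table rows for single-model fits (accepted count 500), 100,000
rows per model for the three-model comparison (accepted 900 of 300,000),
50,000 replicates for the bias test, 50,000-row tables for the 20-dataset
recovery study. All randomness flows from explicit integer seeds through
`numpy.random.SeedSequence`-derived counter streams, so tables are
reproducible and chunkable; the batched reference-table simulator and the
single-dataset API consume identical derived seed pairs and agree
bit-for-bit.

## Known limitations

* The bottleneck-time, pre-bottleneck-size and modern-size marginals are
  weakly identified by four layers of (S, Π, π): their posterior
  densities are broad (the 95% intervals approach the priors) and the
  location of the density bump is sensitive to tolerance, bandwidth and
  transform choices. The package's weighted-KDE modes for the bundled
  observed vector place the bottleneck near 20,000–23,000 generations BP
  with a large pre-bottleneck size; the recovery study shows the same
  upward scatter of modes around a true value of 14,000 even though the
  90% intervals cover it.
* The open model keeps the ancestral (pre-split) size equal to the focal
  deme's size (≤ 20,000), so it cannot host a large pre-split population;
  with the bundled observed vector it is accordingly out-competed by the
  closed model in the comparison step.
* No recombination, selection, diploid scaling or sequencing-error
  overlay; single mitochondrial linkage group only.
* Migration combined with within-window exponential growth uses the
  general (slower) simulation path; the built-in models never combine
  the two.
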