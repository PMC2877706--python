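# paleoabc

Demographic inference from serially sampled ancient mitochondrial DNA.

`paleoabc` is a Python library for the "phylochronological" analysis of
heterochronous sequence data: alignments in which every sequence carries a
known age (calibrated years before present), so that genetic diversity can
be tracked through time and demographic history inferred from it. Its
built-in worked case is the Pymva Shor (northern Pre-Urals) collared-lemming
(*Dicrostonyx torquatus*) series — 708 bp of mtDNA (282 bp cytochrome b +
426 bp control region) sampled at four time points (modern and 11,500 /
15,200 / 25,200 cal. yrs BP; n = 10/20/20/14) — whose published per-layer
summary statistics ship with the package, so the whole reanalysis runs
without any downloads.

It is aimed at population geneticists and ancient-DNA researchers who want
a fast, scriptable, fully reproducible replacement for the classic
serial-coalescent + ABC toolchain (serial SimCoal-style simulation, the
Beaumont rejection/regression machinery, and TCS-style parsimony networks).

## What it computes

**Serial coalescent simulator** (numba-accelerated, ~10⁵ datasets/minute
for single-deme models). Lineages enter the genealogy at their layer age
and coalesce within demes at rate k(k−1)/(2N_d(t)); deme sizes follow
piecewise-exponential trajectories with point events (size scalings,
population joins) and a migration matrix active on a time window.
Mutations are overlaid as a Poisson process under Kimura's two-parameter
model with continuous gamma rate heterogeneity across sites.

**Per-layer diversity statistics.** Segregating sites S, haplotype count
K, mean pairwise difference Π, nucleotide diversity π = Π/L, and haplotype
diversity H = n/(n−1)(1 − Σp²), with pairwise deletion of ambiguous bases.

**Approximate Bayesian computation.** Reference tables of (θ, s) rows;
rejection keeps the closest accepted fraction in MAD-normalized Euclidean
distance with Epanechnikov weights w = 1 − (d/δ)²; local-linear regression
adjustment φ* = φ − (s − s_obs)ᵀβ̂ on log scale for positive parameters;
weighted-KDE posterior modes and weighted quantile intervals; model choice
by accepted-row proportions and weighted multinomial logistic regression.
Three demographic models are built in: constant size, a closed
single-population bottleneck, and an open 4-deme model with ancient
migration.

**Constant-size sampling-bias test.** One-sided lower-tail P-values of
each layer's Π against a constant-population null (fNe ~ U(30,000–50,000)),
asking whether the observed diversity decline could be a sampling artifact.

**Temporal statistical-parsimony networks.** Haplotype networks per time
point under the 95% parsimony connection limit, stacked into a temporal
network by linking identical haplotypes across adjacent layers; GraphML
and DOT export.

## Worked example

Is the diversity decline real, and when did the population crash?

```python
from paleoabc import bias_test, pymva_shor_design, pymva_shor_table

obs_pi = pymva_shor_table("combined")["Pi"].to_numpy()  # oldest -> youngest
report = bias_test(obs_pi, pymva_shor_design(), n_reps=20_000, seed=3)
print(report.to_frame())
```

```
        observed_Pi         P
layer
25200         6.187  0.429979
15200         2.547  0.133393
11500         0.789  0.021599
modern        0.667  0.019499
```

The two youngest layers' low diversity has P < 0.05 under a constant
population — the decline is not a sampling artifact — while the two oldest
layers are fully compatible with it. Fitting the closed-bottleneck model
by ABC (`examples/04_abc_fit.py`, 40,000 simulations) then yields posterior
modes of roughly 3,600 females on the recent side of the collapse against
~10⁵ before it (a ~20-fold reduction), a per-locus mutation rate of
4.3 × 10⁻⁵ per generation, and a bottleneck time in the late-glacial
window (mode ≈ 23,000 generations BP at this desk scale, with wide
intervals — see `docs/methods.md` on the weak identifiability of the
event-time marginal).

The `examples/` directory holds one short script per capability
(statistics, simulation, bias test, ABC fit, model comparison, networks);
each prints what it computes and what the numbers mean. A thin CLI
(`paleoabc sumstats|simulate|network|bias-test|abc-fit|abc-compare|
fixtures|run`) wraps the same functions for shell use.

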