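"""ABC fit of the closed-bottleneck model to the observed statistics.

Simulates a reference table under the model priors, keeps the 0.25% of
rows closest to the observed summary vector (MAD-normalized Euclidean
distance), applies the local-linear regression adjustment, and prints
posterior modes and central quantile intervals per parameter.

A desk run; increase n_sims for sharper posteriors.
"""

from paleoabc import (build_reference_table, default_model, posterior_summary,
                      pymva_shor_design, pymva_shor_observed,
                      regression_adjust, reject)

n_sims = 40_000
table = build_reference_table(default_model("closed_bottleneck"),
                              pymva_shor_design(), "estimation12",
                              n_sims=n_sims, seed=1)
post = regression_adjust(reject(table, pymva_shor_observed(),
                                round(0.0025 * n_sims)))
print(posterior_summary(post).to_string())
print("\nT_b is the bottleneck time (generations BP); fNe_after/fNe_before "
      "the female effective sizes on the recent/ancient side of the event; "
      "mu_locus the mutation rate per 708 bp per generation.")
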