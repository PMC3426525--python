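"""Compare the three parametrizations by cross-validated held-out likelihood.

Runs a reduced grid (C in {2,3,4}, 3 folds, 2 restarts) on 120 simulated
wells and prints the summed test log-likelihood per model and class
count.  On data with correlated descriptors and within-well coherence
the copula mixture should dominate the full Gaussian, which in turn
dominates the flat diagonal baseline.
"""

import wellmix as wm

data, _, _ = wm.make_scenario("negative_like", seed=11, n_wells=120)
cv = wm.cross_validate(
    data,
    parametrizations=["copula", "gaussian_full", "baseline_diag"],
    C_range=[2, 3, 4],
    n_folds=3,
    n_restarts=2,
    n_repeats=1,
    seed=11,
)

rec = cv.records[cv.records["valid"]]
table = rec.groupby(["parametrization", "C"])["test_loglik"].sum().unstack()
print("summed held-out log-likelihood (higher is better):")
print(table.round(1).to_string())
for p in table.index:
    print(f"selected C for {p}: {wm.select_num_classes(cv, p)}")
print(
    "\nThe copula rows should sit far above the Gaussian rows, and the flat\n"
    "diagonal baseline far below both: modelling descriptor dependence and\n"
    "the shared latent class of a well's fields both pay off out of sample."
)
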