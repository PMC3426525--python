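"""Detect experimental-outlier wells through small mixture classes.

Simulates a negative-control plate in which 5% of wells come from an
atypical "imaging artifact" population, fits a copula mixture with one
spare class, and flags classes holding fewer than 5% of wells.  The
flagged member wells are compared against the injected ground truth.
"""

import numpy as np

import wellmix as wm

data, scenario, labels = wm.make_scenario("with_outliers", seed=51)
outlier_label = scenario.true_models["GL2"].C
true_outliers = {
    data.wells[i].well_id for i in np.flatnonzero(labels == outlier_label)
}
print(f"injected {len(true_outliers)} outlier wells of {data.n_wells}")

fit = wm.fit_em(data, C=4, parametrization="copula", seed=0, max_iter=200)
scores = wm.score_wells(fit.model, data)
flagged = wm.flag_small_classes(scores, min_fraction=0.05)

for cls, wells in flagged.items():
    hits = len(set(wells) & true_outliers)
    print(f"small class {cls}: {len(wells)} wells, {hits} of them injected outliers")
found = {w for ws in flagged.values() for w in ws}
recall = len(found & true_outliers) / len(true_outliers)
print(f"recall of injected outliers via small-class flagging: {recall:.2f}")
print(
    "\nThe mixture assigns the recurrent atypical wells their own sparse class;\n"
    "flagging classes below the 5% membership cutoff recovers the injected\n"
    "outliers without any supervision."
)
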