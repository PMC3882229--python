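"""Compare Harrell's and Uno's concordance estimators under censoring.

Generates one dataset from the four-marker AFT design without censoring
(the ground-truth concordance of the true marker combination), then the
same design censored at 50%, and scores the true combination with both
estimators.  Harrell's pair counting ignores pairs whose smaller time is
censored and drifts away from the uncensored value; Uno's IPCW weighting
corrects for the lost pairs.
"""

import numpy as np

from cboost import four_marker_preset, generate, harrell_c, km_fit, uno_c

rng = np.random.default_rng(42)

uncensored = generate(four_marker_preset(n=4000, target_censoring=0.0), rng)
c_full = harrell_c(uncensored.sample, uncensored.true_eta).estimate
print(f"uncensored concordance of the true combination: {c_full:.3f}")

censored = generate(four_marker_preset(n=4000, target_censoring=0.5), rng)
g = km_fit(censored.sample.observed_time, 1 - censored.sample.event)
c_h = harrell_c(censored.sample, censored.true_eta).estimate
c_u = uno_c(censored.sample, censored.true_eta, g).estimate
print(f"at 50% censoring: Harrell {c_h:.3f}, Uno (IPCW) {c_u:.3f}")
print(
    "Harrell's estimator counts only pairs whose earlier time is an event;\n"
    "Uno's estimator reweights those pairs by the inverse squared censoring\n"
    "survival curve, recovering the concordance over the observable horizon."
)
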