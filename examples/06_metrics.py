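"""The evaluation metrics on worked examples.

CI, r_m^2 and AUPR are the field's standard regression/classification
metrics for affinity prediction; McNemar compares two classifiers on the
same instances through their discordant errors.
"""

import numpy as np

from dtafusion import aupr, concordance_index, mcnemar_test, mse, rm2

y = [1, 2, 3, 4]
yhat = [1, 3, 2, 4]
print(f"CI({y}, {yhat}) = {concordance_index(y, yhat):.4f}  "
      "(5 of 6 truth-ordered pairs ranked correctly)")

labels = [1, 0, 1, 0]
scores = [0.9, 0.8, 0.7, 0.1]
print(f"AUPR({labels}, {scores}) = {aupr(labels, scores):.4f}  "
      "(precision 1/1 at the first hit, 2/3 at the second; AP = 5/6)")

truth = np.array([5.1, 6.2, 7.4, 8.0, 9.1])
pred = np.array([5.3, 6.0, 7.6, 7.9, 8.8])
print(f"MSE  = {mse(truth, pred):.4f}")
print(f"r_m2 = {rm2(truth, pred):.4f}  (penalizes through-origin disagreement)")

labels = np.zeros(10, dtype=int)
pa = np.zeros(10, dtype=int)   # classifier A: all correct
pb = np.ones(10, dtype=int)    # classifier B: all wrong
print(f"McNemar p (10 vs 0 discordant) = {mcnemar_test(labels, pa, pb):.6f}  "
      "(= 2 * 0.5^10, the exact two-sided binomial)")
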