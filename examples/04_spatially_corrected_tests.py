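"""Why spatially corrected correlation tests matter.

Two independent but spatially smooth fields look correlated to a naive
Pearson test far too often.  The modified t-test estimates an effective
sample size from distance-class autocovariances and restores calibration.
"""

import numpy as np
from scipy import stats
from scipy.spatial.distance import cdist

from macrogd import modified_ttest

rng = np.random.default_rng(0)
n = 100
coords = rng.uniform(0, 1000, size=(n, 2))
chol = np.linalg.cholesky(np.exp(-cdist(coords, coords) / 400.0) + 1e-10 * np.eye(n))

naive_rej = corrected_rej = 0
sims = 200
for _ in range(sims):
    x = chol @ rng.standard_normal(n)  # two INDEPENDENT smooth fields
    y = chol @ rng.standard_normal(n)
    naive_rej += stats.pearsonr(x, y).pvalue < 0.05
    corrected_rej += modified_ttest(x, y, coords).p < 0.05

res = modified_ttest(x, y, coords)
print(f"one draw: r = {res.r:+.3f}, effective n = {res.effective_n:.1f} "
      f"(nominal n = {n}), p = {res.p:.3f}")
print(f"false-positive rate over {sims} draws at alpha = 0.05:")
print(f"  naive Pearson : {naive_rej / sims:.3f}   (badly anti-conservative)")
print(f"  modified test : {corrected_rej / sims:.3f}   (near nominal)")
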