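"""Laplace smoothing and the arcsin / logit / Blom / Box-Cox transforms.

A row of raw counts becomes a vector of smoothed mapping probabilities
(strictly positive, summing to 1), which the arcsin or logit map carries to
the real line for the Normal model.
"""

import numpy as np

from eqtlmap import laplace_smooth, proportion_transform, transform_counts

z = np.array([[0, 9, 41], [5, 5, 40], [12, 0, 8]])
sm = laplace_smooth(z, c=1.0)
print("counts row 0          :", z[0])
print("smoothed probs row 0  :", np.round(sm.probs[0], 4), " (sums to", sm.probs[0].sum(), ")")
print("arcsin row 0          :", np.round(proportion_transform(sm, "arcsin").values[0], 4))
print("logit  row 0          :", np.round(proportion_transform(sm, "logit").values[0], 4))
# the zero count becomes a small but positive probability 1/53; larger
# smoothing constants pull every probability toward the uniform 1/3.

bc = transform_counts(z, "boxcox")
print("per-gene Box-Cox lambda:", np.round(bc.params["lambda"], 3))
bl = transform_counts(z, "blom")
print("Blom scores col 0      :", np.round(bl.values[:, 0], 3), " (rank-based normal scores)")
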