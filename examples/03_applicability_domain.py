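"""Leverage applicability domain: which predictions can be trusted?

The leverage h(x) = x'(X'X)^-1 x measures how far a query sits from the
training design X. The cutoff h* is the 95th percentile of leave-one-out
leverages of the training rows; queries above it are out of domain.
"""

import numpy as np

from cnlri import fit_ad, in_domain

rng = np.random.default_rng(1)
X_train = rng.normal(size=(200, 4))

ad = fit_ad(X_train, feature_names=[f"d{j}" for j in range(4)], percentile=95)
print(f"h* (95th LOO percentile) = {ad.h_star:.4f}")
print(f"training rows above h*: {int((ad.training_leverages > ad.h_star).sum())}/200")

center = X_train.mean(axis=0)
far = X_train.max(axis=0) * 4
for name, x in [("central query", center), ("far query", far)]:
    inside, h = in_domain(x, ad)
    print(f"{name}: leverage {h:.4f} -> {'inside' if inside else 'OUTSIDE'} the domain")
# predictions for out-of-domain queries should be reported but not trusted.
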