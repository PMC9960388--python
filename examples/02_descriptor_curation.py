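"""Curate replicated molecular-descriptor tables.

Descriptors are min-max scaled jointly across replicate calculations;
any descriptor whose across-replicate variance reaches 0.01 on the
scaled scale is considered numerically unstable and removed.
"""

import numpy as np
import pandas as pd

from cnlri import DescriptorTable, apply_curation, stability_filter

rng = np.random.default_rng(0)
compounds = [f"mol{i}" for i in range(30)]
base = pd.DataFrame(
    {
        "logp_like": rng.normal(2.0, 1.0, 30),
        "tpsa_like": rng.normal(60.0, 20.0, 30),
        "flaky_3d": rng.normal(0.0, 1.0, 30),
    },
    index=compounds,
)

replicates = []
for r in range(3):
    rep = base.copy()
    rep += rng.normal(0, 0.01, rep.shape)          # reproducible numerics
    rep["flaky_3d"] += rng.normal(0, 2.0, 30)       # unstable 3D descriptor
    replicates.append(DescriptorTable(rep, replicate_id=r + 1))

report = stability_filter(replicates, threshold=0.01)
print(f"kept: {report.kept}")
for name, var in report.dropped_unstable.items():
    print(f"dropped {name}: replicate variance {var:.3f} (>= 0.01)")

# the stored scaling is re-applied verbatim to new, un-replicated data
new = DescriptorTable(base.iloc[:3] * 1.5)
print(apply_curation(new, report).frame.round(3))
# values may fall outside [0, 1]: new compounds can exceed the fitted range.
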