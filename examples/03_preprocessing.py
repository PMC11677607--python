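"""Hellinger transform, range normalization and the collinearity screen.

The synthetic landscape deliberately carries a near-duplicate climate pair
(BIO1/BIO5, r > 0.95), which the greedy screen removes while keeping the
earlier column of each offending pair.
"""

import pandas as pd

import phylospat as ps
from phylospat.simulate import LandscapeScenario

# Hellinger: rows become unit vectors of square-rooted relative abundances
M = pd.DataFrame([[1, 0, 3], [2, 2, 0]], index=["site_1", "site_2"],
                 columns=["sp_a", "sp_b", "sp_c"])
print("Hellinger-transformed community:")
print(ps.hellinger_transform(M).round(5))
print()

print("range_normalize([10, 20, 30]) ->", [float(v) for v in ps.range_normalize([10, 20, 30])])
print()

land = ps.simulate_landscape(LandscapeScenario(seed=3))
climate = land.env[[c for c in land.env.columns if c.startswith("BIO")]]
kept, log = ps.drop_collinear(climate, threshold=0.95)
print(f"climate columns in: {list(climate.columns)}")
print(f"retained:           {list(kept.columns)}")
for d in log:
    print(f"dropped {d.dropped} (r={d.r:.4f} with retained {d.against})")
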