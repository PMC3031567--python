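"""Check the one-false-connection-per-signature calibration.

With the significance threshold set to 1/n_sets, a random signature
queried against a *null* database (no real connections) should pick up
one significant connection on average.  This scales the full study
condition down to 50 sets and 20 signatures so it runs in seconds.
"""

import numpy as np

from perturbmap import GeneSignature, NullModel, make_null_db, query

db = make_null_db(n_sets=50, profiles_per_set=2, n_genes=500, seed=3)
rng = np.random.default_rng(30)

counts = []
for i in range(20):
    idx = rng.choice(db.universe.n_genes, 20, replace=False)
    sig = GeneSignature(
        tuple((db.universe.probe_ids[j], int(rng.integers(0, 2) * 2 - 1))
              for j in idx)
    )
    res = query(db, sig, NullModel(K=5_000, seed=600 + i))
    counts.append(sum(r.significant for r in res))

print(f"threshold: 1/{db.n_sets} = {db.significance_threshold}")
print(f"significant connections per signature: {counts}")
print(f"mean: {np.mean(counts):.2f} (expected about 1)")
# Each count is the number of false connections for one random
# signature; their mean near 1 confirms the threshold does what the
# 1/n_sets rule promises.
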