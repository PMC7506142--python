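"""Overlap classification and the randomization null.

Classifies two RBPs' sites on shared 3'UTRs into overlapping/neighboring
scenarios, then asks how often that much overlap would occur if every
site landed uniformly at random on its own UTR.
"""

import numpy as np

from transinteract import (
    BindingSite,
    UtrModel,
    classify_pairs,
    pool_sites,
    randomize_sites,
)

# Deliberately co-localized sites: RBP-A and RBP-B within 10 nt on every gene
utrs = {f"G{i}": UtrModel(f"G{i}", f"T{i}", "+", ((0, 400),)) for i in range(30)}
sites = []
rng = np.random.default_rng(0)
for i in range(30):
    p = int(rng.integers(50, 300))
    sites.append(BindingSite("RBP-A", "RBP", f"G{i}", p, p + 25))
    sites.append(BindingSite("RBP-B", "RBP", f"G{i}", p + 10, p + 35))
catalog = pool_sites(utrs, sites)

trios, pairs = classify_pairs(catalog)
n_over = sum(t.scenario == "overlapping" for t in trios)
print(f"{len(trios)} shared-gene trios: {n_over} overlapping, "
      f"{len(trios) - n_over} neighboring")

null = randomize_sites(catalog, n_rounds=10, seed=17)
print(f"observed overlapped-site fraction: {null.observed_overlap_fraction:.3f}")
print(f"randomized baseline (mean of 10 rounds): {null.null_mean:.3f}")
# The observed fraction far exceeding the randomized baseline is the
# signature of genuine spatial co-localization rather than chance crowding.
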