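"""Concentric-annulus gene-set enrichment with dual permutation nulls.

Generates the reference induced lattice, partitions it into the seven
annuli (breakpoints 500...1825 plus the open outer bin), and tests the
innermost-annulus enrichment against 1,000 random centers and 1,000 random
gene sets.
"""

import numpy as np

from optopattern import (
    DEFAULT_BREAKPOINTS,
    SyntheticConfig,
    dual_permutation_test,
    generate_spot_dataset,
)

cfg = SyntheticConfig(rng_seed=1)
data = generate_spot_dataset(cfg)
center = tuple(data.coords.mean(axis=0))

profile, res_center, res_geneset = dual_permutation_test(
    data, cfg.induced_set, center, DEFAULT_BREAKPOINTS,
    n_permutations=1000, seed=1,
)

print("annulus   score   p(center)  p(geneset)")
for k in range(profile.n_bins):
    print(
        f"c{k + 1}       {profile.norm_score[k]:6.3f}   "
        f"{res_center.p_values[k]:9.4f}  {res_geneset.p_values[k]:9.4f}"
    )

# The normalized score averages to 1 across annuli; values above 1 mark
# annuli where the gene set takes a larger share of the transcripts than
# average. A small p in c1 against BOTH nulls says the enrichment is tied to
# this center and to this particular gene set.
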