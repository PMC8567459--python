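"""Chinese-restaurant-process priors and exact partition combinatorics.

The clustering prior is a rich-get-richer process: a new item joins an
existing cluster in proportion to its size, or opens a new cluster in
proportion to the dispersion parameter alpha.  The number of possible
clusterings grows as the Bell numbers — the reason exact inference is
only feasible for a handful of stimuli.
"""

import numpy as np

from refreshcat.distributions import (
    bell_number,
    crp_assignment_probs,
    crp_joint_logprob,
    enumerate_partitions,
)

probs = crp_assignment_probs([2, 1], alpha=10.0)
print("Seating probabilities with clusters of size 2 and 1, alpha = 10:")
print(f"  join cluster 1: {probs[0]:.3f}   join cluster 2: {probs[1]:.3f}   "
      f"new cluster: {probs[2]:.3f}")
print("  (a high alpha strongly favors opening new clusters)")

lp = crp_joint_logprob([0, 0, 1, 0], alpha=1.0)
print(f"\nlog P of the partition {{1,2,4}},{{3}} at alpha = 1: {lp:.4f}")
print("  identical for every presentation order (exchangeability):",
      crp_joint_logprob([0, 1, 0, 0], alpha=1.0) == lp)

print(f"\nSet partitions of 6 items: {len(enumerate_partitions(6))} "
      f"(= Bell(6) = {bell_number(6)})")
print(f"Partitions of a lifetime of 100 experienced objects: "
      f"{bell_number(100):.2e} — exact posterior inference is hopeless, "
      "which is why the package also ships Gibbs and particle-filter engines.")
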