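"""Neutral coalescent sanity check: simulated diversity matches theory.

Simulates one panmictic population (n=10 chromosomes, θ=5 per locus) and
compares the mean number of segregating sites and mean pairwise diversity
with their closed-form neutral expectations E[S]=θ·Σ1/i and E[π]=θ.
"""

import numpy as np

import sweepscan as ss

model = ss.IWMModel(sample_sizes=(10,), split_time=0.0, migration_rate=0.0,
                    theta=5.0, locus_length=1000)
reps = ss.simulate_neutral_iwm(model, 1000, seed=1)

S = np.array([r.segsites for r in reps])
pi = np.array([r.pairwise_diversity() for r in reps])
a9 = sum(1.0 / i for i in range(1, 10))

print(f"mean segregating sites : {S.mean():.2f}  (expected {5 * a9:.2f})")
print(f"mean pairwise diversity: {pi.mean():.2f}  (expected 5.00)")
print("Both should sit within Monte-Carlo error of the Watterson and")
print("pairwise-diversity expectations for theta = 5.")
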