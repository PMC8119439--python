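"""Non-inferiority testing and sample-size planning.

"Non-inferior" means: not worse than the comparator by more than a
clinically accepted margin — 10 percentage points of accuracy, 5 mm of
slice distance (one CT slice), or 0.25 rank/usefulness units. All tests
are one-sided; p < 0.05 rejects inferiority.
"""

import numpy as np

from pulmotrunk.noninferiority import (
    PairedBinaryTable,
    noninf_distance_test,
    noninf_paired_binary,
    noninf_paired_shifted_wilcoxon,
    sample_size_noninf_t,
    sample_size_paired_binary,
)

rng = np.random.default_rng(0)

# paired accuracy: method A hits 225/239, B hits 215/239, case-matched
table = PairedBinaryTable(n11=210, n10=15, n01=5, n00=9)
res = noninf_paired_binary(table, margin=0.10)
print(f"accuracy (margin 10%)   : z = {res.statistic:.2f}, p = {res.p_value:.2g}, non-inferior = {res.decision}")

# distances to the reference slice, A about as good as B
dist_a = np.abs(rng.normal(5, 4, 239))
dist_b = np.abs(rng.normal(6, 5, 239))
res = noninf_distance_test(dist_a, dist_b, margin_mm=5.0)
print(f"distance (margin 5 mm)  : t = {res.statistic:.2f}, p = {res.p_value:.2g}, non-inferior = {res.decision}")

# per-case ranks judged for both methods (smaller is better)
ranks_a = rng.integers(1, 4, 60).astype(float)
ranks_b = ranks_a + rng.integers(-1, 2, 60)
res = noninf_paired_shifted_wilcoxon(ranks_a, ranks_b, margin=0.25, larger_is_better=False)
print(f"rank (margin 0.25)      : W+ = {res.statistic:.0f}, p = {res.p_value:.2g}, non-inferior = {res.decision}")

print()
n_t = sample_size_noninf_t(power=0.8, alpha=0.05, margin=5.0, sd=10.0)
n_b = sample_size_paired_binary(0.8, 0.05, 0.10, 0.9, 0.9, discordance=0.1)
print(f"sample size, distance design (margin 5 mm, sd 10 mm, power 0.8): n = {n_t}")
print(f"sample size, paired-accuracy design (margin 10%, power 0.8)    : n = {n_b}")
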