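"""Score radiologist judgements: accuracy, mean rank, mean usefulness.

The blinded-reading comparison assigns each method a per-case relative
rank (1 best of 4, ties allowed) and an absolute usefulness grade
(optimal / useful / useless, scored +1 / 0 / -1). Given the count
distributions for a 239-case cohort, the summary scores reduce to
simple weighted means with half-up rounding.
"""

from pulmotrunk.evaluation import accuracy_from_errors, mean_rank, mean_usefulness, rank_by_distance

methods = {
    #                 errors  rank counts        usefulness counts
    "rater 1": dict(errors=40, ranks=(144, 87, 17, 0), useful=(177, 49, 13)),
    "rater 2": dict(errors=122, ranks=(167, 50, 20, 2), useful=(165, 46, 28)),
    "rater 3": dict(errors=66, ranks=(79, 76, 71, 13), useful=(101, 101, 37)),
    "network": dict(errors=6, ranks=(155, 59, 24, 1), useful=(179, 56, 4)),
}

print(f"{'method':8} {'accuracy':>9} {'mean rank':>10} {'usefulness':>11}")
for name, m in methods.items():
    acc = accuracy_from_errors(m["errors"], 239)
    rank = mean_rank(m["ranks"])
    usef = mean_usefulness(*m["useful"])
    print(f"{name:8} {acc:8.1f}% {rank:10.1f} {usef:11.2f}")

print()
print("A usefulness of +1.00 would mean every selected slice was optimal,")
print("-1.00 that every one was useless for bolus tracking.")
print()
dists = (0.0, 5.0, 5.0, 9.0)
print(f"automatic rank stand-in: distances {dists} -> ranks {rank_by_distance(dists)}")
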