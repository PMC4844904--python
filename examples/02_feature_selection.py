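"""Correlation-filter feature selection, test by test.

Each feature of each vocal test is correlated with the PD/control label
(point-biserial r); features with two-sided p < 0.05 survive.  Tests
where nothing survives are 'unsuccessful': MCFS hands them the most
frequently selected features overall, A-MCFS drops them from the vote.
"""

from vocalvote import (
    SyntheticSpec, build_selection_plan, feature_frequencies, generate,
    select_features, separate_by_test, zscore_normalize,
)

table = generate(SyntheticSpec(seed=7))
results = [select_features(zscore_normalize(s)) for s in separate_by_test(table)]

successful = [r.test_id for r in results if r.successful]
print(f"successful tests ({len(successful)}/26): {successful}")
print("(the informative tests 4, 6, 7 should be among them; the rest are "
      "false positives of the 5% filter)")

freqs = feature_frequencies(results)
top = sorted((j for j, c in freqs.items() if c), key=lambda j: (-freqs[j], j))[:4]
print(f"most frequently selected features: {[(j, freqs[j]) for j in top]}")

mcfs = build_selection_plan(results, mode="mcfs", fallback_k=4)
amcfs = build_selection_plan(results, mode="a-mcfs")
print(f"MCFS fallback features for unsuccessful tests: {mcfs.fallback_features}")
print(f"A-MCFS keeps {len(amcfs.per_test_features)} of 26 tests")
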