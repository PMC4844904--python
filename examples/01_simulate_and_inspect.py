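"""Generate a synthetic voice study and look at its structure.

Draws the default study: 40 subjects (20 PD / 20 control), 26 vocal tests
per subject, 26 acoustic features per recording, with a real class signal
(1.5 SD mean shift on features 1-4) confined to tests 4, 6 and 7.
"""

from vocalvote import SyntheticSpec, generate, separate_by_test

table = generate(SyntheticSpec(seed=7))
print(f"rows: {len(table.data)} (subjects x tests = {table.n_subjects} x {table.n_tests})")
print(f"class balance: {int(table.subject_labels().sum())} PD / "
      f"{int((1 - table.subject_labels()).sum())} control")

subsets = separate_by_test(table)
print(f"separated into {len(subsets)} per-test subsets of "
      f"{subsets[0].n_subjects} x {subsets[0].n_features} each")
# Each subset is the unit of modelling: one classifier will be trained per
# vocal test, so a subject contributes exactly one row to each subset.
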