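"""The two classical baselines the framework is compared against.

LOSO pools all 1040 recordings into one matrix and holds out each
subject's 26 recordings together (scored per recording).  s-LOO first
collapses each subject's 26 recordings to per-feature summary statistics
(central tendency + dispersion), then leaves one subject out at a time.
Both ignore *which* vocal test a recording came from — the information
the framework exploits.
"""

from vocalvote import (
    STAT_CODES, ClassifierSpec, SyntheticSpec, generate, loso_cv, run_framework, sloo_cv,
)

table = generate(SyntheticSpec(seed=7))

loso = loso_cv(table, ClassifierSpec("svm_rbf"))
print(f"LOSO (per-recording):      accuracy {loso.accuracy:5.2f}%  MCC {loso.mcc:.4f}")

for code in ("1-4", "2-5", "3-6", "all"):
    m = sloo_cv(table, STAT_CODES[code], ClassifierSpec("svm_linear"))
    print(f"s-LOO ({code:>3s}, linear SVM): accuracy {m.accuracy:5.2f}%  MCC {m.mcc:.4f}")

fw = run_framework(table, mode="a-mcfs", spec=ClassifierSpec("svm_rbf"))
print(f"A-MCFS framework:          accuracy {fw.metrics.accuracy:5.2f}%  MCC {fw.metrics.mcc:.4f}")
# With signal confined to 3 of 26 tests, pooling (LOSO) and summarising
# (s-LOO) dilute it; the per-test framework isolates it.
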