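"""Compare the predictive-interval detector with the three per-gene t-tests
on one simulated dataset where treatment and control differ in variance
(delta=0, gamma=3): the regime where per-gene tests struggle.
"""

from predex import (
    ScenarioConfig,
    compute_treatment_effects,
    pa_detect,
    score_calls,
    simulate_dataset,
)
from predex.baselines import BASELINE_MATRIX_TESTS

cfg = ScenarioConfig(n=1000, delta=0.0, gamma=3.0, seed=7)
labeled = simulate_dataset(cfg, 0)

calls = {"pa": pa_detect(compute_treatment_effects(labeled.data)).called}
for name, test in BASELINE_MATRIX_TESTS.items():
    _, _, p = test(labeled.data.control, labeled.data.treatment)
    calls[name] = p < 0.05

print("method   TPR    FPR    TDR")
for name, c in calls.items():
    m = score_calls(labeled.truth, c)
    tdr = "  n/a" if m.tdr is None else f"{m.tdr:.3f}"
    print(f"{name:6s}  {m.tpr:.3f}  {m.fpr:.3f}  {tdr}")
# The differential genes here have the same mean as control but 3x the
# s.d., which widens the spread of their mean effects: the predictive
# criterion catches many of them, the per-gene t-tests almost none.
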