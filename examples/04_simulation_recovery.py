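"""Operating characteristics of the estimators on ground-truth data.

Draws replicate two-sample datasets under three pleiotropy scenarios and
scores IVW, weighted median and the Egger slope: bias, empirical SE, RMSE,
95% CI coverage, and the Egger intercept test's rejection rate.
"""

import mr2s
from mr2s.simulate import SimulationConfig

scenarios = [
    SimulationConfig(true_effect=0.4, pleiotropy_mode="none"),
    SimulationConfig(true_effect=0.4, pleiotropy_mode="balanced",
                     pleiotropy_sd=0.008),
    SimulationConfig(true_effect=0.4, pleiotropy_mode="directional",
                     pleiotropy_mean=0.01, pleiotropy_sd=0.004),
]
table = mr2s.recovery_experiment(scenarios, n_reps=200, seed=1)

cols = ["pleiotropy_mode", "estimator", "bias", "empirical_se", "rmse",
        "coverage", "egger_intercept_rejection_rate"]
print(table[cols].round(4).to_string(index=False))

print(
    "\nReading: with no pleiotropy every estimator is nearly unbiased and"
    "\nCIs cover the truth at ~95%; balanced pleiotropy widens the spread"
    "\nwithout bias; directional pleiotropy biases IVW upward while the"
    "\nweighted median resists, and the intercept test's rejection rate"
    "\nrises above its ~5% null level."
)
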