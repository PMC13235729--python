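"""Fit the prognostic triplet score and stratify patients at the optimal
log-rank cutoff.

The score is coef_lnc*exp_lnc + coef_imm*exp_imm + coef_ssg*exp_ssg with
coefficients from a multivariate Cox fit; the cutoff maximizes the
two-group log-rank statistic subject to a minimum group size.
"""

import numpy as np
import pandas as pd

from regtriplets import ExpressionCohort, fit_triplet_score, optimal_cutoff_stratify
from regtriplets.synth import generate_survival

rng = np.random.default_rng(44)
n = 400
expr = {g: rng.standard_normal(n) for g in ("lnc", "imm", "ssg")}
planted = 0.8 * expr["lnc"] + 0.5 * expr["imm"] - 0.6 * expr["ssg"]
time, event = generate_survival(planted, baseline=0.3, effect=1.0, seed=44,
                                censor_horizon=40.0)

samples = [f"s{i}" for i in range(n)]
cohort = ExpressionCohort(
    pd.DataFrame(expr, index=samples).T,
    pd.Series({"lnc": "lncRNA", "imm": "immune", "ssg": "SSG"}),
    survival=pd.DataFrame({"time": time, "event": event}, index=samples),
)

model = fit_triplet_score(cohort, ("lnc", "imm", "ssg"))
print(f"Cox coefficients: lnc={model.coef_lnc:.2f} imm={model.coef_imm:.2f} "
      f"ssg={model.coef_ssg:.2f}")
cutoff, high, low, p = optimal_cutoff_stratify(model.scores, cohort.survival)
print(f"optimal cutoff {cutoff:.3f}: {len(high)} high-score vs {len(low)} "
      f"low-score patients, log-rank p = {p:.2e}")
# The fitted coefficients approximate the planted log-hazard weights
# (0.8, 0.5, -0.6) and the high-score group has markedly worse survival.
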