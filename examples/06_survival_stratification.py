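"""Stratify survival by prediction score at a fixed 0.5 threshold.

Prediction scores in [0, 1] are split into High (> 0.5) and Low groups;
Kaplan-Meier curves and a log-rank test quantify the separation.  Here
survival times are simulated with a hazard ratio of 3 against the
high-score group being low-risk, so the split should be clearly
significant.
"""

import numpy as np
import pandas as pd

from tmepredict import SurvivalData, km_logrank_stratify

rng = np.random.default_rng(8)
n = 200
samples = [f"s{i}" for i in range(n)]
scores = pd.Series(rng.uniform(0, 1, n), index=samples)

hazard = np.where(scores > 0.5, 0.5, 1.5)  # high score = low risk
event_time = rng.exponential(1.0 / hazard)
censor_time = rng.exponential(4.0, n)
surv = SurvivalData(
    times=pd.Series(np.minimum(event_time, censor_time) + 1e-9, index=samples),
    events=pd.Series((event_time <= censor_time).astype(int), index=samples),
)

groups, p, curves = km_logrank_stratify(scores, surv, threshold=0.5)
print(f"High-score group: {(groups == 'High').sum()} samples")
print(f"Low-score group:  {(groups == 'Low').sum()} samples")
print(f"log-rank P:       {p:.2e}")
for name, curve in curves.items():
    median = curve[curve[name] <= 0.5].index.min()
    print(f"median survival ({name}): {median:.2f}")
print(
    "\nA log-rank P ≤ 0.05 with longer median survival in the High group "
    "means the score separates risk at the fixed 0.5 cut."
)
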