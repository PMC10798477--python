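"""Simulate the working-memory generation model.

An agent proposes alternations with bias theta, judges candidate elements
by the complexity of its memory window, and fatigues over time -- faster
when its past output is not displayed (invisible condition).
"""

import numpy as np

from humanrand import ModelParams, generate_series, load_ctm_table
from humanrand.complexity import rolling_complexity

table = load_ctm_table()

for condition in ("visible", "invisible"):
    profiles = []
    for seed in range(60):
        params = ModelParams(
            wm_capacity_k=7,
            judgment_accuracy_p0=0.95,
            fatigue_rate_lambda=0.03,
            storage_load_kappa=1.5,
            condition=condition,
            seed=seed,
        )
        series = generate_series(params, table)
        profiles.append(rolling_complexity(series, 7, table).values)
    mean = np.mean(profiles, axis=0)
    print(
        f"{condition:>10s}: first-30-window mean {mean[:30].mean():.3f}, "
        f"last-30-window mean {mean[-30:].mean():.3f}"
    )

print(
    "\nBoth conditions start equally random and decline with fatigue;"
    "\nthe invisible condition declines faster early on because holding"
    "\npast choices in memory competes with the complexity judgment."
)
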