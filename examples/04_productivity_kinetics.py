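"""Specific productivity q_P and per-day condition comparison.

Simulates two 10-day cultivations (logistic growth, product formation
starting between day 3 and 4), computes the biomass-specific productivity
q_P = (1/X)·dP/dt, and runs a per-day one-way ANOVA on replicate q_P values
to ask on which days the conditions differ significantly.
"""

import numpy as np
import pandas as pd

import pelletmetrics as pm
from pelletmetrics.synthetic import CultivationGenParams

rows = []
for cond, pmax, rate in [("control", 38.0, 0.8), ("beads", 95.0, 1.2)]:
    for rep in range(3):
        params = CultivationGenParams(P_max=pmax, production_rate=rate,
                                      noise_sd_P=1.0, seed=17 + rep)
        series = pm.generate_cultivation_series(params, condition=cond)
        qp = pm.specific_productivity(series)
        for t, v in zip(series.t_days, qp):
            rows.append({"day": t, "condition": cond, "value": v})
        if rep == 0:
            peak_day = series.t_days[np.nanargmax(qp)]
            print(f"{cond:8s} final P {series.P_mg_per_L[-1]:5.1f} mg/L, "
                  f"peak qP {np.nanmax(qp):.1f} mg g^-1 d^-1 on day {peak_day:.0f}")

anova = pm.compare_conditions_per_day(pd.DataFrame(rows))
sig_days = anova.loc[anova.significant, "day"].tolist()
print(f"days with significant qP difference (alpha=0.05): {sig_days}")
# q_P isolates the product formation rate per unit biomass, so a higher
# titer with equal growth shows up directly as elevated q_P in mid-culture.
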