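"""Randomized-complete-block ANOVA with planned control contrasts.

Builds a balanced 3-cycle x 4-dose x 2-sex response table with a known dose
effect, fits the block ANOVA and reports LSMeans, SEM, the interaction gate
and each dose's planned contrast against the control.
"""

import numpy as np
import pandas as pd

from penflux import interaction_gate, rcbd_fit

rng = np.random.default_rng(0)
doses = (0.0, 1.38, 5.5, 22.0)
true_effect = {0.0: 22.3, 1.38: 19.5, 5.5: 18.7, 22.0: 18.5}

rows = []
for cycle in (1, 2, 3):
    cycle_shift = rng.normal(0, 2.0)  # seasonal block effect
    for dose in doses:
        for sex in ("steer", "heifer"):
            rows.append(
                {"cycle": cycle, "dose": dose, "sex": sex,
                 "value": true_effect[dose] + cycle_shift + rng.normal(0, 1.5)}
            )
table = pd.DataFrame(rows)

res = rcbd_fit(table)
print("LSMeans by dose (SEM = {:.2f}):".format(res.sem_dose))
print(res.lsmeans_dose.round(2))
print(f"\ndose p = {res.dose_p:.4f}, sex p = {res.sex_p:.3f}, "
      f"dose x sex p = {res.interaction_p:.3f}")

gate = interaction_gate(res)
print(f"\ninteraction gate: report {gate.route} contrasts")
print(gate.contrasts.round(4))
# With no interaction the contrasts compare pooled dose means with control
# on 14 residual df; p < 0.05 marks a dose as different from control.
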