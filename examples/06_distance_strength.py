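"""Bootstrapped distance-strength model: do groups differ in slope/intercept?

Edge strength decays with Euclidean edge distance; a steeper planted decay in
the older group must surface as a negative, significant group-by-distance
coefficient.  The model is refit by OLS on 20% subsamples of the pooled edge
population, and a coefficient is significant when 0 lies outside the central
95% of its bootstrap distribution.
"""

import numpy as np
import pandas as pd

import modbrain as mb

spec = mb.CohortSpec(
    group_sizes={"YA": 6, "OA": 6},
    distance_decay_slope={"YA": 0.0015, "OA": 0.0025},  # steeper decay in OA
    seed=2,
)
cohort = mb.generate_cohort(spec)
dist = cohort.embedding.pairwise_distance

tables = {"YA": [], "OA": []}
for p in cohort.participants:
    net = mb.local_threshold(p.connectome, 10.0)
    i, j = np.nonzero(np.triu(net.adjacency, 1))
    tables[p.group].append(pd.DataFrame({
        "strength": p.connectome.weights[i, j],
        "distance": dist[i, j],
        "age": p.age,
        "sex": 1.0 if p.sex == "F" else 0.0,
    }))

model = mb.distance_strength_fit(
    pd.concat(tables["YA"], ignore_index=True),
    pd.concat(tables["OA"], ignore_index=True),
    n_boot=1000, fraction=0.2, seed=0,
)

print("coefficient          mean        95% CI              significant")
for name in model.coef_names:
    lo, hi = model.ci95[name]
    print(f"{name:18s} {model.mean()[name]: .6f}  [{lo: .6f}, {hi: .6f}]  "
          f"{model.significance[name]}")

b3 = model.mean()["group_x_distance"]
print(f"\ngroup x distance = {b3:.6f} strength/mm: the OA group's strength "
      "falls faster with distance,")
print("recovering the planted slope difference of -0.001/mm in sign and "
      "significance.")
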