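"""PCA compression and evidence-based choice of the network width.

The 19 features are highly redundant: the first three principal
components carry essentially all the variance, so the classifier works
in 3 dimensions.  The hidden-layer width h of the 3-h-1 network is then
chosen by maximising the Laplace-approximation log evidence — wider
networks fit no better but pay an Occam penalty.

Run:  python examples/03_model_selection.py
"""

import numpy as np

from woundtherm import (
    FEATURE_NAMES,
    cumulative_variance,
    extract_feature_table,
    fit_pca,
    generate_cohort,
    project,
    select_architecture,
)

cohort = generate_cohort(n_unhealed=30, n_healed=15, seed=3)
table = extract_feature_table(cohort)
X = table[list(FEATURE_NAMES)].to_numpy(dtype=float)
t = (table["label"] == "unhealed").to_numpy(dtype=float)

model = fit_pca(X, k_selected=3)
cum = cumulative_variance(model)
print("cumulative explained variance:",
      " ".join(f"{v:.4%}" for v in cum[:4]))

scores = project(model, X, 3)
h, net, evidences = select_architecture(scores, t, h_range=range(1, 10),
                                        restarts=3, seed=0)
print("\n  h   log evidence   gamma")
for r in evidences:
    marker = "  <-- selected" if r.h == h else ""
    print(f"  {r.h}   {r.log_evidence:12.3f}   {r.gamma:5.2f}{marker}")
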