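"""Cell-type clustering with feature screening, AIC/BIC and dip tests.

Simulates seven well-separated archetypes, extracts the candidate features
(P2T, CV, CV2, Lv, FR, FF, AUROC), screens them to >= 90% explained
variance, sweeps Gaussian mixtures over k = 2..12 and reports cluster
composition and waveform-width unimodality.
"""

import pandas as pd
from sklearn.metrics import adjusted_rand_score

from fefattn import TaskDesign, cluster_cells, separable_population, simulate_population
from fefattn.attention import attention_result
from fefattn.metrics import cell_metrics

design = TaskDesign(n_trials_per_condition=30, drug_states=("off",))
cells, truth = simulate_population(separable_population(), 15, design, seed=2)

rows = []
for c in cells:
    m = cell_metrics(c)
    m["auroc"] = attention_result(c)["auroc_nodrug"]
    rows.append(m)
features = pd.DataFrame(rows)

model = cluster_cells(
    features[["p2t_us", "cv", "cv2", "lv", "fr", "ff", "auroc"]],
    features["cell_id"].tolist(),
    restarts=50, seed=5, n_boot=500,
)

print(f"screened features: {model.selected_features} "
      f"({model.explained_fraction:.1%} of variance)")
print(f"cluster count: AIC -> {model.k_aic}, BIC -> {model.k_bic}, used {model.k_used}")
print(f"adjusted Rand vs planted truth: "
      f"{adjusted_rand_score(truth, model.assignments):.3f}")
print("\nper-cluster composition (narrow = P2T <= 250 us):")
cols = ["label", "n", "n_narrow", "n_broad", "minority_fraction"]
print(model.composition[cols].to_string(index=False))
print("\nwaveform-width dip test (FDR-adjusted):")
print(model.dip_results[["cluster", "n", "dip", "p_fdr"]].round(4).to_string(index=False))
# A significant adjusted p would indicate a cluster whose waveform widths
# are bimodal, i.e. a mix of physiologically distinct narrow/broad cells.
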