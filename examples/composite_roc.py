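"""Effect-size-weighted composite score and ROC discrimination.

Selects the FDR-significant inter-network features for SCZ vs CON at the
1-back load, weights each subject's feature values by |d|, and evaluates
patient-vs-control discrimination with the rank AUC and Youden threshold.
"""

import cereconn as cc

config = cc.CohortConfig(seed=21)
features = cc.generate_feature_tables(config)
contrasts = cc.run_contrasts(
    features, cc.network_feature_columns(cc.NETWORKS), [("SCZ", "CON")]
)

model = cc.fit_composite(contrasts, contrast="SCZ:CON", condition="1-back")
print("composite features:", dict(zip(model.features, model.weights.round(3))))

sub = features[(features["condition"] == "1-back")
               & (features["group"].isin(["SCZ", "CON"]))]
scores = cc.score(model, sub)
labels = (sub["group"] == "SCZ").astype(int).to_numpy()
result = cc.roc(scores.to_numpy(), labels, n_boot=2000, seed=0)

print(f"AUC = {result.auc:.3f} (95% CI {result.auc_ci[0]:.2f}-{result.auc_ci[1]:.2f})")
print(f"Youden threshold: sensitivity {result.sensitivity:.2f}, "
      f"specificity {result.specificity:.2f}")
# Patients score lower (hypoconnectivity), so the orientation flag is set
# and AUC is reported above 0.5.  At these group sizes (23 vs 20) the
# single-cohort estimate is noisy; the planted-weight expectation over many
# cohorts is about 0.89 (see scripts/acceptance.py).
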