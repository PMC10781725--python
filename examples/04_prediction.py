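"""Leave-one-study-out biomarker prediction from meta-analysis DEGs.

Five studies with a strong planted signature: expression is standardized per
gene within each study (no leakage across the held-out boundary), an
elastic-net classifier is tuned by nested CV on the four training studies,
and accuracy is assessed on the held-out fifth; the mean over the five
rotations is the headline figure.
"""

from psymeta import (
    PredictionConfig,
    SimulationConfig,
    generate_expression_study,
    loso_cv,
    make_ground_truth,
    standardize_per_gene,
    top_features,
)

cfg = SimulationConfig(
    n_genes=50, n_studies_b=5, n_shared_deg=10, n_private_deg_a=0, n_private_deg_b=0,
    samples_per_arm=10, effect_size=2.0, noise_sd=1.0, seed=9,
)
truth = make_ground_truth(cfg)
studies = [generate_expression_study(cfg, "B", i, truth)[0] for i in range(5)]

# features = the "meta-analysis DEGs" (here the planted truth stands in)
X, y, study_ids, names = standardize_per_gene(studies, list(truth.genes))
pcfg = PredictionConfig(
    model="elastic_net", alpha_grid=[0.0, 0.5, 1.0], lambda_grid=[1e-3, 1e-2, 1e-1],
    inner_folds=3, seed=9,
)
report = loso_cv(X, y, study_ids, pcfg, feature_names=names)

for sid, acc in zip(report.study_ids, report.accuracies):
    print(f"held-out {sid}: accuracy {acc:.2f}")
print(f"mean LOSO accuracy: {report.mean_accuracy:.3f}")
top = top_features(report, 10)
recovered = len(set(top) & set(truth.shared_genes))
print(f"planted genes in the top-10 coefficient ranking: {recovered}/10")
# Accuracies near 1.0 reflect the strong planted effect (2.0 log2 units);
# the ranking check shows the final pooled fit concentrates its nonzero
# coefficients on the genes that actually carry the signal.
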