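"""The full staged experiment on synthetic cell images.

Generates 30 cells per class, extracts features, holds out a stratified 30%
test set, and compares the fuzzy C-means classifier trained on all features
against one trained on the swarm-selected subset.  Prints the headline
metrics of both models, including the normal-vs-cancerous collapse.
"""

from cytoswarm.evaluation import ExperimentConfig, run_experiment
from cytoswarm.fcm import FCMConfig
from cytoswarm.features import feature_table, grouped_from_table
from cytoswarm.synthetic import GeneratorConfig, generate_dataset

cells, _ = generate_dataset(GeneratorConfig(counts_per_class=(30,) * 7, seed=1))
df = feature_table(cells)
gf, labels = grouped_from_table(df)

report = run_experiment(gf, labels, ExperimentConfig(seed=1, fcm=FCMConfig(seed=1)))

for key, title in [("without_selection", "all 14 feature groups"),
                   ("with_selection", "swarm-selected subset")]:
    r = report[key]
    print(f"{title}:")
    print(f"  7-class accuracy {r['accuracy']:.3f}   macro-F1 {r['macro_f1']:.3f}"
          f"   kappa {r['kappa']:.3f}   membership MSE {r['mse']:.4f}")
    b = r["binary"]
    print(f"  normal-vs-cancerous: accuracy {b['accuracy']:.3f} "
          f"sensitivity {b['sensitivity']:.3f} specificity {b['specificity']:.3f}")
print(f"selected groups: {', '.join(report['selected_groups'])}")

# Feature selection typically raises macro-F1 substantially here: the BHF
# block alone contributes 38 standardized columns, so unselected Euclidean
# distances are dominated by texture and the morphometric signal is diluted.
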