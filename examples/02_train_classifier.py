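"""Train the 1D CNN emotion classifier and evaluate it held-out.

Uses a reduced dataset (600 records) and a 3-fold cross-validation so
the example finishes in under a minute; the full-scale run (1200→5000
records, 5 folds, depth-5/kernel-7 network) is what
scripts/acceptance.py executes.
"""

from emocomp import datagen, odcnn

records = datagen.generate_dataset(
    datagen.GeneratorConfig(n_base=600, n_augmented=600, seed=0))
X, y = datagen.to_feature_matrix(records)

config = odcnn.ODCNNConfig(depth=3, kernel_size=5, learning_rate=0.001,
                           filters_per_layer=8, epochs=40, seed=0)
report = odcnn.cross_validate(X, y, config, k=3)

print(f"pooled 3-fold accuracy: {report.accuracy:.4f} "
      f"({report.misclassified} of {report.n} misclassified)")
print(f"macro one-vs-rest AUC:  {report.macro_auc:.4f}")
print("confusion matrix (rows = true neutral/happy/excited/angry):")
print(report.confusion)
print("high accuracy reflects the constructed separability of the "
      "synthetic classes (e.g. GSR 6.19±0.05 vs 4.95±0.07)")
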