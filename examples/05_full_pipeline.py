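"""Run the whole pipeline — generate, classify, aggregate, SOM, report.

Uses reduced sizes (300 base records augmented to 900, 3 folds, a small
network) so it finishes in about a minute; artifacts and a hash manifest
land in ./scratch/pipeline_demo.
"""

from emocomp import datagen, odcnn, pipeline, som

config = pipeline.PipelineConfig(
    generator=datagen.GeneratorConfig(n_base=300, n_augmented=900, seed=0),
    odcnn=odcnn.ODCNNConfig(depth=3, kernel_size=5, filters_per_layer=8,
                            mlp_hidden=(16,), epochs=30, learning_rate=0.001),
    som=som.SOMConfig(rows=6, cols=6, n_iter=5000),
    folds=3,
    seed=2024,
)

rundir = pipeline.run_pipeline(config, "scratch/pipeline_demo")
print(f"artifacts in {rundir}:")
for p in sorted(rundir.iterdir()):
    print("  ", p.name)

import json
report = json.loads((rundir / "training_report.json").read_text())
print(f"cross-validated accuracy {report['accuracy']:.4f}, "
      f"macro AUC {report['macro_auc']:.4f}")
print("report.csv lists each organization's emotion profile, SOM cluster "
      "and competitiveness category; rerunning with the same seed "
      "reproduces identical manifest hashes")
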