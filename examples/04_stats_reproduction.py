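"""Reproduce the study's descriptive statistics on generated data.

Runs the one-way ANOVA of every continuous feature across the four
emotion groups (the published pattern: physiological and affect features
strongly significant, BMI not) and reprints the angry-class correlation
table next to its published targets.
"""

from emocomp import datagen, evalstats

records = datagen.generate_dataset(datagen.GeneratorConfig(seed=0))

print("one-way ANOVA across emotion groups (n=1200):")
print(evalstats.anova_table(records).to_string(index=False,
                                               float_format=lambda x: f"{x:.3g}"))

print("\nangry-class Pearson correlations (sample vs published):")
table = evalstats.correlation_table(records, "angry")
published = datagen.CLASS_CORRELATIONS["angry"]
table["published"] = [published.get((a, b), published.get((b, a)))
                      for a, b in zip(table.feature_a, table.feature_b)]
print(table[["feature_a", "feature_b", "r", "published"]].to_string(
    index=False, float_format=lambda x: f"{x:+.2f}"))
print("\nsample r at n=236 fluctuates around the published values; "
      "at n=20000 it converges to within ±0.05 (see the test-suite)")
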