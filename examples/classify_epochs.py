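"""Train and evaluate the k-NN classifier on a synthetic feature template.

Generates a 20-subject training template and a matched test template
(10 epileptic + 10 normal each), then sweeps k, the four distance measures
and three decision rules, printing the accuracy grid — the same evaluation
structure used for clinical templates.
"""

import dataclasses

from seizurekit import EpochSpec, KnnConfig, accuracy_grid, evaluate, generate_template

base = EpochSpec(noise_sd=0.3)
specs = {
    "epileptic": dataclasses.replace(base, kind="epileptic"),
    "normal": dataclasses.replace(base, kind="normal"),
}
train = generate_template(10, specs, seed=0)
test = generate_template(10, specs, seed=1000)

cm = evaluate(train, test, KnnConfig(k=3, metric="euclidean", rule="nearest_neighbour"))
print("confusion matrix (k=3, euclidean, nearest neighbour):")
print(cm, "\n")

grid = accuracy_grid(train, test, ks=(1, 2, 3), seed=0)
pivot = grid.pivot_table(index="metric", columns=["rule", "k"], values="accuracy")
print("accuracy over the k / metric / rule grid:")
print(pivot.round(2))
print("\nEach cell is the fraction of the 20 test epochs labeled correctly.")
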