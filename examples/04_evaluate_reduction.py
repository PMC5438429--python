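"""Does the reduced representation classify as well as the full one?

Builds tasks whose full matrices are dominated by noise bits, reduces
each to its planted informative bits, scores both representations with
a cross-validated random forest, and compares the paired MCC values with
a one-sided Wilcoxon signed-rank test (alternative: reduced >= raw).
"""

from aicmax import RandomForestLearner, compare_representations
from aicmax.synthetic import PlantedBit, SyntheticSpec, generate

tasks, subsets = [], {}
for i in range(6):
    spec = SyntheticSpec(
        n_active=150,
        n_inactive=150,
        planted_bits=[PlantedBit(b, 0.75, 0.25) for b in range(8)],
        n_noise_bits=800,
        p_noise=0.1,
        seed=100 + i,
    )
    (task,), _ = generate(spec)
    task.task_id = f"task{i}"
    tasks.append(task)
    subsets[task.task_id] = list(range(8))  # the reduced representation

report = compare_representations(
    tasks, subsets,
    learner=RandomForestLearner(n_estimators=64, random_state=0),
    folds=5, seed=0,
)

print("task    MCC raw  MCC reduced  sign")
for task_id, raw, red, sign in report.per_task:
    print(f"{task_id:>6}  {raw:7.3f}  {red:11.3f}  {sign:>4}")
print()
print(f"improved {report.n_improved}, worse {report.n_worse}, no change {report.n_nc}")
print(f"Wilcoxon one-sided (reduced >= raw): W = {report.wilcoxon_statistic}, "
      f"p = {report.wilcoxon_p:.4f}")
print()
print("A small p supports the reduced representation: stripping the 800 noise")
print("bits removed dilution without losing the activity-determining signal.")
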