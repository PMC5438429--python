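"""Score fingerprint bits by normalized mutual information with activity.

Builds a small synthetic task with one strongly informative planted bit,
one weak one and pure-noise background, then ranks every bit singly.
"""

from aicmax import rank_bits_individual, aic_score
from aicmax.synthetic import PlantedBit, SyntheticSpec, closed_form_singleton_aic, generate

spec = SyntheticSpec(
    n_active=400,
    n_inactive=400,
    planted_bits=[PlantedBit(0, 0.85, 0.15), PlantedBit(1, 0.55, 0.40)],
    n_noise_bits=10,
    p_noise=0.2,
    seed=7,
)
(task,), manifest = generate(spec)

print("bit  score   (empirical normalized MI with the activity label)")
for bit_id, score in rank_bits_individual(task)[:5]:
    print(f"{bit_id:>3}  {score:.4f}")

print()
print("planted bit 0: closed-form population score",
      f"{closed_form_singleton_aic(0.85, 0.15, 0.5):.4f}")
print("pair {0, 1} scored jointly:",
      f"{aic_score(task.matrix, [0, 1], task.labels):.4f}")
print()
print("A score of 1 would mean the bits determine activity exactly; 0 means")
print("independence. The strong planted bit dominates, noise bits sit near 0,")
print("and the pair scores above either single bit.")
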