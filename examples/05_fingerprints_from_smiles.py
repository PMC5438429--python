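"""Compute structure-key fingerprints from SMILES and label by potency.

Uses a small curated dictionary of pharmacophore SMARTS fragments on a
handful of serotonergic-style molecules, then thresholds a toy potency
table into actives (Ki <= 100 nM) and inactives (Ki > 1000 nM).
"""

from aicmax import ActivityRecord, compute_krfp, labeled_dataset_from_split, split_activity
from aicmax.keys import demo_pharmacophore_keys

molecules = [
    ("buspirone_like", "O=C1CCC(=O)N1CCCCN1CCN(c2ncccn2)CC1"),
    ("arylpiperazine", "c1ccc(N2CCNCC2)cc1"),
    ("phenol_amine", "NCCc1ccc(O)cc1"),
    ("plain_alkane", "CCCCCCCC"),
]
keys = demo_pharmacophore_keys()
matrix = compute_krfp(molecules, keys)

print(f"{matrix.n_compounds} molecules x {matrix.n_bits} substructure keys")
for cid, row in zip(matrix.compound_ids, matrix.values):
    on = [keys[j][1] for j in range(len(keys)) if row[j]]
    print(f"  {cid:>15}: {int(row.sum())} keys on  e.g. {on[:3]}")

records = [
    ActivityRecord("buspirone_like", "5HT1A", 20.0),
    ActivityRecord("arylpiperazine", "5HT1A", 95.0),
    ActivityRecord("phenol_amine", "5HT1A", 450.0),
    ActivityRecord("plain_alkane", "5HT1A", 90000.0),
]
split = split_activity(records, "5HT1A")
print("\npotency split (active <= 100 nM, inactive > 1000 nM, else discarded):")
for compound, status in split.items():
    print(f"  {compound:>15}: {status}")

task = labeled_dataset_from_split(matrix, split, task_id="5HT1A")
print(f"\nclassification task: {task.n_samples} compounds, "
      f"{int(task.labels.sum())} active / {int((1 - task.labels).sum())} inactive")
print("(the 450 nM compound falls in the grey zone and is excluded)")
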