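"""Benchmark per-residue disorder predictors against the consensus.

Three synthetic predictors with different error profiles (precise,
balanced, sensitive) are scored against the majority consensus of a
simulated ensemble.  Counts are pooled over all residues of all proteins
(unknown consensus positions are excluded) and methods are ranked by
Matthews correlation coefficient.
"""

import ldrkit as lk
from ldrkit.synthetic_data import SimConfig, generate

ds = generate(SimConfig(seed=42))
stacks = lk.build_stacks(ds.observations, ds.segments, ds.sequences)
references = {pid: lk.majority_consensus(stack)
              for pid, stack in stacks.items()}

table = lk.benchmark(ds.predictions, references)
cols = ["method", "mcc", "f1", "accuracy", "precision", "specificity",
        "recall"]
print(table[cols].round(3).to_string(index=False))

# The 'precise' profile rarely calls order disordered (high precision and
# specificity) but misses most disordered residues (low recall) - the
# signature that real missing-residue-trained predictors show on long
# disordered regions.  Ranking by MCC balances both error types.
n = int(table.iloc[0][["tp", "fp", "tn", "fn"]].sum())
print(f"\n{n} consensus-resolved residues evaluated per method")
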