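"""Majority vs zero consensus on a hand-built five-chain protein.

Five crystal structures of the same 120-residue protein disagree about
the N-terminal region: it is missing in all five chains for the first 35
residues, missing in only three of five for the next 25, and modeled
everywhere after that.  One chain was crystallized from a truncated
construct, so the last 20 residues are uncovered.
"""

import numpy as np

import ldrkit as lk

L = 120
rows = []
for i in range(5):
    head = "M" * 35                                # missing in every chain
    mid = "M" * 25 if i < 3 else "O" * 25          # missing in 3 of 5
    tail = "O" * 60
    rows.append(head + mid + tail)
# chain 4 comes from a truncated construct: last 20 residues not covered
rows[4] = rows[4][:100] + "N" * 20

stack = lk.ProteinTrackStack(
    protein_id="DEMO1",
    sequence="A" * L,
    tracks=np.array([list(r) for r in rows], dtype="U1"),
    track_ids=[(f"PDB_{i + 1}", "A") for i in range(5)],
)

majority = lk.majority_consensus(stack)
zero = lk.zero_consensus(stack)

print("positions   1-35: majority", majority.states[0], "zero", zero.states[0])
print("positions  36-60: majority", majority.states[40], "zero", zero.states[40])
print("positions 61-120: majority", majority.states[80], "zero", zero.states[80])

maj_regions = lk.extract_regions(majority)
zero_regions = lk.extract_regions(zero)
print("\nmajority regions:", [(r.start, r.end, r.region_class)
                              for r in maj_regions])
print("zero regions:    ", [(r.start, r.end, r.region_class)
                            for r in zero_regions])

for cmp_ in lk.consensus_difference(maj_regions, zero):
    r = cmp_.majority_region
    print(f"\nmajority LDR {r.start}-{r.end}: confirmed by zero rule ="
          f" {cmp_.confirmed}")
    for d in cmp_.differences:
        print(f"  difference interval {d.start}-{d.end} "
              f"(disordered in >50% of chains but ordered in at least one:"
              f" a candidate context-dependent segment)")

# The majority rule calls residues 1-60 one 60-residue LDR; the stricter
# zero rule keeps only 1-35, because two chains model residues 36-60.
# The 36-60 difference interval is exactly the mixture of disorder and
# structure that folding-upon-binding regions produce.
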