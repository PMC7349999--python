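"""Generate a synthetic ensemble and build the dataset-composition table.

Runs the full consensus pipeline (chains -> protein stacks -> majority
consensus -> regions -> protein classes) on 50 simulated proteins and
prints the composition table, the LDR-count distribution, region
localization and the amino-acid enrichment of disordered regions.
"""

import ldrkit as lk
from ldrkit.region_stats import (
    aa_enrichment,
    count_regions_per_protein,
    length_histogram,
    localize_region,
    summarize_dataset,
)
from ldrkit.synthetic_data import SimConfig, generate

ds = generate(SimConfig(seed=42))
stacks = lk.build_stacks(ds.observations, ds.segments, ds.sequences)

tracks, regions, classes = {}, [], []
for pid, stack in stacks.items():
    track = lk.majority_consensus(stack)
    tracks[pid] = track
    regs = lk.extract_regions(track)
    regions += regs
    classes.append(lk.classify_protein(regs, track))

print("dataset composition (rows: protein category):")
print(summarize_dataset(classes, tracks, regions).to_string())
# 'missing' counts consensus-disordered residues, 'unknown' the residues
# never covered by any simulated construct.

print("\nLDRs per protein (most proteins carry exactly one):")
print(count_regions_per_protein(regions).to_string(index=False))

print("\nLDR length histogram (bins of 10 residues from 30):")
print(length_histogram(regions).head(6).to_string(index=False))

ldrs = [r for r in regions if r.region_class == "LDR"]
labels = [localize_region(r, tracks[r.protein_id].length) for r in ldrs]
print("\nLDR localization:",
      {lab: labels.count(lab) for lab in ("N-terminal", "C-terminal",
                                          "middle", "full")})

region_seqs = [ds.sequences[r.protein_id][r.start - 1:r.end] for r in ldrs]
background = list(ds.sequences.values())
enr = aa_enrichment(region_seqs, background).sort_values("fold")
print("\nmost depleted / enriched amino acids in LDRs (fold vs background):")
print(enr.head(3).to_string(index=False))
print(enr.tail(3).to_string(index=False))
# Disordered regions are enriched in charged/hydrophilic residues (E, K,
# P, S) and depleted in hydrophobic/aromatic ones (W, C, F), mirroring
# the known compositional bias of intrinsic disorder.
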