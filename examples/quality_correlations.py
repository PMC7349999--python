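"""Do structure-quality metrics explain missing residues?

Correlates six standard validation metrics (resolution, R-free,
clashscore, Ramachandran / rotamer / RSRZ outliers) with each chain's
fraction of missing residues, first on an ensemble where quality is
independent of disorder, then on one with a planted resolution coupling.
"""

from ldrkit.quality_corr import correlate_quality, missing_fraction_per_chain
from ldrkit.synthetic_data import SimConfig, generate

null = generate(SimConfig(seed=42))
fracs = {o.structure_id: missing_fraction_per_chain(o)
         for o in null.observations}
print("quality independent of disorder (expected: r near 0):")
print(correlate_quality(null.quality, fracs).round(3).to_string(index=False))

signal = generate(SimConfig(seed=42, quality_resolution_coupling=3.0))
fracs = {o.structure_id: missing_fraction_per_chain(o)
         for o in signal.observations}
print("\nresolution generated as disorder fraction plus noise:")
rep = correlate_quality(signal.quality, fracs).round(3)
print(rep[rep.metric == "resolution"].to_string(index=False))
# Near-zero correlations in the first table are the pattern that supports
# reading long missing-residue regions as genuine structural features
# rather than artifacts of poor crystals; the second table shows the
# analysis does detect a coupling when one exists.
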