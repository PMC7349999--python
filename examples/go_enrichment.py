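"""Fisher-exact GO enrichment of LDR proteins against the full background.

Simulates 150 proteins of which ~25% carry a long disordered region; the
generator plants one GO term preferentially on the LDR proteins.  The
enrichment pipeline propagates annotations up the is_a graph, restricts
testing to ontology levels 1-4 and applies a per-namespace Bonferroni
correction.
"""

from ldrkit.enrichment import enrich, load_ontology
from ldrkit.synthetic_data import PLANTED_TERM, SimConfig, generate

ds = generate(SimConfig(n_proteins=150, p_ldr_protein=0.25,
                        n_chains_range=(3, 8), seed=5))
targets = ds.ldr_protein_ids()
background = list(ds.ground_truths)
print(f"target: {len(targets)} LDR proteins; "
      f"background: {len(background)} proteins")

ontology = load_ontology(ds.ontology_obo)
results = enrich(targets, background, ds.annotations, ontology)

cols = ["term", "namespace", "level", "a", "c", "fold", "p_bonferroni",
        "enriched"]
print(results[results.enriched][cols].to_string(index=False))
print(f"\nplanted term: {PLANTED_TERM}")
# 'a' of the planted term counts target proteins carrying it, 'c' the
# background-only carriers; the corrected p-value stays far below 0.05,
# so the planted functional signal survives multiple testing.  Its is_a
# parent is flagged too - annotation propagation makes ancestors of an
# enriched term enriched as well.
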