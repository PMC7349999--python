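# ldrkit

Protein-level detection and analysis of **long intrinsically disordered
regions (LDRs)** from missing residues in X-ray crystal structures.

Residues present in a chain's SEQRES but absent from the deposited model
(poor or no electron density) are the classic experimental proxy for
intrinsic disorder.  Different crystal structures of the same protein
disagree, so `ldrkit` combines all mapped chains of a protein into a
per-residue consensus: with `c` chains covering a position and `m` of
them missing it,

- **majority rule**: disordered iff `m / c > 0.5` (strict),
- **zero rule**: disordered iff `m = c`,
- positions covered by no chain are **unknown** and excluded from every
  decision.

Maximal disordered runs of ≥ 30 residues are LDRs (5–29: SDRs).
Subtracting the zero from the majority consensus exposes segments that
are disordered in most chains but ordered in at least one — candidate
folding-upon-binding regions.  Around the consensus core the package
provides dataset statistics (disorder content, region lengths,
localization, amino-acid enrichment), per-residue benchmarking of
disorder predictors (MCC, F1, BAC, precision, specificity, recall,
pooled over residues), Fisher-exact GO-term enrichment (levels 1–4,
per-namespace Bonferroni) and correlation of structure-quality metrics
with disorder content.  A synthetic-data generator emits every input
format the pipeline reads — PDB (SEQRES + REMARK 465), mmCIF, mapping
TSV, FASTA, prediction TSV, quality CSV, OBO + GAF — with known ground
truth, so the whole pipeline is testable without downloads.

Intended users: structural bioinformaticians building disorder datasets
from the PDB, and developers of disorder predictors who need a
reproducible per-residue reference.

## Worked example

Five crystal structures of one 120-residue protein: residues 1–35 are
missing in all five chains, 36–60 in three of five, the rest is modeled;
one chain's construct stops at residue 100
(`examples/consensus_two_rules.py`):

```text
positions   1-35: majority D zero D
positions  36-60: majority D zero S
positions 61-120: majority S zero S

majority regions: [(1, 60, 'LDR')]
zero regions:     [(1, 35, 'LDR')]

majority LDR 1-60: confirmed by zero rule = True
  difference interval 36-60 (disordered in >50% of chains but ordered in
  at least one: a candidate context-dependent segment)
```

The permissive majority rule calls one 60-residue LDR; the conservative
zero rule keeps only the stretch missing in *every* chain (1–35), which
also confirms the majority region.  The 36–60 difference interval is the
mixture of disorder and structure that context-dependent regions
produce.

A full pipeline run on a simulated ensemble (50 proteins, 15 chains
each; `examples/synthetic_dataset_summary.py`) prints the
dataset-composition table:

```text
             proteins  median_length  sdr  ldr  missing  observed  unknown  missing_pct ...
LDR-protein        47          341.0   10   54     3045      9035     4211         18.7
SDR-protein         1          306.0    1    0        5       144      157          1.6
structured          2          195.5    0    0        0       228      163          0.0
total              50          330.0   11   54     3050      9407     4531         18.0
```

where `missing` counts consensus-disordered residues, `observed`
structured ones and `unknown` residues never covered by any construct.
Further examples cover predictor benchmarking
(`predictor_benchmark.py`), GO enrichment with a planted term
(`go_enrichment.py`), quality-metric correlations
(`quality_correlations.py`) and writing/re-ingesting a full fixture
bundle (`fixture_bundle_roundtrip.py`).

## Layout

```
src/ldrkit/
  ingest.py          PDB / mmCIF missing-residue parsing, chain->protein mapping
  consensus.py       majority & zero rules, regions, classes, consensus difference
  region_stats.py    dataset summaries, histograms, localization, composition
  predictor_eval.py  per-residue confusion counts, metrics, method ranking
  enrichment.py      OBO/GAF handling, Fisher tests, Bonferroni enrichment
  quality_corr.py    validation-metric correlations
  synthetic_data.py  ground-truth ensembles in every ingestible format
docs/methods.md      model, parameters, numerical choices, limitations
examples/            one narrative script per capability
tests/               pytest suite (unit, property and end-to-end checks)
```
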