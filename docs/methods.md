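# Methods

## Problem and model

X-ray crystal structures routinely leave residues unmodeled when the
local electron density is too poor to place atoms.  These *missing
residues* are the standard experimental proxy for intrinsic disorder.
Because many proteins are represented by several deposited chains —
different crystal forms, constructs and conditions — the per-chain
missing-residue signal is noisy and often contradictory.  `ldrkit`
aggregates it at the protein level.

Every deposited chain is treated as one independent vote.  A chain's
SEQRES positions carry a binary observation state (observed `O` /
missing `M`); SIFTS-style affine segment mappings project the chain
track onto protein coordinates, where positions outside the crystallized
construct become *not covered* (`N`).  Stacking all mapped chains of a
protein gives, per position, a coverage count `c` (chains with a non-`N`
cell) and a missing count `m`.  Two consensus rules convert votes into a
per-position call over `{D, S, U}`:

- **majority**: `D` iff `m / c > 0.5` (strict; an exact tie is `S`),
- **zero**: `D` iff `m = c` (missing in every covering chain),
- both: `U` iff `c = 0` (unknown — never crystallized).

Uncovered cells do not vote: the denominator is the number of covering
chains, not the number of chains of the protein.

Maximal runs of consecutive `D` — broken by `S` *and* by `U` — are
classified by length: **LDR** at ≥ 30 residues, **SDR** at 5–29, runs
under 5 discarded.  A protein is an LDR-protein if it has at least one
LDR, an SDR-protein if its longest region is an SDR, structured
otherwise; it is *fully disordered* when consensus `D` covers at least
70% of its length.  Subtracting the zero consensus from a majority LDR
yields the sub-intervals that are disordered in more than half of the
chains yet ordered in at least one — candidate folding-upon-binding or
context-dependent segments.  A majority LDR is *confirmed* by the zero
rule when a full zero-consensus LDR lies within its span.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `ldr_min_len` | 30 residues | minimum long-region length; filters the short gaps that low resolution or crystal handling produce |
| `sdr_min_len` | 5 residues | minimum region length recorded at all |
| `majority_fraction` | 0.5 (strict >) | vote threshold of the majority rule |
| `tail_fraction` | 0.2 | fraction of the sequence counted as an N-/C-terminal tail for localization (`ceil(0.2·L)` positions per end) |
| `fully_disordered_fraction` | 0.7 (≥) | disorder content defining a fully disordered protein |

## Downstream analyses

**Region statistics.** Disorder content is `missing / (missing +
observed + unknown)`, optionally dropping unknown residues from the
denominator.  Printed percentages use half-up rounding to one decimal.
Length histograms use 10-residue bins starting at `ldr_min_len`.
Localization labels a region `full` only when it covers every position;
a region touching both tails is assigned to the tail holding its larger
overlap, ties to N-terminal (the rule is deterministic where the
convention is genuinely open).  Amino-acid enrichment is the fold change
of region composition over a background sequence set, computed over the
20 standard residues; residues absent from the background get a missing
fold.

**Predictor evaluation.** Consensus `D` positions are positives, `S`
negatives, `U` excluded entirely.  Counts are pooled over all residues
of all proteins (micro-averaging — the metrics are per-residue, not
per-protein averages) before deriving accuracy, balanced accuracy, F1,
MCC, precision, specificity and recall.  Any metric with a zero
denominator is reported as 0 and flagged rather than dropped, keeping
benchmark tables rectangular.  When a prediction supplies only scores in
[0, 1], states are binarized at 0.5 (score ≥ 0.5 → disordered).

**GO enrichment.** One-sided (greater) Fisher exact tests on 2×2 tables
of target / background-only × with / without term.  Annotations are
closed under `is_a` propagation before counting, so ancestors of an
enriched term are typically enriched too.  Term *level* is the shortest
`is_a` path from the namespace root (roots at level 0); testing is
restricted to levels 1–4.  Bonferroni `m` counts the terms actually
tested within the same namespace — matching per-ontology reporting —
and a term is enriched when `min(1, p·m) < 0.05`.  Only `is_a` edges are
used; `part_of` is ignored as the conservative default.

**Quality correlations.** Per-structure validation metrics (resolution,
R-free, clashscore, Ramachandran / rotamer / RSRZ outlier rates) are
taken from a pre-computed CSV — they are published alongside structures
and recomputing them from coordinates is out of scope.  Each metric is
correlated (Pearson r, two-sided p from the t distribution with n−2 df)
against the per-chain missing fraction or region length; incomplete rows
are dropped pairwise, and metrics with fewer than 3 complete pairs are
flagged insufficient.  Where a per-structure disorder fraction is
needed for multi-chain entries, the mean of the chains' missing
fractions is used.

## Structure-file handling

PDB-format input uses SEQRES for chain length and REMARK 465 for
missing residues; author residue numbers in REMARK 465 are read as
1-based SEQRES positions, entries that cannot be resolved (unknown
chain, out of range) are skipped with a logged warning, and only the
first MODEL is considered.  mmCIF input takes chain lengths from
`_entity_poly_seq` + `_struct_asym` and missing residues from
`_pdbx_unobs_or_zero_occ_residues` (unobserved rows only — residues
modeled at zero occupancy are *not* counted as missing); when that
category is absent, every declared position without an `_atom_site` row
is marked missing.  Non-standard residues remain positions like any
other, so region lengths always match SEQRES.  Geometry, NMR and
cryo-EM models are out of scope.

## Synthetic data: what it emulates, and what it does not

The generator draws, per protein, a segment architecture over
disordered / structured / uncrystallized states, then simulates
independent chains: uncrystallized segments are excluded from every
construct (they surface as `U` in the consensus), construct termini are
randomly trimmed, and each covered position is missing with a
state-conditional probability.  Defaults are the package's reference
study conditions: 50 proteins of 150–500 residues, 15 chains per
protein, `p(miss | disordered) = 0.9`, `p(miss | structured) = 0.1`,
trimming of up to 10 residues with probability 0.3 per end,
uncrystallized tails of 30–120 residues with probability 0.7 per end
(giving roughly a quarter to a third unknown residues, the order of
magnitude real protein-level datasets show).  Most proteins carry one
long disordered segment; 12% carry two, mirroring the observed
distribution where a single LDR is the norm.  Disordered segments are
drawn from a disorder-promoting composition (enriched P/E/Q/S/K,
depleted W/C/F/Y) so compositional analyses behave realistically.
Per-protein random substreams are derived from `(seed, protein_index)`,
making datasets stable under changes of `n_proteins` alone.

Synthetic predictors flip the truth with per-class error rates; the
default trio (precise / balanced / sensitive) spans the
high-specificity, low-sensitivity profile that missing-residue-trained
predictors show.  Quality records are drawn independently of disorder
unless a resolution coupling is requested.  The bundled ontology is a
small synthetic three-namespace `is_a` DAG (levels 0–5, including a
diamond), with one term planted preferentially on LDR proteins.

What the generator does **not** emulate: real electron density,
B-factors or refinement artifacts; correlated errors between chains of
one crystal form; biased deposition (the same protein solved repeatedly
in the same construct); annotation noise in GO; and the actual PDB-wide
distributions behind published figure values.  Passing tests therefore
demonstrate that the pipeline's logic is correct under controlled vote
noise — not that published snapshot-dependent numbers (predictor
rankings, enrichment term lists, exact correlation coefficients) are
reproduced.  Those require the external PDB/MobiDB/DisProt/GO snapshots
and are covered instead by null/signal simulations and planted-effect
fixtures.

## Numerical and degenerate-input choices

- Exact 50% vote ties are structured (`>` is strict).
- `U` breaks disordered runs; a region never spans uncovered sequence,
  because disorder cannot be asserted without an observation.
- Consensus-difference intervals are reported whatever their length
  (class left unset below 5 residues): truncating them would discard the
  mixture signal they exist to expose.
- Disorder content, Pearson correlation and enrichment raise on empty
  denominators, constant vectors and empty/non-nested target sets
  rather than returning sentinel values; per-residue metrics are the one
  place degenerate denominators yield a flagged 0, to keep tables
  rectangular.
- Fisher p-values come from the exact hypergeometric tail
  (`scipy.stats.fisher_exact`, one-sided greater); tests verify them
  against explicit tail enumeration to 1e-10 relative error.
- Confusion counts use exact integer arithmetic; MCC is computed in
  floating point from integer products.

## Problem sizes used by the test suite and acceptance script

Consensus correctness is established on the complete per-position
column space (every `{O,M,N}` column for 1–4 chains; consensus is
strictly position-wise, so this covers all stacks), exhaustive small
stacks, and seeded random 4-chain × 6-position stacks.  Recovery runs
use 50 proteins × 15 chains (boundary recovery), 10 proteins × 25
chains (error-rate bound), and 150 proteins for the enrichment
scenario; oracle comparisons use 100 random 2×2 tables and 50 random
confusion/correlation draws.  These sizes make every property
measurable with comfortable statistical margins while keeping the whole
suite fast.

## Known limitations

- REMARK 465 author numbering is assumed to equal SEQRES numbering; no
  DBREF-based offset reconciliation is attempted.  Files violating that
  assumption lose those entries (with warnings), not silently.
- Zero-occupancy-but-modeled residues and alternate conformations are
  never counted as missing; only unmodeled residues are.
- The zero rule produces very few regions when many chains cover a
  protein (an all-chains-missing run becomes exponentially unlikely
  under independent noise); analyses of zero-consensus regions are most
  informative at modest chain counts.
- Bonferroni correction is the only multiple-testing scheme offered.
- Plotting is out of scope; all outputs are tabular.
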