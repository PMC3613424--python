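# Methods

## Artificial self-hit records

A MEGAN-like functional assigner needs only three fields of a tabular
alignment record: query id, subject id and bit score. To bin an entire
reference database, sapkit emits one record per subject with query id =
subject id = the record's canonical id (the first GI-bearing token of the
first defline sub-header; nr deflines concatenate merged headers with the
SOH byte, 0x01, and only the first identifies the record). The remaining
fields describe a perfect self-alignment: identity 100.00, alignment length
L, coordinates 1..L on both sides, E-value 0.

The bit score is `2·L + 20` (floored at 40 bits for subjects under 8
residues). Any value above the assigner's default 35-bit minimum would do —
the score is a carrier, not a statistic — but this affine rule scales
monotonically with subject length and yields 814 bits for a 397-residue
subject, the worked reference point used by the tests. Zero E-values are
serialised as `0.0` and integral bit scores without a decimal part.

## Functional assignment

The assigner mirrors MEGAN's functional (KEGG) behaviour on tabular input:

- `min_bit_score` (default **35 bits**): hits below it are ignored.
- `top_percent` (default **10%**): among a read's surviving hits, only hits
  with bit score ≥ (1 − 0.10)·best are co-optimal candidates.
- The read inherits the KO set of the highest-scoring co-optimal hit whose
  GI has a KO mapping; ties break by smaller E-value, then smaller GI, so
  assignment is deterministic and hit-order-invariant.
- A read maps to **every** EC of its assigned KO, so per-EC counts may
  overlap while read totals count distinct reads. Partial EC codes
  (`1.13.12.-`) are opaque labels, not wildcards.
- Min-support is not applied to functional bins (it is a taxonomic-binning
  device), and taxonomic (LCA) binning is out of scope; the SEED/subsystem
  analogue is structurally identical and left as an extension point.

These two knobs are the smallest rule set consistent with per-read KO
binning under a printed 35-bit default; MEGAN's exact tie-breaking among
equal-scored mapped hits is not documented, so the deterministic rule above
is this package's own choice.

## Built-in translated search

A deliberately transparent desk-scale aligner, not a BLAST replacement:

- **Translation**: all six frames, standard code, trailing partial codons
  dropped, stops as `*`, N-codons as `X` (Biopython).
- **Seeding**: exact 3-mer matches over the 20 standard residues (every
  such word has a positive BLOSUM62 self-score); single-hit trigger, no
  two-hit heuristic.
- **Extension**: banded gapped Smith–Waterman (Gotoh affine recurrences,
  numba-compiled) over a band of 15 diagonals around the seed diagonals of
  each (frame, subject) pair; BLOSUM62 with gap open 11, extend 1, a gap of
  length g costing 11 + g. One best alignment per (read, subject) pair,
  maximised over frames.
- **Statistics**: S_bits = (λ·S_raw − ln K)/ln 2 with fixed gapped-BLOSUM62
  constants λ = 0.267, K = 0.041; E = m·n·2^(−S_bits) with m the frame's
  peptide length and n the database residue count. No length corrections or
  composition adjustment: E is then *exactly* linear in n, which is the
  property the filter-pass losslessness proof needs. Fixing λ and K rather
  than computing them keeps results deterministic; pipeline correctness
  depends only on monotonicity in n, not on absolute calibration.
- **Coordinates**: query coordinates are nucleotide positions on the read;
  reverse-frame hits are serialised with start > end, the usual tabular
  convention.

Within its band the kernel returns the true local optimum: the tests verify
raw-score equality with an independent unbanded Smith–Waterman (biotite)
on derived read/subject pairs, and ≤ on arbitrary pairs.

External tools (e.g. `blastx`) plug in through an adapter that parses their
12-column output and applies the same cutoff. Real tools use
composition-adjusted statistics that are only approximately linear in n, so
the exact-agreement guarantee weakens to an approximation; the
`lock_searchspace_full` flag counters this by scoring filter-pass E-values
against the full database's residue count, making the filter strictly more
permissive and restoring the no-loss property at the cost of a larger
candidate set.

## Pipelines

`run_sap` composes target-GI selection → sub-database extraction → filter
pass → read isolation → verification pass → final assignment with off-target
exclusion. `run_direct` is the one-pass full-database oracle; both produce
the same per-EC summary shape (columns: EC, first_pass, final, direct).
Reads with filter-pass hits but no verification-pass hits are counted as
discarded and warned about — impossible under the built-in backend, possible
under external statistics. Stage wall-times and candidate-set sizes are
recorded as run metadata only; no performance claim is tested.

## Synthetic scenarios

The generator emulates the structure of a pathway-targeted annotation run:

- **Reference set**: each target family is one KO with a distinct EC under
  one pathway (nitrogen-cycle labels are used for flavour); members are an
  ancestor protein with 5% per-site substitutions, so within-family identity
  (~90%) far exceeds background. Background proteins are random sequences,
  a quarter mapped to off-target KOs, the rest unmapped. Protein lengths are
  uniform on 120–240 residues.
- **Reads**: 100 nt, reverse-translated protein fragments (uniform
  synonymous codons, random strand) with 2% DNA substitutions by default;
  non-target reads split between background-protein fragments and uniform
  random DNA.
- **Traps**: each trap construct pairs a target-mapped protein T with an
  off-target paralog P at a controlled 12% substitution distance, and emits
  reads *from P*. The margin guarantees (not probabilistically) that the
  reads align to T above the cutoff — so the filter pass admits them — but
  to P strictly better, so final assignment is off-target and they must be
  discarded. This is the failure mode the verification pass exists for.
- All randomness flows from the scenario seed through per-stage generators;
  identical spec and seed give byte-identical outputs.

**Scenario S1** (the default spec, seed 42) is the standard verification
scenario: 3 target families × 5 members, 2 traps, 40 background proteins,
500 reads, of which 30% derive from target families and 10 per trap from
paralogs. At this scale a full SAP + direct comparison at two cutoffs runs
in a few seconds on one CPU, which is why the end-to-end suite can assert
the exact-agreement property at both 1e−5 and 1e−10 on every run.

What passing on synthetic data does and does not show: the generator has no
indels, no codon bias, no quality errors and no real phylogenetic structure,
so it exercises the *logic* (losslessness, off-target exclusion,
monotonicity) exactly, but says nothing about sensitivity on real diverged
homologs or about absolute counts against any real reference release.

## Numerical and degenerate-input choices

- E-value comparisons use unrounded bit scores; serialised bit scores are
  rounded to one decimal, identities to two.
- Hits within one read are ordered by ascending E, then descending bit
  score, then subject id, making output deterministic under any internal
  iteration order.
- Empty read sets, empty hit lists and zero-surviving-read finalisations
  return valid zero summaries; an empty sub-database (target matched
  nothing) is an error, as is a read id mismatch between pipeline stages.
- Reference parsing accepts any FASTA wrap and preserves unknown residues
  (U, B, Z, X); U is scored as C, other unknowns as X.

## Known limitations

- GI-keyed identification only; accession-based mapping is not implemented.
- The built-in aligner is single-hit seeded and banded: a homolog with no
  exact 3-mer seed near the optimal diagonal can be missed — acceptable at
  synthetic scales, and irrelevant to the pipeline equality proof, which
  holds for whatever hit set the (shared) backend produces.
- Fixed Karlin–Altschul constants mean absolute E-values are approximate;
  only their ratios across database sizes are exact.
- Per-EC census absolute values depend entirely on the reference/mapping
  inputs; nothing is claimed about any specific public database release.
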