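# Methods

## Setting and model

The package analyses amplicon resequencing of an ancient specimen. A *locus*
is a short reference region with a published coordinate system (1-based;
promoter-relative systems are negative and have no position 0), one or more
*amplicons* (PCR designs whose primer spans are masked from every statistic),
and *diagnostic sites*: positions where the endogenous individual and modern
contaminants carry different alleles, either haplogroup-diagnostic motif
positions (mitochondrial fragments) or the nuclear target variant being
genotyped.

Sequences are assumed to arise as follows. Each amplification starts from a
few template molecules drawn from the extract; a template is a modern
contaminant with probability *c*, otherwise an endogenous molecule whose
cytosines carry hydrolytic deamination: each C reads as T, and each G as A
(the complementary-strand event), independently with probability δ/2. Clones
copy one template and add independent per-site polymerase error ε; deep
sequencing reads one template molecule per read (emulsion PCR isolates single
molecules) and adds per-site error η. Whole amplifications fail with
probability `p_dropout`. Two consequences drive the statistics:

1. clones of one amplification share template-level damage, so repeated
   identical mismatches within an amplicon are **one** molecular event;
2. contaminant molecules are modern DNA and carry no deamination, so the
   damage spectrum separates the classes.

## Procedures

**Alignment.** Every clone/read is aligned globally to its amplicon reference
slice (Needleman–Wunsch with affine gaps: match +1, mismatch −1, first gap
column −3, each further column −1, computed by Biopython's pairwise aligner).
The reference frame is the common frame for all sequences of an amplicon; no
multiple alignment is computed. Ties between co-optimal paths resolve to the
aligner's first reported path, which is deterministic for fixed input. A
query must be within [0.5×, 2×] of its target length, which catches gross
mis-assignment. Reads arrive primer-trimmed and align to the unmasked
interior; clones include primers, whose columns are masked. Ambiguous query
bases (N/IUPAC) never produce substitution events and are removed from
surveyed-site denominators.

**Classification.** A sequence is endogenous (contaminant) when a strict
majority of the haplogroup-diagnostic sites it covers carry that class's
allele; a tie, zero coverage, or a third allele at any covered site leaves it
unclassified. The third-allele rule is deliberately conservative: a
damage-altered diagnostic site should surface as "unclassified", never flip a
class silently. Per-amplification summaries report percent endogenous over
classified sequences; the locus figure is the *unweighted mean over
amplifications* (not pooled clones), so each independent amplification
carries equal weight.

**Misincorporation spectra.** Substitution types: type I = A→G, T→C;
type II = C→T, G→A (both strands collapsed — the strand of molecular origin
is unobservable in cloned amplicons); the remaining eight are transversions.
Events are deduplicated per amplification on `(amplicon, position, observed
base)` — the observed base is part of the key so two distinct molecular
events at one hotspot are retained. Composition correction divides each class
by its susceptible sites, counted once per amplification to match the
deduplicated numerators: `p_TsII = e_TsII/GC`, `p_TsI = e_TsI/AT`,
`p_Tv = e_Tv/(AT+GC)`; shares are `%P(X) = 100·p_X/Σp`. Pooling across
amplifications sums event and site counts before recomputing, i.e. a
site-count-weighted average, and is exactly equivalent to computing one
spectrum on the concatenated events. The separate *damage frequency per site
per sequence* keeps every sequence's type-II events (no deduplication) over
GC sites summed per sequence — the two statistics answer different questions
(how many molecular lesions vs how often a read shows one).

**Damage contrast.** Endogenous vs contaminant classes are compared by a
Pearson chi-square (df = 1, continuity correction off by default, flag to
enable) on the 2×2 table crossing class with GC sites carrying vs not
carrying a type-II event, per sequence. The table construction is a design
choice; with no events at all the statistic is 0 and p is reported as 1 with
a warning rather than failing.

**Consensus.** Per-position most-frequent symbol among A/C/G/T/gap over
aligned clones (unmasked interior only) or over a deep tally; the two
pathways agree when fed the same sequences. Ties are written as the IUPAC
code over the tied bases and flagged — preserving the information rather than
defaulting to the reference — and gap-majority positions are deleted so the
output is plain FASTA. Insertions relative to the reference are outside the
consensus frame and ignored.

**Genotype.** An allele is accepted as genuine only when it (i) appears in at
least `min_pcrs` independent amplifications and (ii) reaches a pooled
fraction ≥ `derived_threshold` over all molecules, clones and reads combined.
Defaults `min_pcrs=2`, `derived_threshold=0.10` encode the standard aDNA
replication criterion; both are explicit, configurable choices, and a
sub-threshold or unreplicated observation is reported as a warning rather
than silently dropped. The call also records whether the ancestral→derived
change is C→T or G→A, i.e. mimicable by deamination — relevant when weighing
a residual derived fraction.

**Contaminant tracing.** The contaminant-class consensus is expressed as a
motif (differences from the locus reference) and ranked against investigator
profiles by mismatch count over the union of positions either motif names; a
position present in only one motif counts as a mismatch, exact (0-mismatch)
matches are flagged. With partial amplicon coverage the motif covers only the
sequenced positions, so a true carrier can score nonzero mismatches against
their full profile — ranking, not the absolute count, is the signal.

## Simulator and what it does (not) show

The generator emulates: locus-specific endogenous/contaminant haplotypes
differing at the diagnostic sites, contaminant admixture at the template
level, template-shared deamination, per-copy polymerase error, per-read
sequencing error, PCR dropout, and deep-read tallies with the tally-file
conventions (primers excluded). Defaults are the conditions of a
well-preserved-specimen experiment: c = 0.12 (the ~12% modern motif fraction
such extracts show), δ = 0.02 per susceptible site, ε = 10⁻³, η = 5·10⁻⁴,
2 templates and 20 clones per PCR, 3 PCRs per design, 25% dropout, 45,120
reads. It does **not** model fragment-length distributions, positional
(read-end) damage enrichment, homopolymer indel noise (an optional flag-free
simplification — damage statistics ignore indels), chimeras, or
single-stranded library artefacts; passing tests therefore demonstrate
correctness of the statistics under the stated generative model, not
robustness to those real-data effects.

Parameter-recovery checks use sizes where the binomial standard error is the
right yardstick: the contamination recovery samples 2000 single-clone
amplifications (independent template lineages; clone-sharing correlation is
exercised separately by the dedup checks), the damage-rate and error-rate
recoveries use 50,000 reads. The damage-contrast simulation uses 25
amplifications × 8 clones from 4 templates with δ = 0.05 so that ≥50 type-II
events over ≥5000 surveyed GC sites are virtually certain.

## Numerical and interface choices

* Coordinates: signed affine offset per locus, skipping 0 on negative axes;
  mapping and unmapping are exact inverses and validated at registry load.
* Percentages print at 2 decimals (read-level derived fractions additionally
  at 1 decimal, matching the usual reporting style); underlying values are
  kept at full precision.
* Dedup output is sorted, making it idempotent and order-invariant.
* Degenerate inputs fail loudly: empty pools, zero susceptible sites with
  events present, tally rows whose counts do not sum, reference mismatches,
  duplicate FASTA ids, empty sequences.
* All randomness flows from a single integer seed through
  `numpy.random.default_rng`; identical seeds give byte-identical outputs.
* The bundled locus registry uses the published amplicon lengths, primer
  sequences and diagnostic coordinates on synthetic reference backbones; the
  mitochondrial motif positions are synthetic illustrations (files are
  labelled accordingly), so analyses of real data must supply a real registry
  via `--config`.

## Known limitations

* The aligner's tie-break among co-optimal alignments is the library's path
  order, not a hand-specified diagonal preference; event extraction on
  high-identity sequences is unaffected, but exotic equal-score indel
  placements could differ between library versions.
* Damage is modelled with a single rate δ and no positional profile, so the
  spectra cannot be used to fit terminal-enrichment curves.
* The chi-square contrast treats GC site-observations as independent;
  template sharing within amplifications makes the test anti-conservative on
  clone data, which is acceptable for the qualitative class contrast it
  serves but not for calibrated inference.
* Two-class mixtures only; no phylogenetic placement of contaminants and no
  joint likelihood of contamination and damage.
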