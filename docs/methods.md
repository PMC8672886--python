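# Methods

## Scope and design

The package implements a complete desk-scale workflow for characterising
LTR retroelements / endogenous retroviruses in a genome: detection,
structural classification, nomenclature, molecular dating, chromosomal
distribution statistics, protein-feature annotation, and expression
integration. Because the real genome-scale inputs (a full vertebrate
assembly and deposited RNA-seq) are not reproducible at desk scale, the
package treats its synthetic-genome simulator as a first-class module:
every downstream stage is validated by parameter recovery against
planted ground truth, and a packaged 25-chromosome reference table
provides an in-data regression target for the distribution statistics.

## Mutation model and dating

A provirus is synthesised as TSD + 5′LTR + internal region + 3′LTR + TSD,
with both LTRs copied from one ancestor. Each LTR then mutates
independently: every site substitutes with probability R·t (R
substitutions/site/year, t the age in years), with uniform replacement
among the other three bases (Jukes–Cantor-style, capped at 0.75). The
substitution count per LTR is Binomial(L, R·t), i.e. Poisson(R·t·L) to
excellent approximation at these rates. Indels are a config knob and off
by default, because no indel model is available for LTR decay and leaving
them out keeps divergence estimable identically by p-distance and JC.

Expected pairwise divergence between the LTRs is 2·R·t with a small
multiple-hit deficit of (4/3)(R·t)² per site; at 2·R·t ≤ 0.1 the mean
p-distance stays within 5% of 2·R·t (tested over 250 replicates).
Dating inverts the model: the two LTRs are globally aligned (match 1,
mismatch −1, gap open −5, extend −1), gapped columns are excluded from
both numerator and denominator ("overall nucleotide divergence" as a
p-distance, the common default; JC correction optional and flagged
undefined at p ≥ 0.75), and T = D/(2R) is reported in Mya. Cohort
summaries mirror the published filters: score > 300, both LTRs > 100 bp
(the shorter LTR is tested), identical-LTR fraction, 1-Mya age bins, and
medians by LTR-length bin, structure and class. Parameter recovery on
500-bp LTRs at true ages 0.5/2/10 Mya keeps cohort medians within 15% of
truth; the residual negative bias at 10 Mya (~5–10%) is the expected
multiple-hit saturation of the p-distance and shrinks with LTR length or
with the JC model.

The default rate R = 1.46 × 10⁻⁸ subs/site/year is the neutral rate of
fish genomic evolution; it is a plain parameter everywhere.

## Detector

A deliberately simplified three-stage detector, not a reimplementation
of any existing cascade:

1. **Seeding.** Exact shared 15-mers between positions 1–15 kb apart
   (the plausible LTR-start spacing of a provirus), found by integer
   k-mer hashing; k-mers occurring more than 64 times are skipped.
   Seed pairs are clustered by diagonal (±50 bp band).
2. **Refinement.** Each cluster's two loci, padded by 250 bp, are
   locally aligned (match 2, mismatch −3, open −5, extend −2) and the
   alignment is trimmed to its maximal-scoring column segment (+1 match,
   −2 mismatch/gap, Kadane). The trim step is what guarantees that an
   identical LTR pair reports identity exactly 1.0 instead of being
   dragged outward by chance flank matches. Candidates must pass LTR
   length 100–2,000 bp, identity ≥ 0.85 and spacing bounds; overlapping
   candidates collapse to the best identity × length.
3. **Scoring.** score = 250·identity + 30 (TSD found, 2–8 bp exact
   flank duplication) + 20 (plausible spacing) + ORF terms (0.2/aa per
   internal ORF, capped at 100 per slot, up to three non-overlapping
   ORFs ≥ 150 aa) + 20 per distinct conserved motif class (capped 100).
   The weights are calibrated so that a complete recent provirus scores
   well above 300, an LTR-LTR element lands between 250 and ~320, and
   random sequence cannot reach the 250 reporting floor (its candidates
   fail the identity/length gates first). Only the thresholds 250
   (report) and 300 (high confidence) carry over their published
   semantics; the absolute scale is this package's own.

Chromosomes are processed in 9-Mb fragments with 2-kb overlaps and
duplicate calls from overlap zones collapsed (higher score wins).
Element boundaries are the outer LTR boundaries; strand comes from the
orientation of internal ORF evidence, defaulting to "+" for LTR-LTR
elements. Solo LTRs are deliberately not called — single LTRs without a
pair partner produce no seed cluster — mirroring the recognised blind
spot of LTR-pair-based predictors. Gene slots are assigned
positionally (longest internal ORF → pol, upstream → gag, downstream →
env); this heuristic is adequate for census purposes on simulated data
but is not a substitute for homology-based gene annotation on real
genomes.

On the default benchmark (10 Mb, GC 0.384, 20 planted elements with ages
≤ 2 Mya, LTRs 300–800 bp, structure mix of complete / LTR-pol-LTR /
LTR-LTR / LTR-gag-pol-LTR) the detector reaches recall and precision
≥ 0.9 (1.0 on the tested seeds); a pure random genome yields zero calls.

## Classification and nomenclature

Retroviral class is assigned by nearest-reference local-alignment
identity over the reverse-transcriptase region — an explicit surrogate
for an RT phylogeny, which is out of scope. Identity is matches divided
by the shorter sequence length, so short spurious local hits cannot pass
the 0.6 floor; ties go to the first-listed reference. The shipped panel
is synthetic (deterministic sequences, one per class, generated from a
fixed seed and labelled synthetic in code) because curated reference RT
sequences cannot be redistributed; users supply a real panel as FASTA
with `>label|accession` headers.

Names are a reversible format `<prefix>-<locus>-<species>`:
prefix ERV for class I–III (locus initialed E/AB/S for epsilon-,
alphabeta-, spuma-related), ERVL otherwise; locus =
chrom.fragment.ordinal with the fragment index from the 9-Mb
segmentation (elements starting inside a 2-kb overlap zone belong to the
earlier fragment — configurable) and the ordinal the start-position rank
within that fragment; an optional trailing G/P/E marks a gag/pol/env
gene annotated outside the LTR-to-LTR span. `parse(format(x)) == x` is
property-tested on 10⁴ random field tuples. Two conventions were
genuinely open: published class I names always carry "E" even where the
epsilon relation is unverified, so unlabeled class I defaults to "E"
(flagged in metadata); and published names occasionally carry a
sub-lettered fragment token ("7b"), so the parser accepts one lowercase
letter there, defaulting to none.

## Distribution statistics

Density = detected/length (Mb); expected count = length × genome-wide
density. The genome-wide density is a configured input with fallback
total/Σlengths, because a published density can rest on a genome length
that includes unplaced scaffolds and is then not derivable from the
per-chromosome table alone (the packaged reference table has exactly
this property: printed density 2.31/Mb, counts summing to 3,296 against
a stated total of 3,315). The χ² test is the two-cell (on/off
chromosome) goodness-of-fit statistic with 1 df, with the off-cell total
being the genome-wide element total; this choice reproduces the packaged
table's printed χ² values to < 0.1%. p-values are reported raw, with a
Bonferroni column alongside for transparency. Pearson correlations use
the two-sided t-test. Windowed density tracks count a feature in every
window it overlaps.

## Protein grammar

ORFs are scanned in all six frames (ATG-to-stop by default; stop codon
included in the nucleotide interval, reported in forward-strand
coordinates). Simple motifs are regular expressions over the 20-letter
alphabet — furin R/K-X-R/K-R, C-X-X-C, C-X{5,6,7}-CC — with overlapping
matches reported and the ambiguity letter X tolerated in input but never
matching any pattern position. The ISD is located as the best-scoring
17-aa window against reference profiles (per-column exact-match scoring,
earliest best window, minimum score 12/17 when called through
`annotate_env`); residue 14 of the window sets the immunosuppressive
flag (Q on, R/K off, otherwise undetermined). The shipped default
profiles are simulator-oriented placeholders — real group consensi are
published only graphically and must be supplied by the user as plain
17-mers. Transmembrane segments are maximal runs of 19-residue
Kyte–Doolittle window means ≥ 1.6, merged across gaps < 5; the
C-terminal-most segment is taken as the Env TM. Architecture is valid
iff the present features are ordered furin < ISD < C-Xn-CC < TM (absent
features skipped; a featureless protein is vacuously valid and flagged).
Signal-peptide prediction is out of scope.

## Expression integration

TPM and FPKM use the standard formulas (TPM columns sum to 10⁶ by
construction). Replicates are aggregated by mean before thresholding,
matching per-condition reporting. Expressed sets use strict thresholds
(TPM > 100 for stage panels, FPKM > 1 for tissue panels); specificity is
set difference against the union of the other conditions, with a full
Venn-region table emitted. Virus responsiveness is an explicit rule —
infected mean above a floor and log2 fold change ≥ 1 with pseudocount
1 — replacing model-based differential testing, whose internals are out
of scope and whose original thresholds were unstated; all rule
parameters are exposed. Cis association is purely positional (interval
gap ≤ 10 kb, overlap = 0). Trans association keeps pairs with |Pearson
R| > 0.85 and raw p < 0.01 (two-sided t-test), emitting a
Benjamini–Hochberg column alongside; zero-variance features are skipped.
A documented discrepancy — one published passage filters at |R| > 0.99
rather than 0.85 — is handled by exposing `r_min` (default 0.85).

## Expression simulator: what it does and does not emulate

Counts are built as multiplicative means (baseline × condition
specificity × infection response × 2^(correlation term)), jittered
log-normally (σ = 0.2 default) and Poisson-sampled; σ = 0 returns exact
expected counts so noise-free designs recover planted fold changes
identically. Fifty housekeeping-like background features (mean 20,000)
absorb library mass so baseline features sit far below the TPM/FPKM
thresholds, and correlation-pair features start from mean 1,000 so
Poisson noise cannot swamp the planted signal. Planted correlations live
on the log scale (element log2-mean carries a latent factor z, the
partner carries r·z + √(1−r²)·w), so recovery tests correlate
log2(x+1)-transformed values; with amplitude 1.5 and σ = 0.2 the
recovered correlation is attenuated by ≈ 4%, which is why recovery tests
plant r = 0.99 targets. The simulator does not emulate transcript
isoforms, multi-mapping reads (a real concern for repetitive elements),
batch effects, or count overdispersion beyond the log-normal–Poisson
mixture — a green recovery test establishes that the analysis rules
invert the stated generative model, not that they are robust to
real-library artefacts.

## Numerical and tie-breaking choices

- Alignment ties: the first alignment of Biopython's deterministic
  optimal set is used throughout.
- Class assignment ties go to the first-listed panel reference.
- Candidate non-redundancy prefers identity × aligned length; element
  overlap resolution prefers score, then earlier coordinate ordering.
- Insertion points are drawn uniformly with rejection sampling
  (min gap 20 kb in the default benchmark); specs are processed in
  order, making placement deterministic under a fixed seed.
- TSD default 4 bp; detector searches flank duplications of 2–8 bp.
- Degenerate inputs: empty sequences, zero-length chromosomes, p ≥ 0.75
  under JC, zero-variance expression features and single-chromosome χ²
  tables are rejected or flagged rather than silently computed.

## Known limitations

- The detector requires both LTRs: solo LTRs and elements older than the
  0.85 identity floor (≈ 5 Mya at the default rate) are invisible by
  design.
- Gene-slot assignment is positional, not homology-based.
- No PBS/PPT detection, no nested-element resolution, no among-site rate
  variation in dating, and point age estimates only (no CIs).
- The synthetic RT panel and ISD profiles are placeholders standing in
  for curated references; conclusions about real class membership or ISD
  calls require user-supplied panels.
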