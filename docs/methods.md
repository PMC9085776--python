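# Methods

This note documents the models, conventions and numerical choices
behind `doubletap`, and what the synthetic-data tests do and do not
demonstrate about real sequencing data.

## Coordinates and the cut site

All coordinates are 0-based, half-open, on the stored forward strand.
Cut sites are *gap* coordinates (between two bases), which makes indel
placement arithmetic unambiguous. SpCas9 is modelled as a blunt cutter
3 nt 5′ of the PAM: a + strand protospacer starting at *s* cuts at
*s* + 17, a − strand one at *s* + 3. PAM patterns are IUPAC strings
(NGG for SpCas9, NG for the relaxed Cas9-NG variant); IUPAC ambiguity
is honoured only in PAM patterns — spacers are concrete ACGT strings,
and an N in a read or background sequence never matches anything.

## Canonical indel keys

Replicates and different alignments must aggregate identical repair
products, so every indel is reduced to a canonical key:
`ins:<len>:<offset-from-cut>:<bases>` or `del:<len>:<offset-from-cut>`,
after shifting the indel to its leftmost equivalent placement inside
repeats (the same normalisation as VCF left-alignment, with base
rotation for insertions). Key equality is then exactly product-sequence
equality, a property the test suite checks by brute force. A
left-normalised deletion may sit entirely 5′ of the causative cut
inside a long repeat; such reconstructed placements carry a
`normalized` marker that waives the "deletion contains or abuts the
cut" construction check.

## MMEJ deletion model

Deletions producible by microhomology collapse are enumerated
exhaustively: every pair of identical substrings of length ≥ 2 (default
`min_mh`), one ending at or before the cut and one starting at or after
it, whose collapse removes ≤ 60 bases (default `max_del`, appropriate
for short amplicons — larger deletions escape amplicon sequencing
entirely). Products are deduplicated by canonical key, keeping the
longest microhomology and leftmost placement. Each deletion is scored

S = 100 · (L + G) · exp(−D / 20)

with L the microhomology length, G its G/C count and D the deletion
length; normalised scores give a predicted frequency distribution. This
is a transparent, GC-weighted, length-penalised heuristic in the spirit
of published microhomology predictors — a deliberate stand-in for
machine-learned indel predictors, kept simple and swappable
(`MMEJ_DECAY_NT` and the enumeration bounds are module constants or
call parameters). Observed NGS spectra always override the enumeration.
De-novo 1-bp insertions are enumerated with the templated duplication
of the base 5′ of the cut ranked first, matching the dominant NHEJ
outcome.

A protospacer is classified "high precision" when its top three indel
products strictly exceed 40% of all repair products.

## Read classification

Reads are aligned globally (Needleman–Wunsch with affine gaps: match
+5, mismatch −4, gap open −10, gap extend −1; read-terminal gaps free,
so truncated reads are not treated as deletions) against the HDR
amplicon first, then the reference. Classification inside a ±10 nt
quantification window around the cut:

* **HDR_perfect** — no mismatch or gap in the window against the HDR
  amplicon;
* **WT** — likewise against the reference;
* **INDEL** — ≥ 1 alignment gap touching the window against the
  reference, reported under canonical keys (reads carrying the HDR edit
  *plus* an indel land here: perfect HDR means no indels);
* **DISCARD** — everything else: QC failure (mean Phred < 20 or length
  < 80% of the amplicon), alignment identity < 60%, or window
  mismatches without a gap.

Mismatches and gaps *outside* the window are tolerated as sequencing
error. One consequence worth knowing: a substitution error falling
inside the 20-nt window reclassifies a WT or HDR read as DISCARD, so
WT/HDR percentages are biased low by roughly (window length × error
rate) while indel-allele frequencies are unaffected (the gap is still
seen). At the ≤ 1% per-base error rates the simulator emulates this is
a small, documented effect. A read whose single indel exactly
reconstructs the HDR amplicon is an errored HDR read, not a novel
byproduct, and is discarded rather than polluting the indel table.

Frequencies follow the amplicon convention: reads with an allele key ÷
all QC-passing reads × 100, per replicate, with mean and sample SD
across replicates; per replicate WT + HDR + indel + discard = 100.
Alleles below 0.1% mean frequency are pooled as `other`. Reads with two
separate indels count once per canonical key but once as an INDEL read;
how real pipelines treat such reads varies, and this choice is
declared rather than inferred.

Condition comparisons use the quotient rule for error propagation:
fold = b/a with σ = (b/a)·√((σ_a/a)² + (σ_b/b)²); percent decrease in
total indels is (a − b)/a × 100 with the same propagation applied to
b/a.

## Clonal genotyping

Clones (default assumed triploid, as in common pseudotriploid cell
lines) are genotyped from the fraction of classified reads per allele
class; a class is present at ≥ 10% — about one allele of three with
noise margin. Categories follow the standard isogenic-line taxonomy:
homozygous {HDR}, heterozygous {HDR, WT}, HDR/indel (HDR plus any
indel), indel mixture {indel}, WT/indel {WT, indel}, WT {WT}. Clones
under 100 reads are excluded and logged. Summaries report integer
percentages of called clones. The fraction cutoffs are declared
choices, not values inferred from any particular dataset.

## Secondary guide design

Candidates are all protospacers (both strands, each requested PAM
pattern) on the indel allele whose spacer overlaps the indel-altered
region by ≥ 1 nt; the altered region is widened to the full
repeat-ambiguity interval so guides near shiftable indels are not
missed. A candidate is **rejected** (not merely flagged) when its
spacer+PAM occurs verbatim on either strand of the wild-type locus (it
would cut the original sequence at an unwanted alternate site) or of
the HDR product (it would destroy the desired outcome — a conservative
extension: cutting the perfect product is never acceptable).
`keep_flagged` exposes the rejects for expert review. Candidates whose
PAM coincides with the primary protospacer's PAM (position and strand,
projected through the indel) are flagged `uses_original_pam` — the
typical situation for 1-bp insertions and small deletions — otherwise
`uses_alternate_pam`. A PAM created by the indel itself is allowed and
simply appears as an alternate PAM.

Off-target screening is a naive exact/1-mismatch string scan of
user-provided background FASTA (vectorised sliding comparison,
O(background × site length)); the PAM must match its pattern exactly
and the spacer with ≤ 1 substitution. Bulges and genome-scale indexed
search are out of scope. Ranking is deterministic: fewest full-match
off-targets, then fewest 1-mismatch hits, then greatest junction
overlap, then lexicographically smallest spacer.

The improvement model is affine in the summed initial rate of the
targeted indels, *in percentage points*: fold = 0.966 + 0.0167·r
(r² = 0.81), shipped as the default because the full point set behind
the published fit is not printed anywhere re-usable; `fit_improvement_model`
refits by closed-form OLS from user-supplied (rate, fold) pairs.
Predictions below fold 1 carry a warning. The design report greedily
selects up to k = 3 alleles by descending initial rate (three secondary
guides being the practical maximum) and sums their rates.

The re-cutting check on the HDR product (`check_blocking`) uses an
exact-substring rule: any change inside spacer or PAM counts as
blocking. In reality PAM-distal spacer mismatches can still permit
cutting; the simplification is deliberate and documented, and the tool
recommends silent PAM/PAM-proximal blocking mutations whenever the
primary site survives in the donor.

## The simulator

`simulate_reads` draws full-length amplicon reads from a stated
WT/HDR/indel mixture, then applies uniform per-base substitution
errors; quality strings are constant at the Phred score encoding the
configured error rate. `exact_counts` switches from multinomial
sampling to a largest-remainder deterministic composition, used where a
test needs the mixture recovered exactly. Double-tap experiments
reassign a conversion fraction q of each targeted indel's mass — a
share h to HDR, the rest split among configured secondary indel keys
(emulating the new low-frequency indels a secondary cut creates) — so
the implied fold-change has a closed form against which quantification
is checked.

What the simulator does **not** emulate: indel-type sequencing errors,
PCR bias and chimeras, read fragmentation or paired-end structure, UMI
structure, large deletions extending beyond the amplicon, and
cell-population effects (transfection efficiency, viability,
clone-sampling stochasticity). Passing round-trip tests therefore shows
the quantification and design logic is self-consistent at realistic
error rates and depths, not that it reproduces every artefact of real
amplicon libraries.

## Problem sizes and determinism

Default test and acceptance problem sizes — 240-nt loci, 1,500–10,000
reads per sample, 41 clones × 150 reads per genotyping arm, 100 random
instances per brute-force oracle comparison — were chosen as the
smallest sizes at which binomial 3σ bounds are meaningfully tight for
the mixtures used. All randomness flows through explicit integer
seeds; identical configuration yields byte-identical FASTQ.
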