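# Methods

## The two-step position-37 model and its read-out

Position 37 is defined structurally as the base at anticodon start + 3 on the
mature sense strand; the anticodon is located as the occurrence of the
header-declared trinucleotide nearest canonical position 34 (ties toward the
smaller offset). Full Sprinzl numbering is not computed: for mature,
intron-free references the anticodon-relative system is a per-gene bijection
and suffices to name position 37. tRNAs with insertions 5' of the anticodon
keep the correct label because it is anchored on the located anticodon, but
their other positions are reported as anticodon-relative offsets (`ac±k`),
not Sprinzl numbers. Intron-containing records are rejected unless lowercase
intron blocks are explicitly stripped. Coordinates are 0-based half-open
internally and 1-based in every exported table.

The modification model is a per-site discrete distribution over states
{unmodified A, inosine, m1I, unmodified G, m1G, unmodified C}, constrained to
the compatible reference base (inosine/m1I arise from A, m1G from G). The
reverse-transcription read-out maps states to observed bases: A→A, I→G,
m1I→T, and m1G→G. m1G is read as G by default — the misread-to-T signal some
protocols show was not observed in the data this read-out models — with an
optional `m1g_misread_t` rate for protocols where it occurs. The standard
genotype panel encodes wild type (m1I at A37 sites, m1G at G37 sites), *tad1*
(unmodified A37) and *trm5* (inosine at A37, unmodified G37).

## Synthetic data: what it emulates and what it does not

`simulate_reads` emits full-length mature-sequence reads: at each modelled
site a base is drawn from the state's read-out distribution, then uniform
per-base sequencing error ε is applied (each base flips to one of the other
three with probability ε). An optional per-state RT-stop probability
truncates the cDNA to the 3' side of the stopped site; it defaults to 0
because the inference models substitutions only. Read qualities are constant
Q40 (qualities carry no information for the inference). A truth manifest
records the drawn state and final observed base per read per modelled site.
All generators are byte-reproducible under a fixed seed.

What the generator does **not** emulate: adapter content and quality decay,
coverage drop-off along the molecule, RT fall-off gradients, indel
sequencing errors, residual m1G at position 9 or m1I at position 57
(representable by adding modelled sites at those offsets, but omitted by
default because per-site levels are not quantified), and isodecoder
cross-mapping beyond what the four-gene demo set exercises. Passing tests on
synthetic data therefore demonstrate correctness of the inference arithmetic
under the stated noise model, not robustness to every artefact of real
libraries.

Default study conditions: genotype pattern checks use 2,000 reads per gene at
ε = 0.005; parameter-recovery studies use 2,000 reads at ε = 0.001 with true
m1I fractions {0.1, 0.5, 0.9} and 100 runs per fraction, judged against a
3-sigma binomial band `3·sqrt(f(1−f)/n)`. Nucleoside tables default to truth
ratios 0.30 (m1G) and 0.10 (m1I) relative to wild type — the residual levels
reported for *trm5* mutants — with 3 replicates and 10% log-normal CV where
noise is wanted. Expression tables default to the study's class sizes: 1186
transcripts down and 580 up (2-fold), 102 proteins up and 161 down, of which
133 are protein-down with stable mRNA and 28 down in both layers
(133 + 28 = 161, consistent with the reported totals).

## Alignment and pileup

Reads are near-full-length copies of very short references, so alignment is
glocal: read-global, reference-local. Scoring is affine-gap Gotoh (match +1,
mismatch −1, first gap base −3, each further gap base −1; N counts as a
mismatch to everything). A read is assigned when its best score reaches
`min_score_fraction` (default 0.7) of the read length — tolerant of a few
modification-induced mismatches without spurious assignment — and is
strictly greater than the best score on every other reference; score ties
across references are discarded as multimapped rather than fractionally
assigned, which is conservative for proportion estimates. Reads under 20 nt
are not aligned. Sense-strand orientation is assumed; `try_revcomp` also
scores the reverse complement.

Numerical choices: the forward DP is exact (integer-valued scores in float64;
comparisons are exact). The within-row deletion state is computed as a
running prefix maximum, which is algebraically identical to the standard
recurrence because affine gap cost is linear in run length. Tie-breaks: when
an ungapped placement attains the DP optimum, the ungapped placement at the
smallest offset is used; otherwise traceback prefers match states and the
smallest reference end. This makes the per-read route (`align_read`) and the
vectorised batch route (`align_and_pileup`, which accumulates pileups
directly and falls back to traceback only for reads whose optimum requires a
gap) produce identical pileups, a property the tests assert.

Pileups count observed A/C/G/T per reference position; deletions increment a
separate column and insertions are skipped. External SAM alignments can be
ingested instead (primary records only; secondary/supplementary/unmapped are
counted and dropped).

## Calling and contrasts

Proportions at position 37 are computed directly from pileup counts with
deletions excluded from the denominator (RT-stop artefacts, not substitution
signal), so p_A + p_C + p_G + p_T = 1; the deletion fraction is reported
separately for QC. A call requires coverage ≥ `min_cov` (default 50,
otherwise `no_call`); at a reference A the state is m1I / inosine /
unmodified_A when the corresponding proportion reaches `dominance` (default
0.8), else `mixed` with the full vector retained. Both defaults are exposed;
they were chosen as conventional dominant-fraction settings, not fitted. At
non-A reference bases inference is restricted to dominant-reference versus
mixed, which supports reporting p_T at G37 (m1G) sites without a pathway
call.

Genotype contrasts use a two-sided Fisher exact test on the 2×2 table of T
versus non-T counts, with Benjamini–Hochberg adjustment across genes within
one contrast. The depletion effect is reported as delta p_T (reference minus
mutant). The test engines are validated against exact integer enumeration
(all 2×2 tables with margins ≤ 30) and an independent step-up BH
implementation.

## Nucleoside quantification

Each species' peak area is normalised to the sum of the four canonical
nucleosides (A, C, G, U) within the same replicate, making the value
invariant to injection amount. Genotype ratios are ratios of means (not
means of ratios), matching bar-plot-with-SE presentation and stable at small
replicate counts; the standard error is delta-method,
`se_r = r·sqrt((se_m/m)² + (se_c/c)²)`, chosen over bootstrap for
determinism. The control's own ratio is identically 1 with SE 0. The three
isomeric methylguanosines share a mass transition and are labelled by
retention time in the elution order m7G < m1G < m2G; exactly three distinct
peaks are required. Chromatogram integration and raw mzML handling are out
of scope — inputs are integrated peak areas.

## Omics integration

Protein tables carry linear mutant/control fold changes; transcript tables
log2 fold changes (the two conventions of TMT proteomics and RNA-seq
reports). Proteins are up/down when fold change is strictly > 1.20 / < 0.83
with BH-adjusted p < 0.05 (the strict Methods-style wording is used where
sources disagree on boundary inclusivity); transcripts when |log2FC| ≥ 1
("at least 2-fold", inclusive) with adjusted p < 0.05. BH is computed over
the table's raw p-values when no adjusted column is present. In the overlap
analysis genes missing from one layer are treated as unchanged in that layer
(proteomics covers fewer genes than RNA-seq); "protein down, mRNA stable"
means protein-down and not transcript-down. Filters are idempotent and the
intersection cells partition the gene universe.

Codon-usage bias: per-codon relative frequencies (stop codons excluded)
compared by two-proportion chi-square with BH, plus an aggregate chi-square
(no continuity correction, so it matches a label-permutation null) on pooled
modified-versus-other codon counts; "no bias" means aggregate p > alpha. The
modified-codon set is derived from tRNA references: every tRNA with A37
(m1I-eligible) or G37 (m1G-eligible) contributes the Watson–Crick reverse
complement of its anticodon expanded by wobble rules at the third codon
position (G34 → codon-3' U/C; U34 → A/G; C34 → G; A34 treated as inosine by
default, reading U/C/A).

qPCR relative expression is the standard 2^−ΔΔCq arithmetic against a
reference gene and calibrator sample, with technical replicates averaged
first.

## Known limitations

- Position 37 is anticodon-relative, not Sprinzl; exotic secondary
  structures are not modelled.
- The aligner has no mapping-quality model and no indel realignment; the
  pipeline computes proportions from raw pileups rather than via a variant
  caller.
- Mixed m1I/I/A populations below the dominance threshold are reported as
  `mixed` rather than deconvolved.
- The xlsx ingestion for deposited supplementary tables maps columns by
  header-name patterns and may need a manual column mapping for other
  layouts.
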