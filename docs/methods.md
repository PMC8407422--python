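# Methods

This note documents the models behind `ribolens`: what the synthetic-data
generator emulates, how each analysis stage is defined, the defaults that
matter, and the numerical choices made where the design was open.

## Coordinate and format conventions

All in-memory coordinates are 0-based half-open; GFF3 is 1-based closed at
the I/O boundary, bedGraph 0-based half-open. 5'-end tracks are dense
per-strand arrays over the genome; float dtype so noise-free expected tracks
are representable exactly. The chromosome is treated as circular in the
organism but genes never wrap the origin, so interval arithmetic is linear.

## Synthetic-data generator

The generator emulates a two-condition bacterial profiling study
(heterotrophic vs autotrophic growth, biological duplicates) at desk scale.

**Genome layout.** Operons of 1–10 genes (geometric size law, p = 0.45,
capped at 10) are placed with 150–320 nt leading gaps and 15–40 nt
intra-operon gaps, genes of 60–400 codons (length divisible by 3, ATG/TAA at
the annotated bounds), strand chosen per operon. An infeasible packing
raises a configuration error rather than silently truncating.

**Planted expression.** mRNA abundance is shared within an operon
(log₂-normal, SD 2.0 — levels spanning ~3 decades, as bulk RPKM data do);
the mRNA change between conditions is operon-level N(0, 1) on the log₂
scale. Baseline TE is per-gene log₂-normal (SD 0.5). The log₂ TE change is
a three-component mixture mirroring the shape reported for an acetogen's
heterotrophic→autotrophic switch: 16 % high at +2.8 (= 2σ of a σ = 1.4
distribution), 8 % low at −2.8 (component SD 0.3), the rest N(0, 0.8) —
overall SD ≈ 1.5. Truth class labels apply the same μ±σ rule to the
noiseless planted changes, so recovery tests measure estimation error only.
An optional `buffering_coefficient` couples TE change to mRNA change
(default 0: no planted buffering). Subunits of planted complexes have their
copy number folded into TE (not mRNA), so footprint levels — and not
transcript levels — track stoichiometry; the first two-gene operon is
always planted non-equimolar at 1:9.

**TSSs and 5'-UTRs.** Every operon's first gene gets a primary TSS;
downstream members get their own with probability 0.35 (real operons often
carry internal promoters, and this yields roughly 1.5 UTRs per operon, in
line with several hundred UTRs for a few hundred genes). UTR lengths are
floor(Exponential) with median 49 nt — the configurable median mirrors the
study organism — capped at 280 nt so every planted TSS stays inside the
primary window of its gene. TATAAT (−10) and TTGACA (−35) boxes are written
upstream of every TSS, and AGGAGG is written at −12…−7 for high-TE genes so
Shine–Dalgarno contrasts are recoverable. Start/stop codons are written
last and always win over planted motifs.

**Libraries.** Expected 5'-end densities are built per library and scaled
to the configured depth:

* RNA-Seq: uniform over each transcript (TSS→stop), so gene-body counts are
  ∝ abundance × length.
* Ribo-Seq: A-sites uniform over the 5-codon-trimmed elongation window with
  expected gene mass ∝ abundance × TE × length; within a codon the A-site is
  in frame 0 with probability `frame0_fraction` (default 0.8; remainder
  split over frames 1/2), and the recorded 5' end is the A-site minus the
  17-nt offset. UTR footprints are added at a condition-dependent fraction
  of the gene's CDS density (defaults 0.5 and 1.4 — the UTR/CDS relative
  occupancy medians the pipeline should recover).
* dRNA-Seq: 30 % of the RPP+ library concentrates at true TSS positions
  (weights ∝ transcript abundance), the rest is uniform background over
  both strands — the background distribution of processed 5' ends is not
  known, so uniformity is the assumption, and it is genome-wide rather than
  transcript-weighted to keep the ratio test's null simple. At a TSS the
  expected RPP− density is exactly RPP+/enrichment (default 8×); elsewhere
  the two libraries share the same expected background. `library_depth`
  refers to RPP+; RPP− is correspondingly shallower.

**Noise.** Counts are per-position negative binomial with variance
μ + αμ² (α = `dispersion`, default 0.1); α = 0 degenerates to Poisson, and
`exact=True` returns the expected tracks unsampled. Because noise is
per-position, gene-level counts (sums over hundreds of positions) are much
tighter than a gene-level NB with the same α — the generator does **not**
model biological between-replicate dispersion, library-prep biases, rRNA
contamination, sequencing errors, or read-length effects. Recovery results
on this data therefore demonstrate correctness of the estimators, not
robustness to real biological variance.

**Determinism.** One master seed; each library draws from a child seed
derived via `SeedSequence([master, stream, condition, replicate])`, so any
library can be regenerated independently and bit-identically.

## Quantification

RPF reads are assigned by A-site (5' end + 17 nt toward 3' on the coding
strand; on the minus strand the shift is toward smaller coordinates) and
counted within codons 6…L/3−5; genes shorter than 11 codons have an empty
window and count 0 with a logged warning. RNA reads are counted by 5'-end
position in the gene body. "Total mapped reads" in the RPKM formula is the
per-sample sum of the gene-wise count table (the genome-wide total is
ambiguous when tracks contain intergenic signal); it is overridable.

Size factors are median-of-ratios in linear space: the reference is the
per-gene geometric mean over samples (genes nonzero in every sample), the
factor the median count/reference ratio. The differential test is a
two-sided binomial rate-ratio test on summed size-factor-normalized counts
— a deliberate simplification of a negative-binomial Wald test that keeps
the published thresholds (P_adj < 0.01, |log₂FC| > 1) while avoiding GLM
fitting; with the generator's per-position noise its calibration is
adequate, but on real data it will be anti-conservative because it ignores
between-replicate dispersion. Pseudocount 1 (normalized scale) before the
log₂ fold change.

## Translation efficiency

TE uses condition-mean RPKM across replicates; the expression floor is
RPKM_RNA ≥ 1 in a condition (no published floor exists; 1 RPKM is the
conventional "expressed" cut), and TE is additionally undefined where the
RPF level is 0. μ and σ of the log₂ TE-change distribution are the sample
moments (the deterministic equivalent of fitting a Gaussian curve; a
trimmed variant is available via the `trimmed` argument). Classification is
invariant to adding a constant to all changes, which matters because
compositional (fixed-depth) normalization shifts all log-ratios by a
constant. Class fractions are reported both over defined genes and over all
genes, since the denominator choice changes the headline percentages.

## TSS calling

A pseudo-density ε = 0.5 is added to both normalized tracks before the
RPP+/RPP− ratio so positions with zero untreated signal are scorable. The
density floor (default 10 counts-per-million) substitutes for manual
curation of peaks; because it is a relative threshold, its discriminating
power depends on the per-position background density — with a uniform
background of b cpm per position, false calls appear at the rate the NB
tail crosses 10 cpm, which for deep libraries and b ≲ 1 cpm is negligible.
Candidates must be local RPP+ maxima within ±4 nt. Merging is
single-linkage clustering of same-strand candidates within ±4 nt (chains
longer than 9 nt therefore merge; the alternative — splitting chains — is
not taken, and output records are verified pairwise > 4 nt apart, making
merge idempotent); the merged record sits at the position of highest summed
density, densities sum, supporting libraries union, and ties break to the
leftmost position.

Categorization: per gene, candidates on the same strand within <300 nt
upstream to ≤100 nt downstream of the start codon; the highest density is
primary, equal densities break toward the most upstream position; the rest
are secondary. A TSS serving several genes takes the best role
(P > S, then nearest start). Remaining TSSs inside a gene body are internal
(same strand) or antisense (opposite strand) — a same-strand containment
wins over antisense — and anything else is intergenic. The partition is
total: every record gets exactly one category.

5'-UTR length is the strand-aware TSS→start distance; negative distances
(primary TSSs within the 100-nt downstream window) are skipped with a
warning. UTRs shorter than 5 nt are flagged leaderless (no room for any SD
pairing in the scoring window).

## UTR analysis

Metagene profiles normalize each gene's window by its mean ORF density
before averaging so high expressors do not dominate; frame fractions come
from A-site counts within the trimmed ORFs. UTR occupancy uses per-nt
densities: UTR RPF/RNA from the TSS to the start codon (exclusive), CDS RPF
from the trimmed window, CDS RNA from the full ORF; UTRs shorter than 10 nt
are excluded and per-gene UTR vs CDS ratios are compared by two-tailed
Wilcoxon signed-rank (scipy's implementation, exact at small n). Per-gene
rather than pooled ratios are used so long UTRs do not dominate the
medians.

The internal folder is a Nussinov base-pair maximization (pairs AU/GC/GU,
minimum hairpin loop 3 nt) with energy proxy −(pairs); it is deterministic
and dependency-free but not thermodynamic, so the structured/unstructured
split defaults to the cohort median rather than an absolute −30 kcal/mol
cut, which only makes sense with an external folder (an RNAfold subprocess
wrapper is provided). SD scores slide the anti-SD 3'-CCUCCU-5' along the
−20…−5 window (relative to the start codon) and report the longest run of
Watson–Crick/GU-paired columns; AGGAGG scores 6. Windows truncated by short
UTRs are scored on the available span and flagged.

UTR/CDS occupancy medians on real deposited libraries (as opposed to the
generator's planted 0.5/1.4 contrast) are a manual validation, not an
automated test: they require the original sequencing data.

## Stoichiometry

CV is the sample (n−1) SD over the mean × 100 — "SD of the mean × 100" in
the figure-legend sense is read as the standard CV. The first/second operon
gene correlation is computed on log₁₀ levels, matching the log–log
presentation such data are shown in; RPKM (not size-factor-normalized
counts) is the input. Per-complex proportionality reports Pearson r, a
through-origin slope, and the max/min copy-number level ratio as a direct
stoichiometric-fold estimate.

## Problem sizes and defaults in the validation suite

Recovery checks run at desk scale, chosen so sampling error is well inside
the asserted tolerances: ~200 planted TSSs on a ~430 kb genome at 10⁶ reads
(TSS sensitivity/precision), 200 genes at 10⁶ reads (TE recovery and class
accuracy), 10⁴ draws (Gaussian tail), 10⁶ reads (frame periodicity), 500
sequences ≤12 nt (folding oracle), and an 80 kb / 50-gene end-to-end
determinism run. The acceptance script (`scripts/acceptance.py`) recomputes
all of these from a single seed.

## Known limitations

* No biological replicate dispersion, so differential-test calibration on
  real data is untested here.
* Transcript model is per-gene: an internal TSS's UTR overlapping an
  upstream gene adds density to that gene's counts (a real phenomenon, but
  the generator offers no operon-level transcript covering all members).
* The dRNA-Seq background is uniform; real processed-end background tracks
  expression and would make the ratio test noisier near abundant genes.
* The internal fold energy is a pair count; MFE-binned comparisons with it
  are rank-based only.
* The circular origin is never crossed by a gene, a UTR, or a promoter
  window.
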