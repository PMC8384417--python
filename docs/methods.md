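# Methods

## The pause statistic

Footprint 3' ends anchor the ribosome: in bacterial MNase libraries the 3'
boundary of the protected fragment is sharper than the 5' boundary, so the
position of each read is taken as its 3'-terminal nucleotide (rightmost
genomic coordinate on `+`, leftmost on `-`), regardless of read length.
Soft-clips and indels are handled by taking the aligned span on the
reference, not the raw read length.

The 3' end sits downstream of the decoded codon by a fixed geometric
offset. `ribopause` shifts the 3'-end track upstream by `asite_offset`
(default 15 nt) to place density on the first nucleotide of the A-site
codon. The 15 nt default reflects canonical bacterial footprint geometry
(~15 nt from the A-site codon's first nt to the ribosome's downstream
boundary); it is configurable per sample and is stamped into every pause
table, because the optimal value depends on nuclease and library chemistry.

For one codon occurrence the pause score is the A-site-shifted density at
the codon's first nucleotide divided by the gene's mean per-nt density.
Conventions, all configurable:

- **Edge trimming.** The first and last 7 codons of each ORF are excluded
  from the instance set *and* from the gene-mean denominator. Using the
  same interior for both keeps a strictly uniform track at score exactly 1.
- **Coverage filter.** Genes enter only with strictly more than 0.1 reads
  per codon on average. The threshold is in raw read units by design, so
  the filter is depth-dependent while the scores themselves are
  scale invariant (raw vs rpm tracks give identical tables).
- **Aggregation.** Unweighted mean over occurrences across genes — a gene
  with many occurrences contributes proportionally more, matching the
  "average over all instances" definition. Amino-acid rows pool all
  occurrences of the family's codons (not the mean of codon-level means;
  both views are emitted). Stop codons are never scored.
- **Overlapping genes** are flagged at load time and included by default;
  `exclude_overlaps` removes them for sensitivity analyses.

rpm denominators count the reads retained after length filtering and
bounds checks, i.e. the pipeline's own bookkeeping; this choice is recorded
in output metadata since conventions differ between published pipelines.

## Metagene profiles

Windows of gene-mean-normalized density are averaged over all occurrences
of a codon type, aligned at the codon's first nt (offset 0, positive =
downstream in the coding direction). Occurrences within the window of an
ORF edge contribute masked partial windows with per-offset denominators;
dropping them would bias short genes out of the profile. Default window
W = 50 nt. Peak calling is greedy local-maxima selection by height with a
minimum separation (scipy.signal.find_peaks); heights are normalized
densities without background subtraction.

Sign convention: a pause with the aligned codon in the A site peaks at 0.
If the ribosome translates on after lysis, the codon moves into the P and
then E site while the assigned density moves downstream, so run-on blurring
produces shoulders at +3 and +6. A stacked (collided) upstream ribosome
contributes density near −25, one footprint length upstream.

## Expression, occupancy, attenuation

RPKM = counts × 10⁹ / (total_mapped × length_nt); RO = ribo RPKM / RNA
RPKM, undefined (NaN-flagged) where the RNA signal is zero. Attenuation is
read out as the ratio of length-adjusted RNA densities between a leader
region and a downstream-gene region on the same strand; the regions are
user-supplied intervals (BED6), with scenario defaults of the leader ORF
vs the full downstream ORF (leu geometry) or its 5' half (ilv geometry),
since published analyses do not pin the exact windows. The ratio is
invariant to raw-vs-rpm units. Gene-set comparisons use RPKM ratios;
genes with a zero in either condition are excluded by default (a +0.5
pseudocount option exists) and the exclusion count is reported. P-values
are reported raw with set sizes — no multiple-testing machinery is
layered on top, and differential-expression calling (dispersion/shrinkage
estimators) is deliberately out of scope: externally produced gene lists
are the input.

## The generator

The simulator is the generative inverse of the statistic. Per gene:
transcript abundance is log-normal (default μ=0, σ=1 on the ln scale, a
typical spread for bacterial expression); codons are drawn i.i.d. from a
codon-usage law (default uniform over the 61 sense codons, which
equalizes statistical power across codon types — real usage is heavily
skewed and can be supplied); ORF lengths are uniform on 100–500 codons
(E. coli-like mean ~300). Ribosome positions are drawn per nucleotide
with dwell weight 1 everywhere except the first nt of enriched codons;
the 3' end is placed `asite_offset` nt downstream and the read length is
drawn independently (uniform 10–40 nt, or 24–40 nt for the high-Mg²⁺
arrest presets), mirroring 3'-end anchoring. Genes are laid head-to-tail
with 200 nt intergenic padding on alternating strands so read ends never
leave the reference and both strand geometries are exercised.

**Preset targets and the k-correction.** Presets store *target* recovered
pause scores per codon family (Pro CCN, Arg CGG, Leu CUA at the strain
values of a TrmD-depletion experiment: control 1.4/1.0/1.0, depletion
3.5/3.0/1.4, wild-type 1.2/1.0/1.0, knockout 2.5/3.0/1.4). Because the
score is normalized by the gene mean, which itself contains the enriched
positions, a dwell factor f at k occurrences in a gene of L interior nt
recovers only f·L/(L + k(f−1)). The generator therefore solves the
coupled per-gene system s_t = f_t·L/(L + Σ_u k_u(f_u − 1)), whose exact
solution is f_t = s_t(L − Σk)/(L − Σ_u k_u s_u). With that correction the
conditional expectation of every occurrence's score equals its target
exactly (the denominator is the realized interior read total, so the
ratio has no small-sample bias); recovery error is pure sampling noise,
≈ 0.01–0.05 at 200 genes / 10⁶ reads.

**Blur and collisions.** Run-on blurring advances each read by a
geometric number of codons (continuation probability p); collision mode
adds, with a given probability, an extra read 25 ± 2 nt upstream of each
read sitting on an enriched position. Both default to off — including in
the depletion presets, whose contract is exact recovery of the printed
pause-score targets; the unblurred statistic is the one the targets refer
to. The geometric run-on model is a deliberately simple artifact choice,
validated only qualitatively (peak splitting toward +3/+6); no
quantitative dwell model for P/E-site occupancy is claimed.

**Attenuation scenarios** build a two-gene operon (leader + downstream
gene sized after *leuL*/*leuA*: 87/1572 nt, or *ilvL*/*ilvG*: 99/1644 nt)
on top of 20 background genes; the leader is highly expressed (ln-scale
+3 above the expression-law mean) and the downstream abundance is leader
× readthrough. Preset readthrough probabilities are 1/29, 1/4, 1/45, 1/9
so that the expected fold-decrease equals the corresponding target.
RNA-seq 3' ends are uniform within each transcript at fixed 50 nt read
length.

**What the generator does not model:** sequence-dependent ligation/MNase
bias, base-calling errors, rRNA/tRNA contamination, multi-mapping, operon
co-transcription outside the attenuation pair, UTRs, and 5'-end
positional information. Passing recovery tests therefore demonstrates the
*statistical* correctness of the pipeline (estimator, filters, coordinate
arithmetic, normalization) under the stated generative assumptions — not
robustness to the full artifact spectrum of real libraries.

## Numerical and design notes

- Coordinates are 0-based half-open internally; WIG output is 1-based
  variableStep (one block per reference and strand) and round-trips
  byte-stably through the bundled reader. bedGraph output is 0-based.
- Internal alphabet is DNA; `U` is normalized to `T` at load, selectors
  accept either, tables report DNA triplets with an amino-acid column
  (bacterial translation table 11).
- A gene whose interior mean is zero, or that fails the coverage filter,
  is skipped whole; a zero at a scored position is a legal score of 0.
- Degenerate inputs fail loudly: empty read files, all-filtered read
  sets, regions overlapping each other, missing references, ORFs that are
  not a multiple of 3 (dropped with a logged reason).
- Determinism: every stochastic step derives from `numpy`'s
  `default_rng` seeded from the scenario seed via fixed stream offsets
  (transcriptome / footprints / RNA-seq / expression), so one seed fixes
  all outputs byte-identically.
- Problem sizes: tests and the acceptance script use ~200 genes and 10⁶
  reads per scenario — enough for standard errors of a few percent on
  every recovered statistic while keeping a full run to seconds.

## Known limitations

- The A-site offset is a single constant per sample; real offsets can
  vary with read length. With 3'-end assignment the variation is small,
  and the offset is exposed as configuration rather than estimated.
- Pause scores for codons occurring mostly in low-coverage genes are
  noisy; the table reports n so users can gate on it.
- The attenuation readout assumes the user-specified regions; it does not
  locate terminators or leader peptides itself.
- Single-exon (bacterial) gene models only.
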