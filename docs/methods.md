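# Methods

`translatekit` implements a translatome analysis protocol for paired
transcriptome (total RNA) and translatome (heavy-polysomal RNA) sequencing
of two conditions — here an enzalutamide-sensitive castration-resistant
prostate-cancer line ("CRPC") and its enzalutamide-resistant derivative
("ER") — together with the companion analyses that surround it: proteome
differential abundance, biotype enrichment, splicing-event
cross-classification, lncRNA ORF/Kozak analysis, and polysome-profile
quantification. This note records the models, the parameters that matter,
and the numerical choices made where the design was open.

## Translation efficiency

For a gene g, TE is its abundance in the translatome divided by its
abundance in the transcriptome, both in counts per million:

    TE(g) = CPM_polysomal(g) / CPM_total(g)

TE is evaluated under an **all-pairs replicate scheme**: with R
transcriptome and P translatome replicates in a condition, every
(transcriptome replicate i, translatome replicate j) pair contributes one
TE value, giving R x P values per gene per condition. Condition means of
these values form the **TE ratio** (resistant over sensitive); significance
comes from a two-sample Student (equal-variance) t-test on log2 TE values,
Benjamini–Hochberg adjusted across all tested genes. A gene is called `up`
when TE ratio > 1.25 and adjusted p <= 0.05, `down` when TE ratio < 1/1.25
with adjusted p <= 0.05, `unchanged` otherwise, and `untestable` when fewer
than two finite TE values remain in either condition or the statistic
degenerates (zero variance in both groups). Untestable genes are excluded
from the BH family.

Choices worth flagging:

- **Log-scale testing.** The t-test runs on log2(TE), which symmetrizes
  ratios; the equal-variance variant is used here, and Welch's unequal-
  variance test is reserved for the analyses that explicitly call for it
  (isoform-group and correlation comparisons).
- **Zeros.** A TE pair with transcriptome CPM of 0 is a missing value, not
  infinity; no pseudocounts are added by default. A configurable pseudo-CPM
  (suggested 0.5) can be added to both fractions instead.
- **Testability filter.** The default expression filter keeps genes with
  >= 5 CPM (inclusive) in both fractions, the same detection threshold used
  to select candidates for qPCR validation.
- **Known statistical property of the scheme.** The R x P pair values reuse
  replicates, so they are not independent samples; a t-test that treats
  them as independent underestimates the standard error of the mean log-TE
  difference (by about a factor of 2 at R = P = 3) and is therefore
  anti-conservative. In Monte-Carlo under a global null this scheme rejects
  far more often than its nominal level, and Benjamini–Hochberg adjustment
  does not repair miscalibrated inputs. The scheme is retained as specified
  because it is the protocol this package implements; the evaluation module
  (`translatekit.evaluation`) measures and reports the realized false-call
  rate rather than asserting nominal calibration. Users wanting calibrated
  inference should aggregate to per-replicate values or use an
  interaction-model approach.

Summaries report medians of log2 TE ratios over gene groups (all tested vs
significant-only; mRNA = protein_coding vs lncRNA = everything else), and
`concordance_fraction` computes overlap percentages between differential
gene sets (100 * |A intersect B| / |A|, nearest or floor rounding).

## Biotype and event-type enrichment

Enrichment of categories across datasets uses the classical independence
formula for expected counts — (row total x column total) / grand total — a
Pearson chi-squared statistic sum((obs - exp)^2 / exp) with
(rows-1)(cols-1) degrees of freedom, and per-cell standardized residuals
(obs - exp) / sqrt(exp), whose sign is the enrichment/depletion flag. No
Yates continuity correction is applied, including for 2x2 tables, so
results follow the plain formula; cells with expected counts under 5 are
annotated as a classical validity caveat, not rejected.

## Proteome differential abundance

Abundances come as a three-group design (parental VCaP, VCaP-CRPC,
VCaP-ER, three replicates each). Fold changes are ratios of group means;
p-values are two-sided equal-variance t-tests on log2 abundances for the
two ER comparisons (ER/VCaP, ER/CRPC). A protein is `up` when either ER
comparison exceeds 1.25-fold with p <= 0.05 (0.1 in the relaxed variant)
and the other ER comparison does not show a *thresholded* variation in the
opposite direction; `down` is symmetric. A sub-threshold opposite trend
does not veto — "variation" is read as a change passing both thresholds.
The CRPC/VCaP fold change is reported but never gates the call. Proteome
correlation against reference profiles (e.g. patient proteomes) computes
one Pearson or Spearman coefficient per (query replicate, reference
sample) over the shared protein identifiers with pairwise deletion, and
compares coefficient distributions between query lines by Student t-test.

## Splicing-event cross-classification

rMATS-style junction-count events (SE, MXE, A3SS, A5SS, RI) from the two
transcriptome-vs-translatome comparisons are filtered at p < 0.05 AND
|deltaPSI| > 0.1 (both strict), then classified by where they reach
significance: one comparison only, or both with equal / opposite deltaPSI
sign. Event identity across comparisons is the exact tuple (event type,
gene, full coordinates); a 1-bp difference is a distinct event. The sign
convention — deltaPSI = transcriptome inclusion minus translatome
inclusion — is fixed and recorded in output headers, since "same/opposite
direction" is only reproducible under a declared convention. SE and MXE
collapse to alternative exon choice (AEC), A3SS and A5SS to alternative
splice site (ASS), RI stays intron retention. Isoform-group abundance
comparisons (e.g. peptide-exon-retaining vs -skipping transcripts at the
JPX locus) use Welch's two-sided t-test on per-sample counts.

## ORFs and Kozak context

Transcript sequences are reconstructed by concatenating exon sequences
5'->3' (reverse-complemented on the minus strand). The ORF scanner reports
every forward-strand ATG with an in-frame stop codon (nested ATGs give
separate candidates, N-containing codon spans disqualify, stopless ORFs
are excluded unless requested); a minimum peptide length (default 10 aa)
suppresses trivia. The Kozak context is the 10-base window -6..+4 around
the ATG, rendered as RNA, N-padded when the ATG sits within 6 bases of the
5' end.

TIS (translation-initiation-site) scoring is a pluggable interface; any
callable mapping a context to [0, 1] can be used, including wrappers
around external predictors. The default scorer is an explicit
position-weight table over the six upstream positions and +4: the -3
purine and +4 G — the canonical strong-context determinants — carry double
weight, and the raw sum is min-max normalized so the Kozak consensus
GCCACCAUGG scores exactly 1.0 and the least-similar context 0.0. The
weights are documented in `orf_kozak.KozakWeightScorer.DEFAULT_WEIGHTS`
and are deliberately simple and tunable; scores from this table are on
their own scale and are not comparable to any external predictor's output.

## Polysome profiles

A digitized A254 trace is quantified as two trapezoidal areas above a
baseline set to the lowest point of the whole trace (not per-region): the
sub-polysomal region (40S/60S/80S peaks) and the polysomal region (first
to twelfth polysomal peak). Region boundaries are user-supplied — peak
detection on scanned charts is deliberately not automated. The summary
statistic is the polysomal / sub-polysomal area ratio; replicate ratios
are expressed as fold change over the *mean* of the reference group (the
per-matched-pair alternative is noted in output metadata), and the group
comparison is an exact two-sided Mann–Whitney U test, the conventional
nonparametric two-sample location test.

## Synthetic data

The generator emulates the study design so every stage is testable without
downloads: 2 conditions x 2 fractions x `n_reps` replicates (default 3) of
negative-binomial counts (variance mu + phi * mu^2, shared dispersion
phi = 0.1) over 2000 genes split 80/12/8% among protein_coding / lincRNA /
processed_transcript. Per-gene baseline means are lognormal
(log-mean 4.0, log-sd 1.0, i.e. a median of ~55 counts with a realistic
right tail); library sizes vary uniformly within 2-fold so CPM
normalization is genuinely exercised. Planted truth: 20% of mRNAs get a
-0.4 log2 TE shift and 15% of lncRNAs a +0.5 shift, applied to the
translatome mean in the resistant condition only; every gene's true log2
TE ratio is returned. The proteome table couples group means to the same
truth (ER proportional to baseline x 2^shift) with multiplicative
lognormal noise (sd 0.2 on the natural-log scale). Splicing-event tables
are generated category-first (significant events draw p ~ U(0, 0.05) and
|deltaPSI| ~ U(0.15, 0.6)), and transcript/ORF simulation plants exactly
one ATG per transcript with the requested -6..+4 context, so ORF recovery
is exact by construction.

What the generator does **not** emulate: gene-specific dispersions,
GC/length bias, isoform-level counts, correlated genes, batch effects, or
missingness patterns of real MS data. Passing recovery tests therefore
demonstrates that the estimators and rules behave as designed under their
own model, not that the pipeline is robust to every artifact of real data.

## Evaluation sizes and observed behavior

The benchmark module runs 100 simulated datasets per configuration at
2000 genes and 3 replicates: the study-condition shifts (-0.4/+0.5) for
median recovery and the lincRNA enrichment flag, a null configuration for
the false-call rate, and a |log2 shift| = 1 configuration for sensitivity.
Recovered medians land within ±0.1 of the planted shifts, and the lincRNA
over-representation in the TE-up set is flagged (positive residual) in
essentially every run. Because of the pseudo-replication discussed above,
the null false-call rate sits far above the nominal adjusted level, and
sensitivity for 2-fold shifts at 3 replicates and dispersion 0.1 is
limited by the true sampling error of the log-TE-ratio estimate
(~0.53 log2 units), not by the test alone; both realized values are
reported by `scripts/acceptance.py` rather than idealized.
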