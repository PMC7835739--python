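# Methods

This note describes the statistical procedures the package implements,
the synthetic data they are exercised on, and the numerical and design
choices behind both.

## The analysis

The package addresses transcript-level prognosis for a gene with
alternatively spliced isoforms: the same gene can carry transcripts
whose high expression predicts *opposite* survival outcomes, which gene-
level analysis averages away. The canonical example is pyruvate kinase
muscle type (*PKM*), whose dominant PKM2 transcript (~95% of the gene's
mRNA) and three minor isoforms split into favorable and unfavorable
pairs in kidney cancer. The pipeline chains:

1. **Preprocessing.** Gene expression is the sum of its transcripts'
   TPM values. Genes with mean TPM strictly above 1 across patients are
   analyzed; transcripts require mean TPM strictly above 5. The strict
   inequalities are deliberate: rows at the boundary are dropped.
2. **Optimal-cutoff survival stratification.** For each transcript,
   every distinct observed TPM value between the 10th and 90th
   percentiles (nearest-rank) is tried as a high/low threshold
   (high = strictly greater; ties go low); groups are compared by the
   two-group log-rank test (hypergeometric variance per distinct event
   time, chi-square(1) reference), and the cutoff minimizing the
   p-value is selected. The transcript is *unfavorable* when the
   high-expression group has more observed than expected events at the
   selected cutoff, *favorable* otherwise. No multiplicity correction
   is applied across the scan — min-p selection is anti-conservative by
   construction, and the package *measures* that inflation (a null
   simulation rejects at ~40–50% nominal 5%, n = 200) rather than
   correcting it, because reproducing the procedure is the point.
3. **Cox regression.** Univariate and multivariate proportional-hazards
   fits by Newton iteration on the Breslow partial likelihood (gradient
   tolerance 1e-8, 50-iteration cap, step-halving). Breslow is the
   simplest tie treatment and makes the score test at beta = 0 for a
   binary covariate identical to the log-rank chi-square on tie-free
   data — an identity the tests assert to 1e-8.
4. **Differential expression.** Patients in the top and bottom 25% of a
   transcript's expression are compared gene by gene: raw counts are
   normalized by median-of-ratios size factors, transformed to
   log2(x + 1), and tested with a two-sided Welch t test; BH adjustment
   controls FDR, significance at FDR < 1e-5. This is a deliberately
   dependency-light replacement for shrinkage-based count models; it
   controls type-I error on the synthetic surface (asserted within two
   binomial SEs of 5% over 2000 null genes) but makes no parity claim
   with negative-binomial engines. The log2 pseudocount bounds the
   transform at zero counts; its cost is that library-size invariance
   holds to ~1e-4 in p rather than exactly.
5. **Overlap and concordance.** Two DEG lists of sizes L1 and L2 from a
   background of L genes, sharing k genes of which s agree in
   direction, are scored by the cumulative hypergeometric tail
   P = 1 − Σ_{i<s} C(L2,i)·C(L−L2,L1−i)/C(L,L1) and the concordance
   score s/k. The formula plugs the direction-consistent count s into a
   plain overlap null; a purist null for joint overlap-and-direction
   would differ, but the printed procedure is implemented as printed
   and the alternative only noted here. For cross-cohort comparison the
   top 20% of each DEG table (smallest p; ties by |log2FC|, then gene
   id) is used. The tail is evaluated in log space (log-gamma binomial
   coefficients, log-sum-exp over at most min(L1, L2) terms); linear-
   scale values below 1e-300 are reported as that strict upper bound
   with the exact log10 magnitude retained, mirroring how such tails
   are printed as floating-point floors (p < 1.11e-16).
6. **Enrichment summaries.** One-sided hypergeometric
   over-representation of up- and down-regulated DEGs against flat GMT
   gene sets intersected with the per-cohort universe (genes passing
   the mean-TPM filter), BH across terms, significance at FDR < 0.001.
   Per-term cross-cohort summaries: *generality* = number of cohorts
   enriched in either direction, *direction* = up-enriched minus
   down-enriched cohort counts; the display filter keeps terms with
   generality strictly above 10 (configurable, and left at 0 in the
   two-cohort demo where it would otherwise hide everything).
   No GO-hierarchy propagation: sets are flat.
7. **P-value clustering.** Log-rank p-value matrices are transformed to
   −log10, and rows/columns are clustered with Spearman correlation
   distance (1 − rho) under Ward.D2 linkage (scipy's `ward` on a
   precomputed condensed distance implements exactly that update).
   Constant rows have undefined correlation; their distance is defined
   as 1 to everything, with a warning.
8. **Risk signature.** Each signature transcript contributes its
   scan-selected cutoff and a risk side — *below* for favorable
   transcripts, *above* for unfavorable ones. Votes use strict
   inequalities, so a value exactly at the cutoff never votes
   high-risk. A sample is high-risk when at least 2 transcripts vote
   (the threshold is a parameter, default 2, so signatures of other
   sizes reuse the rule). Risk groups are compared by log-rank.
9. **Protein annotation.** Amino-acid length and average molecular mass
   (average residue masses + one water, reported in kDa to 0.1) for
   transcript protein products. Average rather than monoisotopic mass
   because gel band positions are read on the average scale. The
   reference sequences are not bundled: `scripts/fetch_protein_fixtures.py`
   retrieves the five transcript products from Ensembl once, after
   which the annotation checks against the published lengths/masses
   run; sequences are never invented.

## The synthetic cohorts

`splice_prognosis.simulate` generates the data every stage is tested
on. It emulates the features the analysis relies on, with a known
ground truth:

* **A focal gene dominated by one transcript.** Transcript TPMs are
  log-normal: a shared per-sample gene factor (sigma 0.4, natural-log
  scale) times mean-corrected transcript noise. The dominant transcript
  (share 0.95, sigma 0.25) tracks the gene; minor isoforms (shares
  0.013–0.020, sigma 0.5) vary more independently, reflecting that
  splicing regulation is only loosely coupled to overall gene
  expression. An early draft with a stronger shared factor made all
  isoform z-scores ~0.8-correlated, so opposite-sign hazards nearly
  cancelled and the vote rule degenerated; the final defaults encode
  the realistic structure. The default gene mean is 520 TPM, giving
  minor-isoform means of ~7–10 TPM (above the mean-TPM > 5 filter).
* **Proportional-hazards survival.** Event times are exponential with
  rate lambda0 · exp(Σ beta_t · z_t), where z_t is the within-cohort
  z-score of log transcript TPM. Defaults: lambda0 = 1/1500 per day
  (median overall survival around three years, typical of kidney-cancer
  cohorts) and log-hazards ±0.7 — two favorable (dominant + one minor)
  and two unfavorable transcripts. With all betas zero the generator is
  an exact null for the scan, which is how the scan's inflation is
  measured.
* **Right-censoring.** Independent exponential censoring whose rate is
  calibrated by bisection so the expected censored fraction matches the
  configured 50% (TCGA-like overall-survival follow-up).
* **Gene modules.** 2000 background log-normal genes (mean TPM
  log-uniform in 2–100), four 40-gene modules shifted by
  direction · 0.8 · z(driver) log2-units plus N(0, 0.5) module noise —
  the structure the DEG, overlap and enrichment stages recover.
* **Counts.** TPM times a per-sample library factor (uniform 25–35),
  rounded — rank-concordant with TPM by construction.
* **Cohort pairs.** The validation cohort is regenerated with
  independent noise streams and baseline expression rescaled by 1.6
  (emulating an independent cohort measured on a shifted scale, the way
  replication cutoffs differ between cohorts); all effect *signs* are
  shared. Randomness is organized as named sub-streams of one seed (per
  cohort, transcript, module and stage), so adding a feature never
  shifts existing draws, and identical seeds give bit-identical output.

What the generator does **not** emulate: batch effects, tumor purity,
copy-number confounding, read-level noise, overdispersed counts, and
correlated background genes. Passing tests therefore demonstrate that
the procedures are implemented correctly and recover planted structure
under clean conditions — not that the biological findings would
replicate on real cohorts.

## Verification strategy

Every statistical primitive is checked against an independent oracle:
the log-rank test against hand risk-set arithmetic, lifelines, and a
10,000-draw permutation null (agreement within Monte-Carlo error plus
the ~0.01–0.02 finite-sample gap of the chi-square reference at
n = 20); Kaplan–Meier against lifelines; Cox against lifelines on
tie-free data (lifelines has no Breslow option, so tie handling is
covered by the score-test/log-rank identity instead) and against
derived sampling bands (±2.2–2.4 asymptotic SEs, since SE ≈ sqrt(4/n)
for a balanced binary covariate); the overlap tail against exact
rational arithmetic for every configuration with L ≤ 30; BH against a
by-definition sort/scale/cumulative-min oracle; enrichment against
scipy's one-sided Fisher exact test.

End-to-end, with two cohorts of 300 and log-hazards ±0.7, the pipeline
recovers all four prognostic directions and separates risk groups at
log-rank p < 0.01 in both cohorts in well over 90% of 100 replicates.
Problem sizes throughout (300 patients/cohort, 2000 background genes,
100–1000 Monte-Carlo replicates) were chosen as the smallest giving
stable rates; all are configurable.

## Known limitations

* Min-p cutoff selection is reported uncorrected, exactly as the
  procedure defines it; its p-values are not calibrated and should be
  read as rank scores.
* The Welch-on-log-counts DE test loses power against low-count,
  overdispersed genes relative to negative-binomial models.
* The overlap formula's null ignores the direction-flip component of
  consistency (see above); its tail is conservative relative to a
  compound null.
* Flat gene sets only; no GO ancestry.
* The background gene count L for cross-cohort overlaps must be
  supplied by the caller; it is the number of genes commonly tested in
  both cohorts.
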