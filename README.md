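# splice-prognosis

Transcript-level prognostic analysis for genes with alternatively
spliced isoforms — built for the situation where one gene's transcripts
carry *opposite* survival signals that gene-level analysis averages
away (the textbook case being *PKM*, whose dominant PKM2 transcript and
three minor isoforms split into favorable and unfavorable pairs in
kidney cancer).

The package is aimed at computational biologists who have
transcript-level expression matrices (TPM + counts), clinical follow-up
tables, and gene sets, and want the full chain as reusable, tested
components:

* **Optimal-cutoff Kaplan–Meier stratification** — for a transcript
  with expression x, every distinct observed value v between the 10th
  and 90th percentiles is tried as a threshold (high: x > v); the
  cutoff minimizing the two-group log-rank p is selected, and the
  transcript is called unfavorable iff the high group has more observed
  than expected events. The min-p selection is anti-conservative by
  construction; the package measures that inflation instead of hiding it.
* **Cox proportional hazards** (Newton on the Breslow partial
  likelihood) for univariate/multivariate confirmation.
* **Differential expression** between top/bottom 25% expression strata
  (median-of-ratios normalization, Welch t on log2(x+1), BH FDR).
* **Cumulative hypergeometric overlap** of two DEG lists with the
  concordance score s/k: for lists of sizes L1, L2 from a background of
  L genes with s direction-consistent shared genes,
  `P = 1 − Σ_{i<s} C(L2,i)·C(L−L2,L1−i)/C(L,L1)`, evaluated in log
  space so tails around 10⁻⁵⁰⁰ keep their exact magnitude.
* **Hypergeometric gene-set enrichment** with cross-cohort
  generality/direction summaries, and Ward.D2 clustering of −log10
  p-value matrices on Spearman correlation distance.
* **A majority-vote risk signature**: each transcript votes high-risk
  strictly below its cutoff (favorable transcripts) or strictly above
  it (unfavorable); ≥ 2 votes ⇒ high-risk.
* **A synthetic two-cohort generator** with planted transcript hazards,
  gene modules and right-censoring, so the whole chain is testable
  end-to-end with known ground truth and no external data.

The scan and the signature are sklearn-style estimators
(`CutoffSurvivalScanner`, `RiskSignatureClassifier`) that compose with
sklearn tooling; everything else is plain functions over pandas
containers.

## Worked example

Run the packaged two-cohort demo (simulation → preprocessing → scans →
signature → DEG → overlap → enrichment):

```bash
splice-prognosis run-all --seed 11 --out results/demo
```

which logs, among other things:

```
cohort A scan window 10-90 pct: {'TX1': 'favorable@303 (p=5.6e-07)',
  'TX2': 'favorable@8.27 (p=1.6e-06)', 'TX3': 'unfavorable@4.59 (p=0.021)',
  'TX4': 'unfavorable@10.2 (p=5.6e-05)'}
cohort A signature (votes >= 2): log-rank p = 3.5e-14
cohort B signature (votes >= 2): log-rank p = 5.71e-07
overlap TX1: k=191 s=176 concordance=0.921 log10p=-35.31
```

Reading this: in cohort A the scan calls the dominant transcript TX1
and minor transcript TX2 favorable (high expression protective) and
TX3/TX4 unfavorable — matching the planted log-hazard signs — and picks
the TPM cutoff for each (e.g. 303 TPM for TX1). The derived 4-transcript
signature separates high- from low-risk patients at log-rank p ≈ 3×10⁻¹⁴
and replicates in the independent cohort B. Of the top-20% DEG lists
driven by TX1 in the two cohorts, 191 genes are shared and 176 agree in
direction (concordance 0.92), an overlap with hypergeometric tail
10⁻³⁵·³ against the 2001-gene background.

Each stage is also a standalone subcommand over plain TSV/JSON files
(`simulate`, `prep`, `scan`, `deg`, `overlap`, `enrich`, `signature`,
`annotate`), so external tables — e.g. a DEG list from another engine —
can be dropped in at any boundary. As a library:

```python
import numpy as np
from splice_prognosis import CutoffSurvivalScanner

scanner = CutoffSurvivalScanner().fit(tpm_values, np.c_[time_days, event])
scanner.cutoff_, scanner.p_value_, scanner.direction_
```

## Protein annotation fixtures

Length/mass annotation of the PKM transcript protein products checks
against the published values (531/485/457/366 aa; 58.1/57.9/53.0/49.9/
40.2 kDa). The reference sequences are not bundled; fetch them once
with network access:

```bash
python scripts/fetch_protein_fixtures.py   # writes data/pkm_proteins.fa
```

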