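# sizenipt

Size-based noninvasive prenatal testing (NIPT) of fetal trisomies 13, 18
and 21 from maternal-plasma cell-free DNA fragment-length counts.

## The problem

A pregnant woman's plasma carries cell-free DNA (cfDNA) from two sources:
her own cells and the placenta. The placental ("fetal") component is a
minority — typically 5–20% of fragments — and is systematically
**shorter** than the maternal component (fetal mode ≈ 143 bp vs the
maternal mononucleosomal mode ≈ 166 bp). If the fetus carries a trisomy,
fragments from the affected chromosome are over-represented in proportion
to the fetal fraction. Restricting the analysis to a short-fragment window
enriches the fetal signal and makes that over-representation easier to
detect.

`sizenipt` is aimed at people building or evaluating count-based NIPT
pipelines: it computes the statistics, makes the calls, scores them, finds
the optimal fragment-size window, and simulates labelled cohorts with
known ground truth so that everything is testable without patient data.

## The method

For a sample with fragment counts indexed by chromosome and length:

* **Chromosome proportion** (computed over the 22 autosomes by default;
  sex chromosomes are excluded because fetal sex is unknown):

      P_chrN = Sum_chrN / Sum_all

* **Size-filtered ratio** for a target chromosome N ∈ {13, 18, 21},
  with both proportions restricted to a window w (80–155 bp by default):

      R_chrN = P(w)_chrN / P(w)_chrother ,

  where "other" is the 19 autosomes excluding chr13/18/21. The shared
  denominator cancels, so R is the exact quotient of in-window counts.

* **z-score** against a panel of 30 randomly chosen euploid training
  samples (sample SD, n−1):

      z_chrN = (x_chrN − mean_training) / SD_training

Two calling protocols are provided: the *full-range proportion* protocol
(whole length domain, positive when z > 3.5) and the *size-filtered ratio*
protocol (80–155 bp window, positive when z > 2.5). Cutoffs are strict.
Performance is scored one-vs-rest per trisomy as sensitivity and
specificity.

The **two-stage boundary search** recovers the window itself: it scans
lower bounds 30–130 bp (10 bp steps) with the upper bound provisionally at
150 bp, then upper bounds 150–170 bp (5 bp steps) at the chosen lower
bound, and finally refines the lower bound at 1 bp resolution (75–85 bp).
At each candidate window the ratio classifier is evaluated with a shared
training partition; per trisomy the candidates maximizing
sensitivity + specificity form an optimal set, the three sets are
intersected ("AND"), and ties are broken toward the wider window.

## Worked example

Simulate a cohort shaped like a real study (21 T13, 27 T18, 36 T21, 60
euploid pregnancies; 2×10⁵ fragments/sample; fetal fraction uniform on
[0.08, 0.15]), call trisomies with the size-filtered protocol, and search
for the best window:

```sh
$ sizenipt simulate --out cohort.csv --seed 7 --depth 200000
wrote 144 samples to cohort.csv

$ sizenipt call --table cohort.csv --preset size-filtered --seed 7 --outdir calls
chr13: sensitivity=1.000 specificity=1.000 (TP=21 FP=0 TN=93 FN=0)
chr18: sensitivity=1.000 specificity=1.000 (TP=27 FP=0 TN=87 FN=0)
chr21: sensitivity=1.000 specificity=0.987 (TP=36 FP=1 TN=77 FN=0)

$ sizenipt search --table cohort.csv --seed 7 --outdir search
selected window: 75-160 bp
```

Reading the output: 30 of the 60 euploid samples form the training panel;
the remaining 114 samples are tested. Every trisomic sample is detected
(sensitivity 1.000 per target) and one unaffected sample crosses the 2.5
cutoff on chr21 (specificity 77/78 = 0.987) — with purely multinomial
counting noise the null z-scores are approximately standard normal, so
occasional values above 2.5 among ~258 negative tests are expected. The
search window is written to `search/window.txt` together with the full
per-candidate sensitivity/specificity grid (`search/grid.csv`); every
command also writes a `manifest.json` sufficient to reproduce the run.

The same operations are available as library functions
(`sizenipt.simulate_cohort`, `run_protocol`, `two_stage_search`, ...), and
fragment-size tables can be derived from paired-end SAM/BAM with
`sizenipt extract` or loaded from long CSV/TSV and spreadsheet dialects
with `read_size_table`.

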