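# Methods

## Statistics and calling model

Let `c[N, l]` be a sample's count of cfDNA fragments mapped to chromosome
N with template length l (bp). For a fragment-length window
`w = [lower, upper]` (both ends inclusive):

* proportion: `P(w)_N = Σ_{l∈w} c[N,l] / Σ_{M∈D} Σ_{l∈w} c[M,l]` over a
  denominator set D;
* ratio (targets N ∈ {chr13, chr18, chr21}):
  `R(w)_N = Σ_{l∈w} c[N,l] / Σ_{M∈other} Σ_{l∈w} c[M,l]`, with *other*
  the 19 autosomes excluding the three targets.

Both are standardized against a euploid training panel:
`z = (x − mean_train) / sd_train`, with the sample (n−1) SD. A sample is
called positive for trisomy N when z exceeds the protocol cutoff
*strictly* (full-range proportion protocol: 3.5; size-filtered ratio
protocol: 2.5; ties are negative).

**Denominator policy.** D defaults to the 22 autosomes. Sex-chromosome
counts depend on fetal sex, which is generally unknown and would add
variance unrelated to trisomy; they are kept on I/O and excluded from the
statistics. The all-chromosome denominator remains available through the
`included_chroms` argument. Because the ratio's two proportions share a
denominator, R reduces to an integer-count quotient and is exactly
scale-invariant; P is scale-invariant to floating-point precision.

**Training panel.** 30 euploid samples drawn without replacement by a
seeded generator (`ProtocolConfig.seed`); an explicit id list is accepted
so a fixed panel can be pinned. With n = 30 the distinction between the
n−1 and n SD conventions shifts z by ~1.7%; the unbiased n−1 convention
is used throughout. A zero training SD is flagged and any z-score against
it raises rather than returning ±inf.

**Outlier policy.** Optionally (`replace_with_training_mean`, default
off), a test statistic whose |z| exceeds 6 on a chromosome other than the
sample's own trisomy is replaced by the training mean before calling;
every replacement is logged and returned in the result. This makes an
otherwise ad-hoc manual step reproducible and auditable.

## Window search

Stage 1 scans lower bounds 30–130 bp in 10 bp steps with the upper bound
fixed at 150 bp; stage 2 scans upper bounds 150–170 bp in 5 bp steps at
the stage-1 lower bound; an optional fine stage rescans the lower bound at
75–85 bp in 1 bp steps (on by default, disable with
`fine_lower_candidates=None`). All candidates share one training
partition so that grid cells differ only in the window.

The per-trisomy optimality criterion is the Youden-style maximum of
sensitivity + specificity; the optimal *set* is the whole argmax plateau.
The three sets are intersected; within the intersection the candidate with
the highest summed sensitivity + specificity across trisomies is selected,
ties broken toward the wider window (smaller lower / larger upper bound),
since a wider window retains more fragments and hence less counting
noise. An empty intersection falls back to the summed argmax over all
valid candidates, with a warning. A scan in which no candidate ranks above
any other (exact total tie, or zero sensitivity everywhere — e.g. fetal
fraction 0) is *degenerate*; if both coarse stages are degenerate the
search returns the configured fallback window (80–155 bp) and warns
instead of pretending the tie-break was informative. Candidates that
empty some sample's window are excluded with a recorded reason. The full
grids are returned with the result, so the selection is reproducible from
the audit trail alone.

## Synthetic cohorts

Each sample is a two-origin mixture. With fetal fraction f, chromosome
weights b (maternal) and b_fet (fetal; the affected autosome multiplied by
the trisomy dosage 1.5 and renormalized), and length distributions g_m,
g_f, the intensity of cell (N, origin, l) is

    (1−f)·b_N·g_m(l)   and   f·b_fet,N·g_f(l).

Counts are a single multinomial draw of the configured depth over all
cells (exactly normalized); independent per-cell Poisson counting is
available via `counting="poisson"`.

Defaults (the study conditions used by the test suite):

| parameter | default | rationale |
|---|---|---|
| class sizes | 21 T13 / 27 T18 / 36 T21 / 60 euploid | composition of the reference cohort |
| depth | 5×10⁵ fragments/sample | shallow-WGS scale |
| fetal fraction | Uniform(0.08, 0.15) | mid clinical range; below ~5% no count-based method is reliable |
| maternal lengths | discretized N(166, 9) on [60, 400] | mononucleosomal peak |
| fetal lengths | discretized N(143, 9) on [60, 400] | fetal fragments stochastically shorter |
| trisomy dosage | 1.5 | three copies vs two, fetal component only |
| baseline autosome props | 0.7·genome-length + 0.3·uniform blend | places every autosome in the ~2–9% band seen in mapped-read data |
| sex chromosomes | total weight 0.05 per origin, random fetal sex | exercises the autosomes-only policy |
| overdispersion σ | 0 | pure counting noise; see below |

Maternal and fetal sex-chromosome weights are equal in total, so the
autosome-conditional chromosome distribution has the exact closed form

    E[P_N] = (1−f)·Lm·b_N + f·Lf·b_fet,N  (normalized over autosomes),

with Lm, Lf the window masses of the two length distributions.
`expected_statistic` implements this algebra; it is exact for the
proportion (conditionally on the autosome total, counts are multinomial)
and first-order (ratio of expectations) for R, with relative bias
O(1/count) that is negligible against Monte-Carlo error at the depths
used. It requires a fixed fetal fraction and zero overdispersion.

An optional per-sample, per-chromosome lognormal jitter
(`overdispersion_sigma`) emulates uncorrected technical variation
(GC/mappability bias differing between samples). It is applied
identically to both origins and renormalized. The window-recovery studies
use σ = 0.04 together with a maternal length mixture
0.75·N(166, 9) + 0.25·Uniform(30, 170) (mononucleosome peak plus a
degradation floor) and fetal lengths Uniform(85, 150): without a short
maternal background, widening the window below 80 bp costs nothing and
every candidate ties; without overdispersion, z-scores saturate far above
the cutoff and the scan cannot rank candidates.

**What the simulations do and do not show.** The generator reproduces the
mixture mechanism the method relies on — dosage on the affected
chromosome, scaled by fetal fraction and enriched by size selection — so
passing tests demonstrate that the statistics, calling rules and search
recover known signal under realistic noise magnitudes. Real cfDNA
additionally shows a 10 bp nucleosomal periodicity, GC and mappability
bias, duplicate structure, and heavier-tailed between-sample variation;
none of these are modelled (the method consumes window sums, for which
periodicity is irrelevant, but real-data specificity depends on bias
correction upstream of this package). One consequence is worth stating
plainly: any z statistic standardized against a finite euploid panel has
an approximately normal null, so with a cutoff of 2.5 about 0.6–1% of
unaffected tests exceed it by chance. Perfect specificity over hundreds
of null tests is therefore a lucky draw, not a reproducible property, at
any depth — on simulated cohorts the size-filtered protocol's
per-target specificity is typically 97–100%, with sensitivity 100% at
fetal fractions ≥ 8%.

## Numerical and interface choices

* Windows are inclusive on both ends; `--range LOWER:UPPER` mirrors this.
* Restriction to a window that empties a sample raises a
  degenerate-sample error naming the sample.
* Long tables sum duplicate (sample, chromosome, length) rows on read;
  write-then-read is the exact identity on valid tables.
* Chromosome names are normalized to `chr`-prefixed form (`21` ≡ `chr21`).
* SAM/BAM extraction counts each template once, from the mate with
  strictly positive TLEN; fragments outside the configured length window
  are dropped, not clipped. Defaults: MAPQ ≥ 30, proper pairs, duplicates
  removed, lengths 30–600 bp (covering every scanned window).
* The spreadsheet loader is driven by a small YAML layout declaration
  (sheet name and column roles), editable without code changes because
  supplementary spreadsheet layouts drift.
* Fetal fraction 0 is accepted as the zero-signal limit for null studies.
* All randomness (cohort generation, training-panel selection) flows from
  explicit integer seeds; identical config + seed gives bit-identical
  cohorts, calls and search results.

## Problem sizes in the test suite

The suite simulates cohorts of 14–144 samples at depths of 2×10⁴–5×10⁵
fragments; the multi-seed studies (20 seeds each) use the full 144-sample
shape at 5×10⁵. The whole suite runs in about a minute on one CPU.

## Known limitations

* No GC or mappability correction; counts are taken as given.
* No fetal-fraction estimation: f is known in simulation and unused in
  calling (cutoffs are fixed, not f-aware).
* No mosaicism, no joint modelling of multiple aneuploidies (targets are
  called independently; a sample can be positive for more than one).
* The search scans boundaries one at a time (the two-stage traversal),
  not the full 2-D grid; with strongly non-separable optima the staged
  scan can settle on a local ridge.
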