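# liquidfrac

Tumor-fraction estimation from low-pass whole-genome sequencing of
cell-free DNA, together with the cohort-level statistics used to compare
ctDNA against PSMA-PET tumor burden in prostate cancer.

## Who this is for

Circulating tumor DNA (ctDNA) is the tumor-derived subset of plasma
cell-free DNA (cfDNA). In prostate cancer, where copy-number variation
(CNV) is a genomic hallmark, the ctDNA fraction of a plasma sample can be
read out from shallow (~0.1–1×) whole-genome sequencing: aligned reads are
counted in fixed 500 kb genomic bins, and segmental shifts of the per-bin
copy ratio reveal both the tumor's CNV landscape and the fraction `tf` of
tumor-derived molecules. This package implements that estimator, a
synthetic-data generator that produces bin counts at known tumor fraction
(so every stage can be validated against ground truth), and the
discovery-rate / correlation / survival statistics of a 130-patient
PET-vs-ctDNA comparison whose count tables ship with the package.

## The model

The observed count in bin *b* is negative binomial,

```
x_b ~ NB(mean = w_b · ((1 − tf)·2 + tf·c_b) / P̄,  size = r)
```

where `w_b` is the expected count under a copy-neutral model (after
library-size and GC-bias normalization), `c_b ∈ {0,1,2,3,4}` is the tumor
copy number, and `P̄` is the genome-average mixture ploidy — the centring
term expressing that read counts carry only *relative* copy ratio.
Estimation proceeds by:

1. **Normalization** — LOESS regression of count on GC, ratios re-centred
   to weighted mean 1; extreme bins (8 MAD) excluded.
2. **Density initialization** — the gap between the dominant mode and the
   nearest secondary mode of the copy-ratio density gives `tf₀ = 2·|m₁ − m₀|`
   under a one-copy-change model.
3. **NB-HMM decoding** — forward–backward posterior decoding of `c_b`
   over copies {0..4}, chromosome breaks resetting the chain; per-state
   priors anchor the modal state at copy-neutral.
4. **Fraction refit** — bounded 1-D maximum likelihood for `tf` given the
   decoded states; steps 3–4 alternate until `|Δtf| < 10⁻³`. A sample
   whose first decode finds no CNVs gets one re-decode at the default
   fraction 0.05 before being called negative.
5. **QC gates** — the fitted model must beat a permuted-bin noise model
   in a Kolmogorov–Smirnov comparison of absolute residuals (keep when
   p ≤ 0.05), and calls whose deletions are predominantly
   peri-centromeric are excluded as technical artifacts.

## Worked example

```bash
python analysis/01_simulate_samples_and_cohort.py
python analysis/02_estimate_tumor_fractions.py
python analysis/03_cohort_statistics.py
```

The first script simulates eight bin-count samples (3,077 bins over
chromosomes 1–8, mean depth 500 reads/bin) at tumor fractions
{0, 0.1, 0.2, 0.4} plus a 130-patient cohort. The second runs the
estimator on each sample and prints:

```
 sample_id  true_tf  est_tf         status  iterations         ks_p  abs_error
  S000_tf0      0.0  0.0000   not_detected           0          NaN     0.0000
  S001_tf0      0.0  0.0000   not_detected           0          NaN     0.0000
S002_tf0.1      0.1  0.1356 excluded_noise          11 8.639870e-02     0.0356
S003_tf0.1      0.1  0.1028 excluded_noise          11 3.588490e-01     0.0028
S004_tf0.2      0.2  0.2030       detected          13 2.895057e-42     0.0030
S005_tf0.2      0.2  0.2039       detected          16 1.307491e-20     0.0039
S006_tf0.4      0.4  0.3968       detected           9 4.475960e-49     0.0032
S007_tf0.4      0.4  0.3875       detected           7 5.613421e-70     0.0125

median |tf_hat - tf| over tf>0 samples: 0.0036
null samples called detected: 0/2
```

Reading this: both null samples are correctly negative; fractions 0.2 and
0.4 are recovered to within ~0.01 and pass the noise gate (tiny KS p);
the two 0.1 samples are estimated accurately but fall below the KS gate's
power at this genome size, so they are conservatively excluded — exactly
the behaviour the gate is designed for. The third script recomputes the
reference discovery statistics (PET-positivity odds ratio 0.31 with 95%
CI [0.13, 0.74] between castration-resistant and hormone-sensitive
patients, p = 0.013; ctDNA discovery not status-dependent, p = 0.311) and
runs the Spearman/ROC/Kaplan–Meier/Cox battery on the simulated cohort.

A CLI mirrors the library: `liquidfrac estimate --counts sample.tsv
--seed 17 --out call.json`, plus `simulate`, `cohort-stats`, `run` and
`fixtures` subcommands.

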