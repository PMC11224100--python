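# Methods

## The estimation problem

A plasma cfDNA sample is a mixture: a fraction `tf` of molecules derive
from tumor cells whose genome carries segmental copy-number alterations,
the rest from diploid normal cells. After counting aligned reads in 500 kb
bins, the expected count of bin *b* is proportional to the mixture copy
number `m_b(tf) = (1 − tf)·2 + tf·c_b`, with `c_b` the integer tumor copy
number. Total-count sequencing carries no absolute-ploidy anchor, so only
the *relative* profile `m_b / P̄` is observable, where `P̄` is the
genome-average of `m_b`. This is the root identifiability problem: a
one-copy loss at fraction `tf` and a two-copy loss at `tf/2` produce the
same relative mean, and a wholesale relabelling of all states by ±1 copy
can likewise mimic a different fraction. The estimator's design — density
initialization, per-state priors, alias restarts — exists to resolve this
degeneracy.

## Normalization

Raw counts are scaled by library size, then divided by a robust LOESS fit
(statsmodels `lowess`, frac = 0.3, 3 robustness iterations) of count on GC
fraction; with fewer than 1,000 usable bins the fit falls back to medians
within GC deciles. Bins deviating from the median ratio by more than
8 MAD are excluded (keeping index alignment), and ratios are re-centred
so their expected-count-weighted mean is exactly 1. The per-bin expected
neutral count `w_b` (the fitted GC curve) becomes the emission weight of
the HMM, so high-GC bins with systematically fewer reads contribute
proportionally less evidence.

## Dispersion

A single NB size parameter `r` is estimated by method of moments from the
central 80% of included ratios: the trimmed variance is divided by the
central-80% truncation factor of a normal (0.4377), the average sampling
variance `mean(1/w_b)` is subtracted, and the excess inverted. When CNVs
occupy part of the central window the estimate is biased low (more
overdispersion assumed), which is conservative for state calling. Samples
with no excess variance get `r = 10⁶` (effectively Poisson).

## Density initialization

A Gaussian KDE (Silverman bandwidth) of the included ratios is scanned
for local maxima. The dominant mode is taken as copy-neutral; the nearest
secondary mode with density ≥ 10% of the peak gives the initial fraction
`tf₀ = 2·|m₁ − m₀|` (one-copy-change model, clipped to [0.01, 0.95]).
Profiles with no qualifying secondary mode — including samples whose
alterations are too sparse to form a mode — start from the default
fraction 0.05 instead.

## Copy-number decoding and fraction refit

States {0, 1, 2, 3, 4} are decoded by forward–backward over a stationary
chain with per-bin stay probability 1 − 10⁻³ (uniform off-diagonal);
chromosome boundaries reset the chain to its stationary (uniform)
distribution. Emissions are negative binomial with mean
`w_b · m_b(tf)/P̄` evaluated through the gamma-function form so
non-integer working counts are handled; excluded bins contribute a flat
emission, keeping the chain intact across gaps. Posterior (marginal)
decoding is used rather than Viterbi — per-bin argmax with ties broken
toward copy 2.

Per-state log-priors (default 0 for copy 2, −0.1 for 1 and 3, −0.3 for
0 and 4) are added to every included bin's emission. They act like a
segment-length-proportional penalty against non-neutral and extreme
states, anchoring the modal state at copy-neutral and breaking the
relabelling degeneracy described above. The magnitudes are small relative
to one bin's worth of likelihood at readily detectable fractions, so they
decide ties, not clear calls.

Given states, `tf` is refit by bounded 1-D likelihood maximization on
[0, 1] (tolerance 10⁻⁴). Decode and refit alternate until
`|Δtf| < 10⁻³` (max 20 iterations). The tracked objective is the
penalized conditional log-likelihood; because per-bin posterior argmax
does not mathematically guarantee ascent, a decode that lowers the
objective is rejected and the previous iterate kept — the reported
trajectory is therefore monotone by construction. After convergence the
two alias partners of the solution (`2·tf` and `tf/2`) are refit from
scratch and the best penalized objective wins; without this step roughly
a third of high-fraction samples in our simulations converged to the
half-fraction relabelling.

A sample whose first decode yields no non-neutral segment gets exactly
one re-decode at the default fraction 0.05; if still neutral the sample
is reported `not_detected` with `tf = 0`.

## Quality gates

**Permuted-bin noise gate.** Primary residuals are `ratio − fitted ratio`
per included bin. Each of 3 noise replicates shuffles the (ratio, weight)
pairs across bin positions — destroying segmental structure while keeping
the marginal distribution — and re-runs the full fit on the shuffled
profile; its residuals are pooled. A two-sample KS test compares absolute
residual distributions; the call is kept only when the primary model
beats noise significantly (p ≤ 0.05). Under an exchangeable null the
shuffle changes nothing and the gate rejects; with true segmental signal
the noise model cannot absorb the displaced bins and its residuals are
visibly wider. The KS p-value uses the exact (permutation) null when
`n_a·n_b ≤ 10⁴`, the asymptotic Kolmogorov distribution otherwise.

**Centromere-artifact filter.** The share of called deletion bins lying
on or within 2 Mb of a centromere-flagged bin is computed; a sample whose
share exceeds 0.5 ("predominantly peri-centromeric deletions") is
excluded as a likely technical artifact.

Status semantics: `not_detected` (no CNVs, tf reported 0),
`excluded_noise`, `excluded_artifact`, `detected`.

## Synthetic data

The count generator draws from the estimator's own model family:
alternating neutral/altered segments with geometric lengths (altered mean
10 Mb; neutral gaps scaled so the expected altered genome share hits its
target), altered copies drawn from weights over {0, 1, 3, 4}, NB counts
at mean depth 500 reads/bin with size 1000 (per-bin ratio noise
sd ≈ 0.055 — realistic for ~0.2× coverage in 500 kb bins), and a
quadratic GC-bias curve peaking near GC 0.45. GC fractions are i.i.d.
Beta(mean 0.41, sd 0.05); real GC tracks are spatially autocorrelated and
real data contain mappability artifacts, replication-timing waves and
fragment-length effects that this generator deliberately omits — passing
recovery tests therefore validate the inference machinery under its
stated model, not robustness to every real-world bias.

The cohort generator emulates a 130-patient PET/ctDNA prostate-cancer
population: a ~55% castration-resistant share; log-normal PSA per status;
zero-inflated log-normal PSMA tumor volume (PET-positive share 68%/87%);
zero-inflated log-normal ctDNA concentration (detected 25%/35%); a
Gaussian copula linking the ctDNA and tumor-volume margins, with the
copula correlation set as `ρ = 2·sin(π·ρ_s/6)` to hit a target Spearman
`ρ_s` on continuous margins (zero inflation ties shrink the realized
value, and status-driven mean shifts add correlation on top — the
calibration checks therefore use a status-homogeneous, fully continuous
configuration); and exponential survival with log-hazard increments for
the above-median ctDNA and tumor-volume groups (defaults ln 7.56 and
ln 6.65), uniform censoring on (0.2, 49.5) months. Exponential event
times make configured hazard ratios exactly recoverable by Cox
regression at large n.

## Cohort statistics conventions

- 2×2 tables use the Yates continuity correction; larger tables the
  uncorrected Pearson statistic. This combination reproduces the
  reference tables' printed p-values exactly.
- Odds-ratio intervals are Woolf log-normal with z = 1.96;
  Haldane–Anscombe +0.5 on zero cells (flagged).
- PSA strata are left-open/right-closed, e.g. (0, 0.5].
- Dunn post-hoc z-tests (tie-corrected rank variance, Bonferroni
  multiplied) run only when the global Kruskal–Wallis test rejects at 5%.
- ROC thresholds maximize Youden's J over observed scores; J-ties break
  toward the higher threshold (higher specificity). AUC is the
  tie-corrected Mann–Whitney statistic.
- Survival grouping splits at the in-cohort median; ties at the median go
  to the low group. Kaplan–Meier, logrank and Cox (Breslow ties, Wald
  intervals) are computed through lifelines.

## Numerical and scale choices

Forward–backward runs in scaled linear space (log-space emissions,
per-step renormalization), so chains of tens of thousands of bins are
stable. The recovery experiments in the test suite use the ~5,750-bin
autosome lattice at mean depth 500, 20% genome altered, 20 replicates per
fraction and 200 null replicates; the acceptance script uses 10/60
replicates — sizes chosen so each stage's sampling error is comfortably
below the tolerances being checked. Seeds fan out from one global seed
through a counter-based `SeedSequence` scheme so adding samples never
perturbs earlier ones, and identical configurations produce byte-identical
reports.

## Known limitations

- Subclonal (non-integer) copy states, allelic imbalance and
  fragmentomics are out of scope; state 4 absorbs all high gains.
- The fraction is unidentifiable in a genuinely CNV-free tumor; such
  samples are reported `not_detected` regardless of true ctDNA content.
- The KS gate's power grows with genome size and alteration burden: at a
  few hundred bins, true fractions below ~0.15 are often (correctly,
  given the evidence) excluded as indistinguishable from noise.
- Dispersion is shared across bins; locus-specific noise is not modelled.
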