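"""Tumor-fraction estimation from low-pass WGS bin counts.

The estimator treats the observed per-bin read count as a negative-binomial
draw whose mean is proportional to the *relative* copy ratio of a mixture
of diploid background and tumor-derived DNA:

    mean_b = w_b * ((1 - tf) * 2 + tf * c_b) / Pbar

where ``w_b`` is the bin's expected count under the neutral model (after
library-size and GC normalization), ``c_b`` is the integer tumor copy
number of bin b, ``tf`` is the tumor fraction of the sample, and ``Pbar``
is the genome-average mixture ploidy — the centring term that encodes the
fact that total-count data carry no absolute-ploidy anchor.

Copy-number states are decoded with a negative-binomial hidden Markov
model (forward-backward posterior decoding over copies {0..4}), and the
fraction is re-fit by bounded 1-D likelihood maximization given the
decoded states; the two steps alternate until the fraction stabilizes.
Samples whose first decode finds no alterations get one re-decode at a
default fraction of 0.05 before being called negative. A call is kept
only when the fitted model beats a permuted-bin noise model in a
Kolmogorov–Smirnov comparison of absolute residuals, and when called
deletions are not predominantly peri-centromeric (a technical-bias
signature).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .genome_bins import BinGrid, BinCounts

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# containers


@dataclass
class NormalizedProfile:
    """Per-bin copy-ratio estimates for one sample (1 = diploid average)."""

    ratio: np.ndarray        # copy-ratio estimate per bin
    weight: np.ndarray       # expected count under the neutral model
    excluded: np.ndarray     # masked / invalid-GC / outlier bins
    chromosome: np.ndarray   # chromosome label per bin (chain breaks)
    centromere_flag: np.ndarray
    bin_size: int
    sample_id: str = "sample"

    @property
    def included(self) -> np.ndarray:
        return ~self.excluded

    def n_included(self) -> int:
        return int(np.sum(~self.excluded))

    def permuted(self, rng: np.random.Generator) -> "NormalizedProfile":
        """Noise-model twin: ratio/weight pairs shuffled across included bins."""
        idx = np.flatnonzero(~self.excluded)
        perm = rng.permutation(idx)
        ratio = self.ratio.copy()
        weight = self.weight.copy()
        ratio[idx] = self.ratio[perm]
        weight[idx] = self.weight[perm]
        return replace(self, ratio=ratio, weight=weight,
                       sample_id=self.sample_id + ":permuted")


@dataclass
class StatePath:
    """Decoded copy-number states with per-bin posteriors."""

    state: np.ndarray                 # integer copies per bin
    posterior: np.ndarray             # (n_bins, n_states)
    states: tuple[int, ...]           # state set, e.g. (0,1,2,3,4)
    segments: list[tuple[str, int, int, int]]
    log_likelihood: float             # marginal loglik of the chain

    def n_altered(self, included: np.ndarray | None = None) -> int:
        alt = self.state != 2
        if included is not None:
            alt &= included
        return int(np.sum(alt))


@dataclass
class FractionEstimate:
    """Final call for one sample: fraction, states, QC verdict."""

    tumor_fraction: float
    status: str                       # detected|not_detected|excluded_noise|excluded_artifact
    iterations: int
    converged: bool
    log_likelihood: float
    qc: dict
    path: StatePath | None = None
    profile: NormalizedProfile | None = None
    history: list = field(default_factory=list)
    sample_id: str = "sample"

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "tumor_fraction": round(float(self.tumor_fraction), 6),
            "status": self.status,
            "iterations": self.iterations,
            "converged": self.converged,
            "log_likelihood": round(float(self.log_likelihood), 4),
            "qc": {k: (None if v is None or (isinstance(v, float) and math.isnan(v))
                       else round(float(v), 6)) for k, v in self.qc.items()},
            "history": self.history,
        }


@dataclass
class EstimatorConfig:
    """Tunable parameters of the fraction estimator."""

    tf_default: float = 0.05      # reinjected fraction when no CNVs found
    ks_alpha: float = 0.05        # KS gate: keep when p <= alpha
    max_iter: int = 20
    tf_tol: float = 1e-3          # |delta tf| convergence threshold
    stay_prob: float = 1 - 1e-3   # HMM per-bin self-transition probability
    states: tuple[int, ...] = (0, 1, 2, 3, 4)
    #: per-bin log-prior per state; favors copy-neutral and penalizes the
    #: extreme states, breaking the tf/2tf relabelling degeneracy of
    #: ratio-only data (a one-copy loss at fraction tf and a two-copy loss
    #: at tf/2 give identical means)
    state_prior: tuple[float, ...] = (-0.3, -0.1, 0.0, -0.1, -0.3)
    dispersion: float | None = None   # NB size; None = estimate from data
    k_mad: int = 8                # outlier cut in MADs
    n_permutations: int = 3       # noise-model replicates pooled for KS
    artifact_threshold: float = 0.5   # peri-centromeric deletion share
    centromere_window: int = 2_000_000  # bp around flagged bins
    min_qc_bins: int = 50
    run_qc: bool = True
    seed: int = 0


# ---------------------------------------------------------------------------
# normalization


def normalize_counts(counts: BinCounts, grid: BinGrid) -> NormalizedProfile:
    """Library-size and GC normalization of raw bin counts.

    Steps: (i) scale by total included reads; (ii) divide each count by
    its expected value under a robust local regression (LOESS) of count on
    GC — or GC-decile medians when fewer than 1,000 bins are available;
    (iii) exclude bins more than ``k·MAD`` (k = 8) from the median ratio;
    (iv) re-centre so the weighted mean ratio over included bins is 1.
    """
    if len(counts) != grid.n_bins:
        raise ValueError("counts not aligned with grid")
    x = counts.counts.astype(float)
    valid_gc = np.isfinite(grid.gc) & (grid.gc > 0) & (grid.gc <= 1)
    included = ~grid.mask_flag & valid_gc
    if int(np.sum(included)) < 100:
        raise ValueError("need >= 100 unmasked bins with positive GC annotation")
    if not np.any(x[included] > 0):
        raise ValueError("empty sample")

    gc = grid.gc
    if np.sum(included) >= 1000:
        order = np.argsort(gc[included])
        fit = lowess(x[included][order], gc[included][order],
                     frac=0.3, it=3, return_sorted=False)
        expect = np.full(grid.n_bins, np.nan)
        expect[np.flatnonzero(included)[order]] = fit
    else:
        deciles = np.nanquantile(gc[included], np.linspace(0, 1, 11))
        deciles[0], deciles[-1] = -np.inf, np.inf
        idx = np.digitize(gc, deciles) - 1
        expect = np.full(grid.n_bins, np.nan)
        for d in range(10):
            sel = included & (idx == d)
            if np.any(sel):
                expect[sel] = np.median(x[sel])
    bad = included & ~(expect > 0)
    included &= expect > 0

    ratio = np.full(grid.n_bins, np.nan)
    ratio[included] = x[included] / expect[included]
    med = np.median(ratio[included])
    mad = np.median(np.abs(ratio[included] - med))
    k = EstimatorConfig.k_mad
    if mad > 0:
        outlier = included & (np.abs(ratio - med) > k * mad)
        included &= ~outlier
    # re-centre to weighted mean 1 (weights = expected neutral counts)
    w = expect
    centre = np.average(ratio[included], weights=w[included])
    ratio = ratio / centre
    weight = np.where(np.isfinite(expect), expect * centre, 0.0)
    return NormalizedProfile(
        ratio=ratio, weight=weight, excluded=~included,
        chromosome=grid.chromosome, centromere_flag=grid.centromere_flag,
        bin_size=grid.bin_size, sample_id=counts.sample_id)


def estimate_dispersion(profile: NormalizedProfile) -> float:
    """Method-of-moments NB size from the central 80% of included ratios.

    The trimmed variance is rescaled by the central-80% truncation factor
    of a normal (0.4377), the per-bin sampling variance 1/w is subtracted,
    and the remainder inverted into a size parameter. Returns a large size
    (near-Poisson) when no excess variance remains.
    """
    r = profile.ratio[profile.included]
    w = profile.weight[profile.included]
    lo, hi = np.quantile(r, [0.1, 0.9])
    core = r[(r >= lo) & (r <= hi)]
    var = np.var(core) / 0.4377  # central-80% normal truncation factor
    excess = var - np.mean(1.0 / w)
    if excess <= 1e-8:
        return 1e6
    return float(np.clip(1.0 / excess, 10.0, 1e6))


# ---------------------------------------------------------------------------
# density-based initialization


def initial_fraction_from_density(profile: NormalizedProfile) -> float | None:
    """Initial fraction from the modes of the copy-ratio density.

    A Gaussian KDE (Silverman bandwidth) of the included ratios is scanned
    for local maxima. Under a one-copy-change model the neutral mode sits
    at ratio 1 and a one-copy loss/gain at 1 -/+ tf/2, so the gap between
    the dominant mode and the nearest secondary mode with density >= 10%
    of the peak gives tf0 = 2*|m1 - m0|, clipped to [0.01, 0.95]. Returns
    None when no qualifying secondary mode exists.
    """
    r = profile.ratio[profile.included]
    if len(r) < 10 or np.std(r) == 0:
        return None
    try:
        kde = stats.gaussian_kde(r, bw_method="silverman")
    except np.linalg.LinAlgError:
        return None
    xs = np.linspace(np.min(r), np.max(r), 512)
    d = kde(xs)
    peaks = np.flatnonzero((d[1:-1] > d[:-2]) & (d[1:-1] >= d[2:])) + 1
    if len(peaks) < 2:
        return None
    main = peaks[np.argmax(d[peaks])]
    others = [p for p in peaks if p != main and d[p] >= 0.10 * d[main]]
    if not others:
        return None
    m1 = xs[min(others, key=lambda p: abs(xs[p] - xs[main]))]
    tf0 = 2.0 * abs(m1 - xs[main])
    return float(np.clip(tf0, 0.01, 0.95))


# ---------------------------------------------------------------------------
# NB emission and HMM decoding


def _nb_loglik(x: np.ndarray, mean: np.ndarray, size: float) -> np.ndarray:
    """Continuous-x negative binomial log-density (gamma-function form)."""
    mean = np.clip(mean, 1e-12, None)
    return (special.gammaln(x + size) - special.gammaln(size)
            - special.gammaln(x + 1.0)
            + size * np.log(size / (size + mean))
            + x * np.log(mean / (size + mean)))


def _mixture_means(tf: float, states: Sequence[int]) -> np.ndarray:
    return (1.0 - tf) * 2.0 + tf * np.asarray(states, dtype=float)


def _mean_mixture_ploidy(tf: float, state_per_bin: np.ndarray,
                         included: np.ndarray) -> float:
    mix = (1.0 - tf) * 2.0 + tf * state_per_bin.astype(float)
    return float(np.mean(mix[included]))


def decode_states(
    profile: NormalizedProfile,
    tf: float,
    stay_prob: float = 1 - 1e-3,
    dispersion: float = 100.0,
    states: tuple[int, ...] = (0, 1, 2, 3, 4),
    reference_states: np.ndarray | None = None,
    state_prior: Sequence[float] | None = None,
) -> StatePath:
    """Posterior-decode per-bin copy states with an NB hidden Markov model.

    The chain runs left to right within each chromosome and resets to its
    stationary distribution (uniform, since the transition matrix is
    symmetric) at chromosome breaks. Emission for state c at bin b is NB
    with mean ``w_b * ((1-tf)*2 + tf*c) / Pbar`` and shared ``dispersion``;
    ``Pbar`` is the genome-average mixture ploidy of ``reference_states``
    (all-neutral when absent). ``state_prior`` log-weights (optional) are
    added to every included bin's emission; the default estimator uses
    them to anchor the modal state at copy-neutral. Posteriors come from
    forward-backward in scaled space; the per-bin argmax is tie-broken
    toward copy 2.
    """
    if not 0.0 <= tf <= 1.0:
        raise ValueError("tf outside [0,1]")
    K = len(states)
    n = len(profile.ratio)
    included = profile.included
    if reference_states is None:
        pbar = 2.0
    else:
        pbar = _mean_mixture_ploidy(tf, reference_states, included)
    x = np.where(included, profile.ratio * profile.weight, 0.0)
    means = np.outer(profile.weight, _mixture_means(tf, states) / pbar)
    logem = _nb_loglik(x[:, None], means, dispersion)
    if state_prior is not None:
        logem = logem + np.asarray(state_prior, dtype=float)[None, :]
    logem[~included] = 0.0  # missing data: uniform emission keeps the chain intact

    posterior = np.zeros((n, K))
    loglik = 0.0
    state_arr = np.asarray(states)
    chrom = profile.chromosome
    breaks = np.flatnonzero(np.concatenate(
        ([True], chrom[1:] != chrom[:-1], [True])))
    stay = stay_prob
    move = (1.0 - stay) / (K - 1)
    for s0, s1 in zip(breaks[:-1], breaks[1:]):
        em = np.exp(logem[s0:s1] - logem[s0:s1].max(axis=1, keepdims=True))
        m = s1 - s0
        alpha = np.empty((m, K))
        c = np.empty(m)
        a = em[0] / K
        c[0] = a.sum()
        alpha[0] = a / c[0]
        for t in range(1, m):
            pred = stay * alpha[t - 1] + move * (1.0 - alpha[t - 1])
            a = em[t] * pred
            c[t] = a.sum()
            alpha[t] = a / c[t]
        beta = np.empty((m, K))
        beta[-1] = 1.0
        for t in range(m - 2, -1, -1):
            b = em[t + 1] * beta[t + 1]
            beta[t] = (stay * b + move * (b.sum() - b)) / c[t + 1]
        post = alpha * beta
        post /= post.sum(axis=1, keepdims=True)
        posterior[s0:s1] = post
        loglik += float(np.sum(np.log(c))
                        + np.sum(logem[s0:s1].max(axis=1)))

    # argmax with ties broken toward the neutral state
    best = posterior.max(axis=1)
    tied = posterior >= best[:, None] - 1e-12
    pref = np.abs(state_arr - 2)  # neutral first, then nearest to neutral
    choice = np.argmin(np.where(tied, pref, np.inf), axis=1)
    decoded = state_arr[choice]

    segments = _merge_segments(profile, decoded)
    return StatePath(state=decoded, posterior=posterior, states=tuple(states),
                     segments=segments, log_likelihood=loglik)


def _merge_segments(profile: NormalizedProfile,
                    state: np.ndarray) -> list[tuple[str, int, int, int]]:
    """Merge equal-state runs per chromosome; coordinates from bin index."""
    chrom = profile.chromosome
    bs = profile.bin_size
    chrom_start: dict[str, int] = {}
    prev = None
    for i, c in enumerate(chrom):
        if c != prev:
            chrom_start[c] = i
            prev = c
    segs: list[tuple[str, int, int, int]] = []
    n = len(state)
    run = 0
    for i in range(1, n + 1):
        if i == n or chrom[i] != chrom[run] or state[i] != state[run]:
            base = chrom_start[chrom[run]]
            segs.append((str(chrom[run]), (run - base) * bs,
                         (i - base) * bs, int(state[run])))
            run = i
    return segs


# ---------------------------------------------------------------------------
# fraction fitting


def _conditional_loglik(profile: NormalizedProfile, state: np.ndarray,
                        tf: float, dispersion: float) -> float:
    included = profile.included
    pbar = _mean_mixture_ploidy(tf, state, included)
    mix = (1.0 - tf) * 2.0 + tf * state.astype(float)
    mean = profile.weight * mix / pbar
    x = profile.ratio * profile.weight
    return float(np.sum(_nb_loglik(x[included], mean[included], dispersion)))


def fit_fraction(profile: NormalizedProfile, path: StatePath,
                 dispersion: float, tol: float = 1e-4) -> float:
    """Maximum-likelihood tumor fraction given fixed copy states.

    Bounded 1-D search of the NB log-likelihood over tf in [0, 1]
    (tolerance 1e-4). Raises when every included bin is neutral — the
    fraction is unidentifiable without at least one altered bin.
    """
    if path.n_altered(profile.included) == 0:
        raise ValueError("fraction unidentifiable: all states neutral")
    from scipy.optimize import minimize_scalar
    obj = lambda tf: -_conditional_loglik(profile, path.state, tf, dispersion)
    fit = minimize_scalar(obj, bounds=(0.0, 1.0), method="bounded",
                          options={"xatol": tol})
    return float(fit.x)


# ---------------------------------------------------------------------------
# QC


def ks_two_sample(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sample KS test: D = sup |ECDF_a - ECDF_b|.

    Uses the exact (permutation) null distribution when n_a * n_b <= 10,000
    and the asymptotic Kolmogorov distribution otherwise.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty sample")
    method = "exact" if len(a) * len(b) <= 10_000 else "asymp"
    res = stats.ks_2samp(a, b, method=method)
    return float(res.statistic), float(res.pvalue)


def centromere_artifact_flag(path: StatePath, grid: BinGrid,
                             window: int = 2_000_000,
                             threshold: float = 0.5) -> tuple[float, bool]:
    """Share of called deletion bins that are peri-centromeric.

    Peri-centromeric means the bin itself is centromere-flagged or lies
    within ``window`` bp of a flagged bin on the same chromosome. A sample
    is flagged as an artifact when this share exceeds ``threshold``
    (deletions predominantly at centromeres suggest technical bias).
    Returns (share, flag); zero deletions give (0.0, False).
    """
    deletion = path.state < 2
    if not np.any(deletion):
        return 0.0, False
    reach = int(np.ceil(window / grid.bin_size))
    near = grid.centromere_flag.copy()
    for sl in grid.chrom_slices().values():
        flags = grid.centromere_flag[sl]
        if not np.any(flags):
            continue
        idx = np.flatnonzero(flags)
        ext = np.zeros(sl.stop - sl.start, dtype=bool)
        for i in idx:
            ext[max(0, i - reach):i + reach + 1] = True
        near[sl] |= ext
    share = float(np.sum(deletion & near) / np.sum(deletion))
    return share, share > threshold


def residual_qc(
    profile: NormalizedProfile,
    path: StatePath,
    tf: float,
    dispersion: float,
    config: EstimatorConfig,
    seed: int,
) -> dict:
    """Permuted-bin noise gate for a fitted call.

    Primary residuals are ratio minus fitted ratio per included bin. Each
    noise replicate shuffles the bin order of the profile (destroying the
    segmental structure while keeping the marginal count distribution),
    re-runs the full fraction/CNV fit on the shuffled profile, and collects
    its residuals. A two-sample KS test compares the absolute residual
    distributions; the call is kept only when it beats noise significantly
    (p <= ks_alpha).
    """
    included = profile.included
    if int(np.sum(included)) < config.min_qc_bins:
        raise ValueError("profile too short for QC")
    pbar = _mean_mixture_ploidy(tf, path.state, included)
    fitted = ((1.0 - tf) * 2.0 + tf * path.state.astype(float)) / pbar
    primary = profile.ratio[included] - fitted[included]

    rng = np.random.default_rng(seed)
    noise_parts = []
    for _ in range(config.n_permutations):
        perm_profile = profile.permuted(rng)
        est = _fit_sample(perm_profile, config, dispersion, alias_check=False)
        if est.path is None:
            fit_perm = np.ones(len(perm_profile.ratio))
        else:
            pb = _mean_mixture_ploidy(est.tumor_fraction, est.path.state, included)
            fit_perm = ((1.0 - est.tumor_fraction) * 2.0
                        + est.tumor_fraction * est.path.state) / pb
        noise_parts.append(perm_profile.ratio[included] - fit_perm[included])
    noise = np.concatenate(noise_parts)
    d, p = ks_two_sample(np.abs(primary), np.abs(noise))
    return {
        "ks_statistic": d,
        "ks_p": p,
        "residual_sd_primary": float(np.std(primary)),
        "residual_sd_noise": float(np.std(noise)),
    }


# ---------------------------------------------------------------------------
# the iterative estimator


def _penalized_objective(profile: NormalizedProfile, state: np.ndarray,
                         tf: float, dispersion: float,
                         config: EstimatorConfig) -> float:
    """Conditional NB loglik plus the per-bin state log-prior."""
    obj = _conditional_loglik(profile, state, tf, dispersion)
    if config.state_prior is not None:
        prior = dict(zip(config.states, config.state_prior))
        obj += float(sum(prior[int(s)] for s in state[profile.included]))
    return obj


def _alternate(profile: NormalizedProfile, tf: float, path: StatePath,
               config: EstimatorConfig, dispersion: float,
               history: list) -> tuple[float, StatePath, float, int, bool]:
    """Decode/fit coordinate ascent from a starting (tf, path).

    Returns (tf, path, objective, iterations, converged). The tracked
    objective is the penalized conditional log-likelihood; a decode step
    that lowers it is rejected (previous iterate kept), which keeps the
    ascent monotone.
    """
    converged = False
    iterations = 0
    obj_prev = -np.inf
    best_tf, best_path = tf, path
    for it in range(config.max_iter):
        iterations = it + 1
        tf_new = fit_fraction(profile, path, dispersion)
        obj = _penalized_objective(profile, path.state, tf_new, dispersion,
                                   config)
        history.append({"iteration": iterations, "tf": round(tf_new, 6),
                        "objective": round(obj, 3),
                        "n_altered": path.n_altered(profile.included)})
        if obj < obj_prev - 1e-9:
            # coordinate-ascent safeguard: a decode that lowered the
            # objective is rejected and the previous iterate kept
            converged = True
            break
        best_tf, best_path, obj_prev = tf_new, path, obj
        if abs(tf_new - tf) < config.tf_tol:
            converged = True
            tf = tf_new
            break
        tf = tf_new
        new_path = decode_states(profile, tf, config.stay_prob, dispersion,
                                 config.states, reference_states=path.state,
                                 state_prior=config.state_prior)
        if new_path.n_altered(profile.included) == 0:
            converged = True
            break
        path = new_path
    return best_tf, best_path, obj_prev, iterations, converged


def _fit_sample(profile: NormalizedProfile, config: EstimatorConfig,
                dispersion: float,
                alias_check: bool = True) -> FractionEstimate:
    """Density init + decode/fit alternation, without the QC gate.

    After convergence the alias partners of the solution (half and double
    the fitted fraction — indistinguishable through one-copy/two-copy
    relabelling on ratio-only data) are refit and the best penalized
    objective wins.
    """
    history: list[dict] = []
    tf0 = initial_fraction_from_density(profile)
    used_default = tf0 is None
    tf = config.tf_default if tf0 is None else tf0
    history.append({"stage": "init", "tf": round(tf, 6),
                    "source": "default" if used_default else "density"})

    path = decode_states(profile, tf, config.stay_prob, dispersion,
                         config.states, state_prior=config.state_prior)
    if path.n_altered(profile.included) == 0 and not used_default:
        # fallback: reinject the default fraction once and re-decode
        tf = config.tf_default
        used_default = True
        history.append({"stage": "default_reinjection", "tf": tf})
        path = decode_states(profile, tf, config.stay_prob, dispersion,
                             config.states, state_prior=config.state_prior)
    if path.n_altered(profile.included) == 0:
        history.append({"stage": "final", "tf": 0.0, "note": "no CNVs"})
        return FractionEstimate(
            tumor_fraction=0.0, status="not_detected", iterations=0,
            converged=True, log_likelihood=path.log_likelihood,
            qc={}, path=path, profile=profile, history=history,
            sample_id=profile.sample_id)

    tf, path, obj, iterations, converged = _alternate(
        profile, tf, path, config, dispersion, history)

    if alias_check:
        for tf_alt in (2.0 * tf, 0.5 * tf):
            tf_alt = float(np.clip(tf_alt, 0.01, 0.95))
            if abs(tf_alt - tf) <= config.tf_tol:
                continue
            alt_path = decode_states(profile, tf_alt, config.stay_prob,
                                     dispersion, config.states,
                                     state_prior=config.state_prior)
            if alt_path.n_altered(profile.included) == 0:
                continue
            history.append({"stage": "alias_restart", "tf": round(tf_alt, 6)})
            a_tf, a_path, a_obj, a_it, a_conv = _alternate(
                profile, tf_alt, alt_path, config, dispersion, history)
            iterations += a_it
            if a_obj > obj + 1e-6:
                tf, path, obj, converged = a_tf, a_path, a_obj, a_conv
                history.append({"stage": "alias_accepted", "tf": round(tf, 6)})
    return FractionEstimate(
        tumor_fraction=float(tf), status="fitted", iterations=iterations,
        converged=converged, log_likelihood=obj, qc={},
        path=path, profile=profile, history=history,
        sample_id=profile.sample_id)


def estimate_ctdna(counts: BinCounts, grid: BinGrid,
                   config: EstimatorConfig | None = None) -> FractionEstimate:
    """Full pipeline for one sample: normalize, fit, QC-gate.

    Status semantics: ``not_detected`` (no CNVs even after the default-
    fraction reinjection; fraction reported as 0), ``excluded_noise``
    (model does not beat the permuted-bin noise model at the KS gate),
    ``excluded_artifact`` (deletions predominantly peri-centromeric), or
    ``detected``.
    """
    config = config or EstimatorConfig()
    profile = normalize_counts(counts, grid)
    dispersion = config.dispersion or estimate_dispersion(profile)
    est = _fit_sample(profile, config, dispersion)
    if est.status == "not_detected":
        return est

    qc: dict = {"dispersion": dispersion}
    status = "detected"
    assert est.path is not None
    share, artifact = centromere_artifact_flag(
        est.path, grid, config.centromere_window, config.artifact_threshold)
    qc["centromere_deletion_share"] = share
    if config.run_qc:
        qc.update(residual_qc(profile, est.path, est.tumor_fraction,
                              dispersion, config, config.seed))
        if qc["ks_p"] > config.ks_alpha:
            status = "excluded_noise"
    if artifact:
        status = "excluded_artifact"
    if status != "detected":
        log.warning("sample %s excluded by QC: %s", est.sample_id, status)
    est.status = status
    est.qc = qc
    est.history.append({"stage": "qc", "status": status})
    return est
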