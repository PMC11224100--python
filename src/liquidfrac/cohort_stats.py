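"""Comparative statistics for biomarker-discovery cohorts.

Covers the study-level analyses: contingency tests on discovery rates
(chi-squared with/without Yates correction, Fisher exact, Woolf odds-ratio
intervals), rank statistics (Kruskal–Wallis with Dunn–Bonferroni post-hoc,
Spearman correlation), ROC/Youden threshold selection, and survival
analysis (Kaplan–Meier with logrank, multivariate Cox with Breslow ties).

Conventions fixed here: 2×2 chi-squared defaults to the Yates continuity
correction while larger tables use the uncorrected Pearson statistic; PSA
strata are left-open/right-closed; median splits send ties to "low".
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test


@dataclass
class ContingencyTable:
    """Labelled integer cross-tabulation."""

    cells: np.ndarray
    row_labels: list[str]
    col_labels: list[str]

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=np.int64)
        if self.cells.ndim != 2:
            raise ValueError("cells must be 2-D")
        if self.cells.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("labels do not match cell dimensions")
        if np.any(self.cells < 0):
            raise ValueError("negative cell count")

    def row_percentages(self) -> np.ndarray:
        totals = self.cells.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(totals > 0, 100.0 * self.cells / totals, 0.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.cells, index=self.row_labels,
                            columns=self.col_labels)


def chi_squared_test(table: ContingencyTable | np.ndarray,
                     yates: bool = False) -> tuple[float, int, float]:
    """Pearson chi-squared test of independence.

    The Yates continuity correction (|O-E| - 0.5, floored at 0) is applied
    only when requested *and* the table is 2×2.
    """
    cells = table.cells if isinstance(table, ContingencyTable) else np.asarray(table)
    if cells.shape[0] < 2 or cells.shape[1] < 2:
        raise ValueError("need at least a 2x2 table")
    if np.any(cells.sum(axis=0) == 0) or np.any(cells.sum(axis=1) == 0):
        raise ValueError("zero marginal row or column")
    correction = bool(yates) and cells.shape == (2, 2)
    chi2, p, df, _ = stats.chi2_contingency(cells, correction=correction)
    return float(chi2), int(df), float(p)


def fisher_exact_2x2(table: ContingencyTable | np.ndarray) -> float:
    """Two-sided Fisher exact p: sum of hypergeometric probabilities of
    tables (with the observed margins) no more likely than the observed."""
    cells = table.cells if isinstance(table, ContingencyTable) else np.asarray(table)
    if cells.shape != (2, 2):
        raise ValueError("Fisher exact requires a 2x2 table")
    return float(stats.fisher_exact(cells, alternative="two-sided")[1])


def odds_ratio_woolf(table: ContingencyTable | np.ndarray,
                     z: float = 1.959963984540054) -> tuple[float, float, float, bool]:
    """Odds ratio with the Woolf log-normal 95% CI.

    OR = ad/bc; CI = exp(ln OR ± z * sqrt(1/a + 1/b + 1/c + 1/d)). Zero
    cells trigger the Haldane–Anscombe +0.5 correction; the returned flag
    reports whether it was applied.
    """
    cells = table.cells if isinstance(table, ContingencyTable) else np.asarray(table)
    if cells.shape != (2, 2):
        raise ValueError("odds ratio requires a 2x2 table")
    cells = cells.astype(float)
    corrected = bool(np.any(cells == 0))
    if corrected:
        cells = cells + 0.5
    a, b = cells[0]
    c, d = cells[1]
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = np.exp(np.log(or_) - z * se), np.exp(np.log(or_) + z * se)
    return float(or_), float(lo), float(hi), corrected


def kruskal_wallis_dunn(
    values: Sequence[float], groups: Sequence,
    bonferroni: bool = True, alpha: float = 0.05,
) -> tuple[float, float, dict[tuple, float]]:
    """Kruskal–Wallis H with tie correction, plus Dunn post-hoc z-tests.

    Pairwise Dunn comparisons (on mean ranks, with the tie-corrected
    variance) run only when the global test rejects at ``alpha``; their
    p-values are Bonferroni-multiplied when requested.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    samples = [values[groups == g] for g in labels]
    if any(len(s) == 0 for s in samples):
        raise ValueError("empty group")
    h, p = stats.kruskal(*samples)

    pairwise: dict[tuple, float] = {}
    if p < alpha:
        n = len(values)
        ranks = stats.rankdata(values)
        _, counts = np.unique(values, return_counts=True)
        tie_term = np.sum(counts ** 3 - counts) / (12.0 * (n - 1))
        var_unit = n * (n + 1) / 12.0 - tie_term
        mean_ranks = {g: ranks[groups == g].mean() for g in labels}
        sizes = {g: int(np.sum(groups == g)) for g in labels}
        m = len(labels) * (len(labels) - 1) // 2
        for g1, g2 in combinations(labels, 2):
            se = np.sqrt(var_unit * (1 / sizes[g1] + 1 / sizes[g2]))
            zstat = (mean_ranks[g1] - mean_ranks[g2]) / se
            praw = 2 * stats.norm.sf(abs(zstat))
            pairwise[(g1, g2)] = float(min(1.0, praw * m) if bonferroni else praw)
    return float(h), float(p), pairwise


def spearman_corr(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation (Pearson on mid-ranks), p by the
    t approximation."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def roc_youden(score: Sequence[float],
               label: Sequence[bool]) -> tuple[float, float, float, float]:
    """AUC by the rank (Mann–Whitney) identity and the Youden-optimal cut.

    The threshold maximizing J = sensitivity + specificity - 1 is searched
    over the observed scores; a positive call is ``score >= threshold``.
    Ties on J are broken toward higher specificity (higher threshold).
    Returns (auc, threshold, sensitivity, specificity).
    """
    score = np.asarray(score, dtype=float)
    label = np.asarray(label, dtype=bool)
    n1, n0 = int(label.sum()), int((~label).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(score)  # mid-ranks handle ties
    auc = (ranks[label].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)

    best = (-np.inf, -np.inf)  # (J, threshold)
    best_stats = (0.0, 0.0)
    for t in np.unique(score):
        pred = score >= t
        sens = np.sum(pred & label) / n1
        spec = np.sum(~pred & ~label) / n0
        j = sens + spec - 1
        if (j, t) > best:
            best = (j, t)
            best_stats = (sens, spec)
    return float(auc), float(best[1]), float(best_stats[0]), float(best_stats[1])


def km_logrank(time: Sequence[float], event: Sequence[bool],
               group: Sequence) -> tuple[dict, float, float]:
    """Kaplan–Meier curves per group and the two-group logrank test.

    Returns ({group: survival DataFrame}, chi-squared statistic, p).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    group = np.asarray(group)
    labels = pd.unique(group)
    if len(labels) != 2:
        raise ValueError("logrank comparison needs exactly two groups")
    if not np.any(event):
        raise ValueError("no events observed")
    curves = {}
    for g in labels:
        kmf = KaplanMeierFitter()
        kmf.fit(time[group == g], event[group == g], label=str(g))
        curves[g] = kmf.survival_function_
    m0, m1 = group == labels[0], group == labels[1]
    res = logrank_test(time[m0], time[m1], event[m0], event[m1])
    return curves, float(res.test_statistic), float(res.p_value)


def cox_fit(df: pd.DataFrame, duration_col: str, event_col: str,
            covariates: list[str]) -> pd.DataFrame:
    """Multivariate Cox proportional-hazards fit (Breslow tie handling).

    Returns one row per covariate: hazard ratio, Wald 95% CI and p.
    Raises on constant covariates or non-convergence, naming the culprit.
    """
    for c in covariates:
        if df[c].nunique() < 2:
            raise ValueError(f"constant covariate: {c}")
    if int(df[event_col].sum()) < len(covariates):
        raise ValueError("fewer events than covariates")
    cph = CoxPHFitter()
    try:
        cph.fit(df[[duration_col, event_col] + covariates],
                duration_col=duration_col, event_col=event_col)
    except Exception as exc:  # lifelines raises ConvergenceError subclasses
        raise ValueError(f"Cox fit failed for {covariates}: {exc}") from exc
    out = pd.DataFrame({
        "hr": np.exp(cph.params_),
        "ci_low": np.exp(cph.confidence_intervals_.iloc[:, 0]),
        "ci_high": np.exp(cph.confidence_intervals_.iloc[:, 1]),
        "p": cph.summary["p"],
    })
    out.index.name = "covariate"
    return out


def median_split(values: Sequence[float]) -> np.ndarray:
    """Binary high/low split at the in-cohort median; ties go to 'low'."""
    values = np.asarray(values, dtype=float)
    return values > np.median(values)


def discovery_table(cohort: pd.DataFrame,
                    psa_breaks: Sequence[float]) -> dict[str, ContingencyTable]:
    """Cross-tabulate PET and ctDNA positivity by PSA stratum.

    Strata are left-open/right-closed intervals over ``psa_breaks``; PSA
    values outside every interval land in an ``outside`` overflow row.
    Returns one ContingencyTable per modality ('pet', 'ctdna').
    """
    breaks = list(psa_breaks)
    if any(b1 <= b0 for b0, b1 in zip(breaks, breaks[1:])):
        raise ValueError("psa_breaks must be strictly increasing")
    labels = [f"({breaks[i]}, {breaks[i + 1]}]" for i in range(len(breaks) - 1)]
    out: dict[str, ContingencyTable] = {}
    if len(cohort) == 0:
        for name in ("pet", "ctdna"):
            out[name] = ContingencyTable(
                np.zeros((len(labels), 2), dtype=int), labels,
                ["positive", "negative"])
        return out
    cut = pd.cut(cohort["psa"], bins=breaks, right=True, labels=labels)
    overflow = cut.isna()
    for name, col in (("pet", "pet_positive"), ("ctdna", "ctdna_detected")):
        rows, row_labels = [], []
        for lab in labels:
            sel = (cut == lab).to_numpy()
            pos = int(cohort.loc[sel, col].sum())
            rows.append([pos, int(sel.sum()) - pos])
            row_labels.append(lab)
        if overflow.any():
            pos = int(cohort.loc[overflow.to_numpy(), col].sum())
            rows.append([pos, int(overflow.sum()) - pos])
            row_labels.append("outside")
        out[name] = ContingencyTable(np.array(rows), row_labels,
                                     ["positive", "negative"])
    return out
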