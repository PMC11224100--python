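"""End-to-end orchestration: simulate -> estimate -> cohort statistics.

A run is fully determined by its :class:`RunConfig` and seed: one global
seed fans out to per-sample seeds through a counter-based scheme
(``SeedSequence([seed, index])``), so adding samples never perturbs
earlier ones, and reports are byte-identical across reruns.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import datasets
from .genome_bins import GRCH38_AUTOSOMES, write_bin_table
from .synthetic_data import (
    CohortParams, DEFAULT_GC_BIAS, simulate_cfdna_counts, simulate_cnv_profile,
    simulate_cohort, synthetic_grid, write_truth_sidecar,
)
from .ctdna_fraction import EstimatorConfig, estimate_ctdna
from . import cohort_stats as cs


def sample_seed(seed: int, index: int) -> int:
    """Counter-based per-sample seed derived from the global seed."""
    return int(np.random.SeedSequence([seed, index]).generate_state(1)[0] % 2**31)


@dataclass
class RunConfig:
    """Everything a run needs; serializable to/from YAML."""

    seed: int = 0
    out_dir: str = "results/run"
    bin_size: int = 500_000
    chromosomes: list[str] = field(
        default_factory=lambda: list(GRCH38_AUTOSOMES))
    # simulator
    tumor_fractions: list[float] = field(
        default_factory=lambda: [0.0, 0.1, 0.2, 0.4])
    n_samples: int = 8
    mean_depth_per_bin: float = 500.0
    dispersion: float = 1000.0
    gc_bias: tuple[float, float, float] = DEFAULT_GC_BIAS
    altered_genome_fraction: float = 0.2
    mean_segment_length: float = 10_000_000
    # estimator
    estimator: EstimatorConfig = field(default_factory=EstimatorConfig)
    # cohort
    n_patients: int = 130
    cohort: CohortParams = field(default_factory=CohortParams)
    psa_breaks: list[float] = field(
        default_factory=lambda: list(datasets.PSA_BREAKS))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        est_raw = raw.pop("estimator", {})
        for key in ("states", "state_prior"):  # YAML has no tuple type
            if key in est_raw:
                est_raw[key] = tuple(est_raw[key])
        est = EstimatorConfig(**est_raw)
        coh_raw = raw.pop("cohort", {})
        if "censor_window" in coh_raw:
            coh_raw["censor_window"] = tuple(coh_raw["censor_window"])
        for key in ("psa_log", "psma_tv_log", "ctdna_log"):
            if key in coh_raw:
                coh_raw[key] = {k: tuple(v) for k, v in coh_raw[key].items()}
        coh = CohortParams(**coh_raw)
        if "gc_bias" in raw:
            raw["gc_bias"] = tuple(raw["gc_bias"])
        return cls(estimator=est, cohort=coh, **raw)


def cohort_report(cohort: pd.DataFrame, psa_breaks: list[float]) -> dict:
    """All cohort-level statistics in one JSON-ready dictionary."""
    report: dict = {"n_patients": int(len(cohort))}
    if len(cohort) == 0:
        report["note"] = "empty cohort"
        return report
    tables = cs.discovery_table(cohort, psa_breaks)
    report["discovery"] = {}
    for name, tab in tables.items():
        pct = tab.row_percentages()
        report["discovery"][name] = {
            "counts": tab.cells.tolist(),
            "row_labels": tab.row_labels,
            "positive_pct": [round(p, 2) for p in pct[:, 0]],
            "overall_positive_pct": round(
                100.0 * tab.cells[:, 0].sum() / tab.cells.sum(), 2),
        }
        if tab.cells.shape[0] >= 2 and not np.any(tab.cells.sum(axis=1) == 0):
            chi2, df, p = cs.chi_squared_test(tab, yates=False)
            report["discovery"][name]["chi2_p"] = p

    # castration-status contingency (Yates-corrected 2x2 + Woolf OR)
    by_status = {}
    for name, col in (("pet", "pet_positive"), ("ctdna", "ctdna_detected")):
        tab = pd.crosstab(cohort["castration_status"], cohort[col])
        if tab.shape == (2, 2) and (tab.values.sum(axis=1) > 0).all():
            # rows hsPC/CRPC, columns positive-then-negative
            cells = tab.loc[["hsPC", "CRPC"]].to_numpy()[:, ::-1]
            chi2, df, p = cs.chi_squared_test(cells, yates=True)
            or_, lo, hi, _ = cs.odds_ratio_woolf(cells)
            by_status[name] = {"p_yates": p, "or": or_, "ci": [lo, hi]}
    report["by_castration_status"] = by_status

    pos = (cohort["ctdna_conc"] > 0) | (cohort["psma_tv"] > 0)
    try:
        rho, p = cs.spearman_corr(cohort["ctdna_conc"], cohort["psma_tv"])
        report["spearman_ctdna_psma_tv"] = {"rho": rho, "p": p}
    except ValueError:
        pass
    try:
        auc, thr, sens, spec = cs.roc_youden(
            cohort["psma_tv"], cohort["ctdna_detected"])
        report["roc_psma_tv_for_ctdna"] = {
            "auc": auc, "threshold": thr,
            "sensitivity": sens, "specificity": spec}
    except ValueError:
        pass

    if cohort["death_event"].any():
        ct_high = cs.median_split(cohort["ctdna_conc"])
        tv_high = cs.median_split(cohort["psma_tv"])
        surv = {}
        for name, grp in (("ctdna", ct_high), ("psma_tv", tv_high)):
            if grp.any() and (~grp).any():
                _, stat, p = cs.km_logrank(
                    cohort["followup_months"], cohort["death_event"], grp)
                surv[name] = {"logrank_chi2": stat, "logrank_p": p}
        df_cox = pd.DataFrame({
            "time": cohort["followup_months"],
            "event": cohort["death_event"].astype(int),
            "ctdna_high": ct_high.astype(int),
            "psma_tv_high": tv_high.astype(int),
        })
        try:
            cox = cs.cox_fit(df_cox, "time", "event",
                             ["ctdna_high", "psma_tv_high"])
            surv["cox"] = {
                cov: {"hr": float(cox.loc[cov, "hr"]),
                      "ci": [float(cox.loc[cov, "ci_low"]),
                             float(cox.loc[cov, "ci_high"])],
                      "p": float(cox.loc[cov, "p"])}
                for cov in cox.index}
        except ValueError as exc:
            surv["cox"] = {"error": str(exc)}
        report["survival"] = surv
    return report


def run_end_to_end(config: RunConfig) -> dict:
    """Simulate samples and a cohort, estimate fractions, run statistics.

    Writes per-sample TSV counts, BED truth/call segments, a samples CSV,
    a cohort CSV, the cohort-statistics JSON, a config echo and a manifest
    hashing every output. Per-sample failures are recorded and skipped.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sizes = {c: GRCH38_AUTOSOMES[c] for c in config.chromosomes}
    grid = synthetic_grid(sizes, bin_size=config.bin_size,
                          seed=sample_seed(config.seed, 10_000))

    rows = []
    for i in range(config.n_samples):
        tf = config.tumor_fractions[i % len(config.tumor_fractions)]
        sid = f"S{i:03d}_tf{tf:g}"
        seed_i = sample_seed(config.seed, i)
        try:
            truth = simulate_cnv_profile(
                grid, tumor_fraction=tf,
                mean_segment_length=config.mean_segment_length,
                altered_genome_fraction=config.altered_genome_fraction,
                seed=seed_i)
            counts = simulate_cfdna_counts(
                grid, truth, config.mean_depth_per_bin, config.gc_bias,
                config.dispersion, seed=seed_i, sample_id=sid)
            est_cfg = dataclasses.replace(config.estimator, seed=seed_i)
            est = estimate_ctdna(counts, grid, est_cfg)
            rows.append({
                "sample_id": sid, "true_tf": tf,
                "est_tf": est.tumor_fraction, "status": est.status,
                "iterations": est.iterations, "converged": est.converged,
                "ks_p": est.qc.get("ks_p"),
                "abs_error": abs(est.tumor_fraction - tf),
            })
            if est.path is not None:
                with open(out / f"{sid}.segments.bed", "w") as fh:
                    for c, s, e, st in est.path.segments:
                        fh.write(f"{c}\t{s}\t{e}\t{st}\n")
        except Exception as exc:
            rows.append({"sample_id": sid, "true_tf": tf, "est_tf": np.nan,
                         "status": f"error: {exc}", "iterations": 0,
                         "converged": False, "ks_p": np.nan,
                         "abs_error": np.nan})
    samples = pd.DataFrame(rows, columns=[
        "sample_id", "true_tf", "est_tf", "status", "iterations",
        "converged", "ks_p", "abs_error"])
    samples.to_csv(out / "samples.csv", index=False)

    cohort = simulate_cohort(config.n_patients, config.cohort,
                             seed=sample_seed(config.seed, 20_000))
    cohort.to_csv(out / "cohort.csv", index=False)
    stats_report = cohort_report(cohort, config.psa_breaks)

    detected = samples[samples["status"] == "detected"]
    report = {
        "config_seed": config.seed,
        "n_samples": config.n_samples,
        "samples": samples.drop(columns=["ks_p"]).to_dict("records"),
        "recovery": {
            "n_detected": int(len(detected)),
            "median_abs_error_detected": (
                float(detected["abs_error"].median()) if len(detected) else None),
        },
        "cohort_stats": stats_report,
    }
    (out / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=_json_default))
    # echo the config with the output location normalized, so identical
    # runs into different directories produce identical artifacts
    dataclasses.replace(config, out_dir=".").to_yaml(out / "config.yaml")
    _write_manifest(out)
    return report


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _write_manifest(out: Path) -> None:
    entries = {}
    for p in sorted(out.iterdir()):
        if p.name == "manifest.json" or p.is_dir():
            continue
        entries[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    payload = {"files": entries,
               "manifest_hash": hashlib.sha256(
                   json.dumps(entries, sort_keys=True).encode()).hexdigest()}
    (out / "manifest.json").write_text(json.dumps(payload, indent=2, sort_keys=True))


def make_fixtures(out_dir: str | Path, seed: int = 0) -> list[Path]:
    """Write the small deterministic fixtures used by tests and docs.

    Produces a 12-bin single-chromosome toy count table, the reference
    discovery-count CSV (row sums = 130 patients), and a 200-bin sample
    simulated at tumor fraction 0.3 with its truth BED and JSON sidecar.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    toy_grid = synthetic_grid({"chr1": 6_000_000}, bin_size=500_000,
                              centromere_bins=0, seed=seed)
    toy_truth = simulate_cnv_profile(toy_grid, tumor_fraction=0.4,
                                     mean_segment_length=2_000_000,
                                     altered_genome_fraction=0.4, seed=seed)
    toy_counts = simulate_cfdna_counts(toy_grid, toy_truth, 500.0,
                                       dispersion=1000.0, seed=seed,
                                       sample_id="toy12")
    p = out / "toy12.tsv"
    write_bin_table(p, toy_grid, toy_counts)
    written.append(p)

    p = out / "discovery_counts.csv"
    datasets.discovery_counts_frame().to_csv(p, index=False)
    written.append(p)

    grid200 = synthetic_grid({"chr1": 50_000_000, "chr2": 50_000_000},
                             bin_size=500_000, seed=seed)
    truth = simulate_cnv_profile(grid200, tumor_fraction=0.3,
                                 mean_segment_length=10_000_000,
                                 altered_genome_fraction=0.3, seed=seed + 1)
    counts = simulate_cfdna_counts(grid200, truth, 500.0,
                                   dispersion=1000.0, seed=seed + 1,
                                   sample_id="sample200")
    p = out / "sample200.tsv"
    write_bin_table(p, grid200, counts)
    written.append(p)
    p = out / "sample200.truth.bed"
    truth.write_bed(p)
    written.append(p)
    p = out / "sample200.truth.json"
    write_truth_sidecar(p, truth, seed + 1, {"tf": 0.3})
    written.append(p)
    return written
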