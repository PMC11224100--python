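#!/usr/bin/env python
"""Compute the study's comparative statistics.

Part A recomputes the discovery-rate statistics from the bundled
130-patient reference count tables (PET/ctDNA by castration status and
PSA stratum: Yates 2x2 chi-squared, Woolf odds ratio, Pearson 4x2).
Part B runs the full statistic battery (discovery tables, Spearman,
ROC/Youden, Kaplan-Meier/logrank, multivariate Cox) on the simulated
cohort from 01_simulate_samples_and_cohort.py.

Writes results/cohort_statistics.json and prints the headline numbers.
"""

import json
from pathlib import Path

import pandas as pd

from liquidfrac import datasets
from liquidfrac.cohort_stats import chi_squared_test, odds_ratio_woolf
from liquidfrac.pipeline import cohort_report

OUT = Path("results")
COHORT_CSV = Path("results/simulated/cohort.csv")


def reference_statistics() -> dict:
    or_, lo, hi, _ = odds_ratio_woolf(datasets.PET_BY_CASTRATION)
    _, _, p_pet = chi_squared_test(datasets.PET_BY_CASTRATION, yates=True)
    _, _, p_ct = chi_squared_test(datasets.CTDNA_BY_CASTRATION, yates=True)
    _, _, p_ct_psa = chi_squared_test(datasets.CTDNA_BY_PSA, yates=False)
    _, _, p_pet_psa = chi_squared_test(datasets.PET_BY_PSA, yates=False)
    return {
        "pet_by_castration": {"or": round(or_, 3),
                              "ci": [round(lo, 3), round(hi, 3)],
                              "p_yates": round(p_pet, 4)},
        "ctdna_by_castration": {"p_yates": round(p_ct, 4)},
        "ctdna_by_psa_range": {"p_pearson": round(p_ct_psa, 4)},
        "pet_by_psa_range": {"p_pearson": round(p_pet_psa, 6)},
    }


def main() -> None:
    OUT.mkdir(exist_ok=True)
    ref = reference_statistics()
    print("reference 130-patient tables:")
    print(f"  PET by castration: OR={ref['pet_by_castration']['or']} "
          f"CI={ref['pet_by_castration']['ci']} "
          f"p={ref['pet_by_castration']['p_yates']}")
    print(f"  ctDNA by castration: p={ref['ctdna_by_castration']['p_yates']}")
    print(f"  ctDNA by PSA range: p={ref['ctdna_by_psa_range']['p_pearson']}")
    print(f"  PET by PSA range:   p={ref['pet_by_psa_range']['p_pearson']}")

    report = {"reference_tables": ref}
    if COHORT_CSV.exists():
        cohort = pd.read_csv(COHORT_CSV)
        sim = cohort_report(cohort, datasets.PSA_BREAKS)
        report["simulated_cohort"] = sim
        print(f"\nsimulated {sim['n_patients']}-patient cohort:")
        if "spearman_ctdna_psma_tv" in sim:
            print(f"  Spearman(ctDNA, PSMA-TV) = "
                  f"{sim['spearman_ctdna_psma_tv']['rho']:.3f}")
        if "roc_psma_tv_for_ctdna" in sim:
            roc = sim["roc_psma_tv_for_ctdna"]
            print(f"  AUC(PSMA-TV -> ctDNA detection) = {roc['auc']:.3f}, "
                  f"Youden threshold {roc['threshold']:.1f} cm^3")
        if "survival" in sim and "cox" in sim["survival"]:
            for cov, row in sim["survival"]["cox"].items():
                if isinstance(row, dict) and "hr" in row:
                    print(f"  Cox HR[{cov}] = {row['hr']:.2f} "
                          f"CI [{row['ci'][0]:.2f}, {row['ci'][1]:.2f}]")
    else:
        print("\n(no simulated cohort found; run the 01 script first)")
    (OUT / "cohort_statistics.json").write_text(
        json.dumps(report, indent=2, sort_keys=True))
    print(f"\nwrote {OUT / 'cohort_statistics.json'}")


if __name__ == "__main__":
    main()
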