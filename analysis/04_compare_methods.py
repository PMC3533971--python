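#!/usr/bin/env python
"""Method comparison: individual vs group cut points, and right vs left hip.

Computes Bland-Altman agreement (SEM, LoA) between hip-specific cut points,
the CV / Spearman / Wilcoxon comparison of MVPA outcomes under ICPs vs the
GCP, the >= 30 min/day bouted-MVPA guideline reclassification (percent
agreement and Cohen's kappa), the quadratic association between ICPs and
MVPA minutes, and partial correlations of the ICPs on their physiological
drivers (resting VO2, work economy, BMI).

Reads results/{synthetic,calibration,freeliving}/, writes results/agreement/.
"""

from pathlib import Path

import pandas as pd

from accelcal.agreement import (
    PairedMeasures,
    bland_altman,
    bland_altman_plot,
    guideline_reclassification,
    partial_correlations,
    polynomial_association,
)

ROOT = Path(__file__).resolve().parents[1]
RES = ROOT / "results"
OUT = RES / "agreement"


def report_to_row(outcome, rep):
    return {
        "outcome": outcome, "n": rep.n, "median_diff": rep.median_diff,
        "mean_diff": rep.mean_diff, "sd_diff": rep.sd_diff, "sem": rep.sem,
        "loa": rep.loa, "limit_low": rep.limits[0], "limit_high": rep.limits[1],
        "cv_percent": rep.cv_percent, "spearman_rho": rep.spearman_rho,
        "spearman_p": rep.spearman_p, "wilcoxon_p": rep.wilcoxon_p,
    }


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rows = []

    # right vs left hip cut points
    hips = pd.read_csv(RES / "calibration" / "two_hip_cutpoints.csv")
    p = PairedMeasures.from_arrays(hips["right_hip"], hips["left_hip"],
                                   ids=hips["subject_id"])
    rep = bland_altman(p)
    rows.append(report_to_row("icp_left_vs_right", rep))
    bland_altman_plot(p, rep, OUT / "bland_altman_hips.png")
    print(f"hips (n = {rep.n}): median difference {rep.median_diff:.1f}, "
          f"SEM {rep.sem:.0f}, LoA {rep.loa:.0f} counts/min, "
          f"limits {rep.limits[0]:.1f} to {rep.limits[1]:.1f}")

    # ICP- vs GCP-derived activity outcomes
    subjects = pd.read_csv(RES / "freeliving" / "subject_outcomes.csv")
    valid = subjects[subjects["valid_measurement"]]
    wide = {}
    for outcome in ("mvpa_per_day", "bouts_per_day"):
        w = valid.pivot(index="subject_id", columns="source", values=outcome).dropna()
        wide[outcome] = w
        rep = bland_altman(PairedMeasures.from_arrays(w["icp"], w["gcp"], ids=w.index))
        rows.append(report_to_row(f"{outcome}_gcp_vs_icp", rep))
        print(f"{outcome} (n = {len(w)}): ICP median {w['icp'].median():.1f} vs "
              f"GCP median {w['gcp'].median():.1f} min/day, CV {rep.cv_percent:.1f}%, "
              f"Spearman rho {rep.spearman_rho:.2f}, Wilcoxon p {rep.wilcoxon_p:.3f}")
    pd.DataFrame(rows).to_csv(OUT / "agreement.csv", index=False)

    # guideline reclassification on bouted MVPA
    w = wide["bouts_per_day"]
    rec = guideline_reclassification(w["icp"], w["gcp"], threshold=30.0)
    pd.DataFrame([{
        "threshold": rec.threshold, "percent_agreement": rec.percent_agreement,
        "kappa": rec.kappa, "kappa_p": rec.kappa_p,
        "both_meet": rec.table[0, 0], "only_icp": rec.table[0, 1],
        "only_gcp": rec.table[1, 0], "neither": rec.table[1, 1],
    }]).to_csv(OUT / "guideline_reclassification.csv", index=False)
    print(f"guideline (>= 30 min bouted/day): {rec.percent_agreement:.0f}% agreement, "
          f"kappa {rec.kappa:.2f}")

    # association structure: ICP -> MVPA (quadratic) and ICP drivers (partial r)
    cuts = pd.read_csv(RES / "calibration" / "individual_cutpoints.csv")
    truth = pd.read_csv(RES / "synthetic" / "calibration_truth.csv")
    merged = cuts.merge(truth, on="subject_id").merge(
        wide["mvpa_per_day"]["icp"].rename("mvpa_icp"), on="subject_id"
    )
    quad = polynomial_association(merged["mvpa_icp"], merged["icp"], degree=2)
    drivers = partial_correlations(
        merged["icp"], merged[["resting_vo2", "work_economy", "bmi"]]
    )
    pd.DataFrame([
        {"model": "mvpa_on_icp_quadratic", "r_squared": quad.r_squared,
         "f_stat": quad.f_stat, "p": quad.f_pvalue},
        {"model": "icp_on_drivers", "r_squared": drivers.r_squared,
         "f_stat": drivers.f_stat, "p": drivers.f_pvalue,
         **{f"partial_r_{k}": v for k, v in drivers.partial_r.items()}},
    ]).to_csv(OUT / "associations.csv", index=False)
    print(f"quadratic ICP->MVPA R^2 = {quad.r_squared:.3f}; ICP drivers R^2 = "
          f"{drivers.r_squared:.3f} with partial r "
          + ", ".join(f"{k} {v:+.2f}" for k, v in drivers.partial_r.items()))


if __name__ == "__main__":
    main()
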