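#!/usr/bin/env python
"""Clinical associations with the RS measures.

Fits the three longitudinal mixed-model presets on the AN group
(adjusted-BMI percentile with a cross-condition RS x time interaction;
EDE over two timepoints; BAS with neutral-reward RS, no interaction) and
runs the exploratory partial correlations (PDS-adjusted, Pearson and
Spearman) between neutral-reward RS and baseline CDRS / adjusted-BMI /
HAM-A, BH-FDR corrected as one family. Writes lmm_results.csv and
partial_correlations.csv under results/analysis/.

Run after 03_rsa_maps.py:
    python analysis/05_clinical_associations.py
"""

from pathlib import Path

import pandas as pd

from rewardrs.clinical import LMM_PRESETS, adjust_family, fit_lmm, \
    partial_corr
from rewardrs.simulate import load_cohort

OUT = Path("results/analysis")
FAMILY = ("cdrs", "adjusted_bmi", "ham_a")


def main() -> None:
    cohort = load_cohort(OUT / "cohort")
    rs = pd.read_csv(OUT / "rs_summaries.csv")
    wide = rs.pivot_table(index="subject_id", columns="condition",
                          values="mean_z").rename(columns={
                              "cross_rewarded": "rs_cross",
                              "neutral_rewarded": "rs_neutral"})
    merged = (cohort.clinical
              .merge(wide[["rs_cross", "rs_neutral"]], on="subject_id")
              .merge(cohort.participants, on="subject_id"))

    lmm_rows = []
    an = merged[merged.group == "AN"]
    for preset in LMM_PRESETS:
        res = fit_lmm(an, preset)
        for _, row in res.fixed_effects.iterrows():
            lmm_rows.append((preset, row.term, row.estimate, row.se, row.p,
                             res.converged, res.random_structure))
        for term in ("time", "rs", "time:rs"):
            try:
                r = res.term(term)
                print(f"LMM {preset}: {term} = {r.estimate:.3f} "
                      f"(se {r.se:.3f}, p = {r.p:.3f})")
            except KeyError:
                pass
    pd.DataFrame(lmm_rows, columns=["model", "term", "estimate", "se", "p",
                                    "converged", "random_structure"]
                 ).to_csv(OUT / "lmm_results.csv", index=False)

    baseline = (merged[merged.timepoint == "entry"]
                .pivot_table(index="subject_id", columns="measure",
                             values="value").reset_index()
                .merge(cohort.participants, on="subject_id")
                .merge(wide[["rs_neutral"]], on="subject_id"))
    prows = []
    for method in ("pearson", "spearman"):
        fam = []
        for measure in FAMILY:
            try:
                fam.append((measure, partial_corr(
                    baseline["rs_neutral"], baseline[measure],
                    baseline["pds"], method)))
            except ValueError as err:
                print(f"partial corr rs_neutral ~ {measure} ({method}) "
                      f"skipped: {err}")
        adjust_family([r for _, r in fam])
        for measure, r in fam:
            prows.append((method, measure, r.coefficient, r.p,
                          r.p_adjusted, r.n))
            print(f"partial corr ({method}) rs_neutral ~ {measure}: "
                  f"r = {r.coefficient:.2f}, p = {r.p:.3f}, "
                  f"FDR-adjusted p = {r.p_adjusted:.3f}")
    pd.DataFrame(prows, columns=["method", "measure", "coefficient", "p",
                                 "p_adjusted", "n"]
                 ).to_csv(OUT / "partial_correlations.csv", index=False)


if __name__ == "__main__":
    main()
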