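#!/usr/bin/env python
"""Group-level inference on the RS measures.

Runs, per condition: the mask-level ANCOVA (log RS ~ group + PDS), the
leave-one-ROI-out MANOVA sensitivity series, the two-sample searchlight
permutation test (Freedman-Lane, TFCE, max-statistic FWE) and the
within-group one-sample tests. Writes ancova.csv, manova.csv and
searchlight inference maps under results/analysis/.

Run after 03_rsa_maps.py:
    python analysis/04_group_inference.py [--n-perm 500] [--seed 7]
"""

import argparse
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from rewardrs.permutation import one_sample_perm_test, permutation_group_test
from rewardrs.rsa import log_transform_cohort
from rewardrs.simulate import load_cohort
from rewardrs.stats import ancova_group, leave_one_roi_out_manova
from rewardrs.tfce import TfceParams

OUT = Path("results/analysis")
CONDITIONS = ("anxiety_rewarded", "anxiety_nonrewarded",
              "neutral_rewarded", "neutral_nonrewarded")


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--n-perm", type=int, default=500)
    ap.add_argument("--seed", type=int, default=7)
    args = ap.parse_args()

    cohort = load_cohort(OUT / "cohort")
    mask = cohort.phantom.union_mask
    rs = pd.read_csv(OUT / "rs_summaries.csv")
    roi = pd.read_csv(OUT / "rs_by_roi.csv")

    rows = []
    for cond in CONDITIONS:
        sub = rs[rs.condition == cond].sort_values("subject_id")
        logged, shift = log_transform_cohort(sub["mean_z"].to_numpy())
        res = ancova_group(logged, sub["group"], sub["pds"])
        rows.append((cond, res.F, res.df2, res.p, res.eta_sq, shift))
        print(f"ANCOVA {cond}: F(1,{res.df2}) = {res.F:.2f}, "
              f"p = {res.p:.3f}, eta^2 = {res.eta_sq:.3f}")
    pd.DataFrame(rows, columns=["condition", "F", "df2", "p", "eta_sq",
                                "log_shift"]).to_csv(OUT / "ancova.csv",
                                                     index=False)

    mrows = []
    for cond in ("neutral_rewarded", "anxiety_rewarded"):
        wide = (roi[roi.condition == cond]
                .pivot_table(index=["subject_id", "group", "pds"],
                             columns="roi", values="mean_z").reset_index())
        cols = [c for c in wide.columns
                if c not in ("subject_id", "group", "pds")]
        try:
            for r in leave_one_roi_out_manova(wide[cols], wide["group"],
                                              wide["pds"]):
                mrows.append((cond, r.omitted_roi, r.wilks_lambda, r.F,
                              r.p))
        except ValueError as err:
            print(f"MANOVA for {cond} skipped: {err}")
    if mrows:
        mdf = pd.DataFrame(mrows, columns=["condition", "omitted_roi",
                                           "wilks_lambda", "F", "p"])
        mdf.to_csv(OUT / "manova.csv", index=False)
        worst = mdf.loc[mdf.p.idxmin()]
        print(f"leave-one-ROI-out MANOVA: smallest p = {worst.p:.3f} "
              f"(omitting {worst.omitted_roi}, {worst.condition})")

    participants = cohort.participants.set_index("subject_id")
    for cond in ("neutral_rewarded", "anxiety_rewarded"):
        sids = sorted(participants.index)
        maps = [np.nan_to_num(np.asarray(nib.load(
            str(OUT / "slmaps" / f"{s}_{cond}_z.nii.gz")).dataobj,
            dtype=float)) for s in sids]
        group = participants.loc[sids, "group"].to_numpy()
        pds = participants.loc[sids, "pds"].to_numpy()
        perm = permutation_group_test(maps, group, pds, mask, args.n_perm,
                                      args.seed, TfceParams())
        nib.save(nib.Nifti1Image((1 - perm.fwe_p_map).astype(np.float32),
                                 cohort.phantom.affine),
                 OUT / f"group_{cond}_1minus_fwep.nii.gz")
        print(f"searchlight group test {cond}: min FWE p = "
              f"{perm.fwe_p_map[mask].min():.3f}, "
              f"{int(perm.significant().sum())} significant voxels")
        for g in ("AN", "CON"):
            sel = group == g
            one = one_sample_perm_test([m for m, s in zip(maps, sel) if s],
                                       pds[sel], mask, args.n_perm,
                                       args.seed + {"AN": 1, "CON": 2}[g],
                                       TfceParams())
            n_sig = int(one.significant().sum())
            nib.save(nib.Nifti1Image((1 - one.fwe_p_map).astype(np.float32),
                                     cohort.phantom.affine),
                     OUT / f"onesample_{cond}_{g}_1minus_fwep.nii.gz")
            print(f"  within-group {g}: {n_sig} voxels with positive RS at "
                  f"FWE p < .05")


if __name__ == "__main__":
    main()
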