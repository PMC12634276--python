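#!/usr/bin/env python
"""Volume censoring and single-trial beta estimation.

For every run: DVARS against the boxplot fence (Q75 + 1.5 IQR) flags
motion-like intensity spikes, flagged volumes are censored, and one LSS
GLM per feedback event yields that trial's multivoxel beta pattern over
the union ROI mask. Writes results/analysis/censoring.csv and one beta
stack per subject under results/analysis/stacks/.

Run after 01_simulate_cohort.py:
    python analysis/02_qc_and_betas.py
"""

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from rewardrs.design import read_events_tsv
from rewardrs.glm import estimate_trial_betas
from rewardrs.qc import compute_dvars, flag_outlier_volumes
from rewardrs.simulate import SESSIONS, load_cohort

OUT = Path("results/analysis")


def main() -> None:
    cohort = load_cohort(OUT / "cohort")
    task = cohort.manifest["spec"]["task"]
    mask = cohort.phantom.union_mask
    rows = []
    for t in cohort.truths:
        per_session = []
        for sess in SESSIONS:
            ses_dir = cohort.root / t.subject_id / f"ses-{sess}"
            run = np.asarray(nib.load(str(ses_dir / "bold.nii.gz")).dataobj)
            design = read_events_tsv(ses_dir / "events.tsv", sess,
                                     task["tr"], task["n_volumes"])
            censor = flag_outlier_volumes(compute_dvars(run, mask),
                                          f"{t.subject_id}_{sess}")
            rows.append((t.subject_id, sess, censor.n_excluded,
                         censor.percent_excluded,
                         len(t.spike_volumes.get(sess, []))))
            per_session.append(estimate_trial_betas(
                run, design, mask, censor, subject_id=t.subject_id,
                session=sess, on_error="skip"))
        stack = per_session[0].concat(per_session[1])
        stack.save(OUT / "stacks" / t.subject_id)
    censor_df = pd.DataFrame(rows, columns=[
        "subject_id", "session", "n_excluded", "percent_excluded",
        "n_injected_spikes"])
    censor_df.to_csv(OUT / "censoring.csv", index=False)
    print(f"censored volumes per run: mean {censor_df.n_excluded.mean():.1f}"
          f", max {censor_df.n_excluded.max()} "
          f"({censor_df.percent_excluded.max():.1f}% of the run)")
    print(f"injected spike volumes per run: mean "
          f"{censor_df.n_injected_spikes.mean():.1f}")
    print(f"beta stacks written for {len(cohort.truths)} subjects "
          f"(~{60} trials per session before censoring)")


if __name__ == "__main__":
    main()
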