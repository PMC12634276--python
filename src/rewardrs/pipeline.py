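"""End-to-end orchestration: simulate -> QC/betas -> RSA -> group
inference -> clinical associations, with a reproducible manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from . import __version__
from .clinical import LMM_PRESETS, adjust_family, fit_lmm, partial_corr
from .design import read_events_tsv
from .glm import estimate_trial_betas
from .phantom import default_phantom_spec
from .permutation import (cluster_table, one_sample_perm_test,
                          permutation_group_test)
from .qc import compute_dvars, flag_outlier_volumes
from .rsa import (cross_condition_rs, log_transform_cohort, mask_rs_summary,
                  searchlight_rs, fisher_z)
from .simulate import CONDITIONS, SESSIONS, Cohort, CohortSpec, \
    generate_cohort, GroupSpec
from .stats import ancova_group, leave_one_roi_out_manova
from .tfce import TfceParams

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    seed: int = 0
    cohort: CohortSpec = field(default_factory=CohortSpec)
    n_perm: int = 5000
    rs_mode: str = "searchlight"
    radius: float = 2.0
    tfce: TfceParams = field(default_factory=TfceParams)
    log_shift_delta: float = 0.01
    fdr_families: dict[str, list[str]] = field(default_factory=lambda: {
        "baseline_rs_neutral": ["cdrs", "adjusted_bmi", "ham_a"]})
    run_searchlight_inference: bool = True

    @classmethod
    def demo(cls, seed: int = 0) -> "RunConfig":
        """Desk-scale profile: small grid/cohort, 500 permutations."""
        groups = {
            "AN": GroupSpec(n=6, rho_mean={
                "anxiety_rewarded": 0.18, "anxiety_nonrewarded": 0.16,
                "neutral_rewarded": 0.12, "neutral_nonrewarded": 0.16},
                pds_mean=14.2, pds_sd=4.3, bmi_entry_mean=27.0,
                bmi_entry_sd=18.0, ede_entry_mean=3.5, ede_entry_sd=1.6,
                cdrs_mean=42.0, cdrs_sd=18.0, hama_mean=14.3, hama_sd=7.8,
                ybc_mean=24.0, ybc_sd=10.0),
            "CON": GroupSpec(n=6, rho_mean={
                "anxiety_rewarded": 0.18, "anxiety_nonrewarded": 0.16,
                "neutral_rewarded": 0.20, "neutral_nonrewarded": 0.16},
                pds_mean=17.9, pds_sd=1.4, bmi_entry_mean=63.0,
                bmi_entry_sd=23.0, ede_entry_mean=0.5, ede_entry_sd=0.7,
                cdrs_mean=23.0, cdrs_sd=5.5, hama_mean=7.2, hama_sd=4.5,
                ybc_mean=1.5, ybc_sd=3.0)}
        cohort = CohortSpec(groups=groups,
                            phantom=default_phantom_spec((16, 16, 16)))
        return cls(seed=seed, cohort=cohort, n_perm=500)


def validate_config(config: RunConfig) -> list[str]:
    """Schema and cross-field checks; empty list means valid."""
    issues: list[str] = []
    if config.seed is None:
        issues.append("missing seed")
    if config.n_perm < 100:
        issues.append("n_perm below 100 gives unusable FWE resolution")
    if config.rs_mode not in ("searchlight", "pairwise"):
        issues.append(f"unknown rs_mode {config.rs_mode!r}")
    task = config.cohort.task
    min_trial_ms = (task.fixed_trial_ms + 2 * task.jitter_min_ms)
    if task.n_trials * min_trial_ms > task.n_volumes * task.tr * 1000:
        issues.append("trial time exceeds run length: reduce n_trials or "
                      "increase n_volumes")
    for g, gs in config.cohort.groups.items():
        if gs.n < 2:
            issues.append(f"group {g} needs at least 2 subjects")
        for cond, rho in gs.rho_mean.items():
            if not 0 <= rho <= 1:
                issues.append(f"group {g} condition {cond}: rho outside [0,1]")
    return issues


def _config_hash(config: RunConfig) -> str:
    def enc(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))

    blob = json.dumps(dataclasses.asdict(config), default=enc, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()


def _df_checksum(df: pd.DataFrame) -> str:
    return hashlib.sha256(
        df.round(10).to_csv(index=False).encode()).hexdigest()


def _session_condition(session: str, rewarded: bool) -> str:
    return f"{session}_{'rewarded' if rewarded else 'nonrewarded'}"


def run_full_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute all stages on a simulated cohort.

    Writes the cohort tree under ``out_dir/cohort``, stage outputs under
    ``out_dir`` (RS summaries, ANCOVA/MANOVA tables, searchlight
    inference maps, association tables, report.md) and returns the
    manifest dict. Aborts with the failing stage named.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    issues = validate_config(config)
    if issues:
        raise ValueError(f"stage config: invalid configuration: {issues}")
    manifest = {"version": __version__, "config_hash": _config_hash(config),
                "seed": config.seed, "stages": [], "checksums": {}}
    stage = "simulate"
    try:
        cohort = generate_cohort(config.cohort, config.seed,
                                 out / "cohort")
        manifest["stages"].append(stage)

        stage = "qc_betas"
        censor_rows, stacks = _qc_and_betas(cohort, config)
        censor_df = pd.DataFrame(censor_rows, columns=[
            "subject_id", "session", "n_excluded", "percent_excluded"])
        censor_df.to_csv(out / "censoring.csv", index=False)
        manifest["stages"].append(stage)

        stage = "rsa"
        rs_df, roi_df, sl_maps = _rsa_stage(cohort, stacks, config)
        rs_df.to_csv(out / "rs_summaries.csv", index=False)
        roi_df.to_csv(out / "rs_by_roi.csv", index=False)
        manifest["stages"].append(stage)

        stage = "group_inference"
        infer = _group_inference(cohort, rs_df, roi_df, sl_maps, config, out)
        manifest["stages"].append(stage)

        stage = "clinical_assoc"
        assoc = _clinical_stage(cohort, rs_df, config)
        assoc["lmm"].to_csv(out / "lmm_results.csv", index=False)
        assoc["pcorr"].to_csv(out / "partial_correlations.csv", index=False)
        manifest["stages"].append(stage)

        stage = "report"
        _write_report(out, cohort, censor_df, rs_df, infer, assoc, config)
        manifest["stages"].append(stage)
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    manifest["checksums"] = {
        "participants": _df_checksum(cohort.participants),
        "clinical": _df_checksum(cohort.clinical),
        "censoring": _df_checksum(censor_df),
        "rs_summaries": _df_checksum(rs_df),
        "rs_by_roi": _df_checksum(roi_df),
        "lmm": _df_checksum(assoc["lmm"]),
        "pcorr": _df_checksum(assoc["pcorr"]),
    }
    manifest["ancova"] = infer["ancova"]
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
    return manifest


def _qc_and_betas(cohort: Cohort, config: RunConfig):
    mask = cohort.phantom.union_mask
    censor_rows = []
    stacks = {}
    for t in cohort.truths:
        per_session = []
        for sess in SESSIONS:
            ses_dir = cohort.root / t.subject_id / f"ses-{sess}"
            run = np.asarray(nib.load(str(ses_dir / "bold.nii.gz")).dataobj)
            design = read_events_tsv(ses_dir / "events.tsv", sess,
                                     config.cohort.task.tr,
                                     config.cohort.task.n_volumes)
            censor = flag_outlier_volumes(compute_dvars(run, mask),
                                          f"{t.subject_id}_{sess}")
            censor_rows.append((t.subject_id, sess, censor.n_excluded,
                                censor.percent_excluded))
            stack = estimate_trial_betas(run, design, mask, censor,
                                         hrf_spec=config.cohort.sim.hrf,
                                         subject_id=t.subject_id,
                                         session=sess,
                                         on_error="skip")
            per_session.append(stack)
        stacks[t.subject_id] = per_session[0].concat(per_session[1])
    return censor_rows, stacks


def _rsa_stage(cohort: Cohort, stacks, config: RunConfig):
    phantom = cohort.phantom
    mask = phantom.union_mask
    rs_rows = []
    roi_rows = []
    sl_maps = {c: {} for c in ("anxiety_rewarded", "neutral_rewarded")}
    for t in cohort.truths:
        stack = stacks[t.subject_id]
        cond_stacks = {}
        for sess in SESSIONS:
            for rewarded in (True, False):
                cond = _session_condition(sess, rewarded)
                cond_stacks[cond] = stack.select(word_type=sess,
                                                 rewarded=rewarded)
        for cond, cstack in cond_stacks.items():
            if cond in sl_maps:
                sl = searchlight_rs(cstack, mask, config.radius, cond)
                zmap = np.where(np.isfinite(sl.values),
                                fisher_z(sl.values), np.nan)
                sl_maps[cond][t.subject_id] = zmap
                summary = mask_rs_summary(sl, mask, "searchlight",
                                          config.radius, t.subject_id, cond)
                mean_z = summary.mean_z
                alt = mask_rs_summary(cstack, mask, "pairwise",
                                      subject_id=t.subject_id,
                                      condition=cond)
                pairwise_z = alt.mean_z
            else:
                mean_z = mask_rs_summary(
                    cstack, mask, config.rs_mode, config.radius,
                    t.subject_id, cond).mean_z
                pairwise_z = mask_rs_summary(
                    cstack, mask, "pairwise", subject_id=t.subject_id,
                    condition=cond).mean_z
            rs_rows.append((t.subject_id, t.group, t.pds, cond,
                            mean_z, pairwise_z))
            for roi in phantom.legend:
                roi_z = mask_rs_summary(cstack, phantom.roi_mask(roi),
                                        "pairwise", subject_id=t.subject_id,
                                        condition=cond).mean_z
                roi_rows.append((t.subject_id, t.group, t.pds, cond, roi,
                                 roi_z))
        rs_cross = cross_condition_rs(cond_stacks["anxiety_rewarded"],
                                      cond_stacks["neutral_rewarded"],
                                      mask, mode="pairwise")
        rs_rows.append((t.subject_id, t.group, t.pds, "cross_rewarded",
                        rs_cross, rs_cross))
    rs_df = pd.DataFrame(rs_rows, columns=["subject_id", "group", "pds",
                                           "condition", "mean_z",
                                           "pairwise_z"])
    roi_df = pd.DataFrame(roi_rows, columns=["subject_id", "group", "pds",
                                             "condition", "roi", "mean_z"])
    return rs_df, roi_df, sl_maps


def _group_inference(cohort: Cohort, rs_df, roi_df, sl_maps,
                     config: RunConfig, out: Path):
    mask = cohort.phantom.union_mask
    results = {"ancova": {}, "manova": {}, "searchlight": {}}
    seed_seq = np.random.SeedSequence(config.seed ^ 0x5EED)
    perm_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                  for s in seed_seq.spawn(8)]

    ancova_rows = []
    for cond in CONDITIONS:
        sub = rs_df[rs_df["condition"] == cond].sort_values("subject_id")
        logged, shift = log_transform_cohort(sub["mean_z"].to_numpy(),
                                             config.log_shift_delta)
        res = ancova_group(logged, sub["group"].to_numpy(),
                           sub["pds"].to_numpy())
        results["ancova"][cond] = {
            "F": res.F, "df1": res.df1, "df2": res.df2, "p": res.p,
            "eta_sq": res.eta_sq, "log_shift": shift}
        ancova_rows.append((cond, res.F, res.df1, res.df2, res.p,
                            res.eta_sq, shift))
    pd.DataFrame(ancova_rows, columns=["condition", "F", "df1", "df2", "p",
                                       "eta_sq", "log_shift"]
                 ).to_csv(out / "ancova.csv", index=False)

    manova_rows = []
    for cond in ("neutral_rewarded", "anxiety_rewarded"):
        sub = roi_df[roi_df["condition"] == cond]
        wide = sub.pivot_table(index=["subject_id", "group", "pds"],
                               columns="roi", values="mean_z").reset_index()
        roi_cols = [c for c in wide.columns
                    if c not in ("subject_id", "group", "pds")]
        try:
            res = leave_one_roi_out_manova(wide[roi_cols],
                                           wide["group"].to_numpy(),
                                           wide["pds"].to_numpy())
        except ValueError as err:
            logger.warning("MANOVA skipped for %s: %s", cond, err)
            continue
        for r in res:
            manova_rows.append((cond, r.omitted_roi, r.wilks_lambda, r.F,
                                r.df1, r.df2, r.p))
    manova_df = pd.DataFrame(manova_rows, columns=[
        "condition", "omitted_roi", "wilks_lambda", "F", "df1", "df2", "p"])
    manova_df.to_csv(out / "manova_leave_one_roi_out.csv", index=False)
    results["manova"] = manova_df

    if config.run_searchlight_inference:
        subject_order = sorted(sl_maps["neutral_rewarded"])
        participants = cohort.participants.set_index("subject_id")
        for k, cond in enumerate(("neutral_rewarded", "anxiety_rewarded")):
            maps = [sl_maps[cond][s] for s in subject_order]
            maps = [np.nan_to_num(m, nan=0.0) for m in maps]
            group = participants.loc[subject_order, "group"].to_numpy()
            pds = participants.loc[subject_order, "pds"].to_numpy()
            perm = permutation_group_test(
                maps, group, pds, mask, config.n_perm, perm_seeds[k],
                config.tfce)
            _save_perm_maps(out, f"group_{cond}", perm, cohort)
            results["searchlight"][f"group_{cond}"] = {
                "min_fwe_p": float(perm.fwe_p_map[mask].min()),
                "n_significant": int(perm.significant().sum())}
            for j, g in enumerate(("AN", "CON")):
                sel = group == g
                one = one_sample_perm_test(
                    [m for m, s in zip(maps, sel) if s], pds[sel], mask,
                    config.n_perm, perm_seeds[2 + 2 * k + j], config.tfce)
                _save_perm_maps(out, f"onesample_{cond}_{g}", one, cohort)
                results["searchlight"][f"onesample_{cond}_{g}"] = {
                    "min_fwe_p": float(one.fwe_p_map[mask].min()),
                    "n_significant": int(one.significant().sum())}
    return results


def _save_perm_maps(out: Path, name: str, perm, cohort: Cohort) -> None:
    d = out / "searchlight"
    d.mkdir(exist_ok=True)
    aff = cohort.phantom.affine
    nib.save(nib.Nifti1Image(np.nan_to_num(perm.stat_map).astype(np.float32),
                             aff), d / f"{name}_tstat.nii.gz")
    nib.save(nib.Nifti1Image(perm.tfce_map.astype(np.float32), aff),
             d / f"{name}_tfce.nii.gz")
    nib.save(nib.Nifti1Image((1 - perm.fwe_p_map).astype(np.float32), aff),
             d / f"{name}_1minus_fwep.nii.gz")
    cluster_table(perm).to_csv(d / f"{name}_clusters.csv", index=False)


def _clinical_stage(cohort: Cohort, rs_df, config: RunConfig):
    rs_wide = rs_df.pivot_table(index="subject_id", columns="condition",
                                values="mean_z").rename(columns={
                                    "cross_rewarded": "rs_cross",
                                    "neutral_rewarded": "rs_neutral"})
    merged = cohort.clinical.merge(rs_wide[["rs_cross", "rs_neutral"]],
                                   on="subject_id")
    merged = merged.merge(cohort.participants, on="subject_id")

    lmm_rows = []
    an_table = merged[merged["group"] == "AN"]
    for preset in LMM_PRESETS:
        res = fit_lmm(an_table, preset)
        for _, row in res.fixed_effects.iterrows():
            lmm_rows.append((preset, row["term"], row["estimate"], row["se"],
                             row["p"], res.converged, res.random_structure))
    lmm_df = pd.DataFrame(lmm_rows, columns=["model", "term", "estimate",
                                             "se", "p", "converged",
                                             "random_structure"])

    baseline = merged[merged["timepoint"] == "entry"].pivot_table(
        index="subject_id", columns="measure", values="value").reset_index()
    baseline = baseline.merge(cohort.participants, on="subject_id")
    baseline = baseline.merge(rs_wide[["rs_neutral"]], on="subject_id")
    pcorr_rows = []
    for family, measures in config.fdr_families.items():
        for method in ("pearson", "spearman"):
            fam_results = []
            for measure in measures:
                try:
                    r = partial_corr(baseline["rs_neutral"],
                                     baseline[measure], baseline["pds"],
                                     method)
                except ValueError as err:
                    logger.warning("partial correlation rs_neutral ~ %s "
                                   "(%s) skipped: %s", measure, method, err)
                    continue
                fam_results.append((measure, r))
            adjust_family([r for _, r in fam_results])
            for measure, r in fam_results:
                pcorr_rows.append((family, method, "rs_neutral", measure,
                                   r.coefficient, r.p, r.p_adjusted, r.n))
    pcorr_df = pd.DataFrame(pcorr_rows, columns=[
        "family", "method", "x", "y", "coefficient", "p", "p_adjusted", "n"])
    return {"lmm": lmm_df, "pcorr": pcorr_df}


def _write_report(out: Path, cohort: Cohort, censor_df, rs_df, infer, assoc,
                  config: RunConfig) -> Path:
    lines = ["# Reward representational-similarity pipeline report", ""]
    n_by_group = cohort.participants["group"].value_counts().to_dict()
    lines.append(f"Cohort: {n_by_group} subjects, seed {config.seed}.")
    lines.append(f"Censoring: mean {censor_df['n_excluded'].mean():.1f} "
                 f"volumes excluded per run "
                 f"(max {censor_df['n_excluded'].max()}).")
    lines.append("")
    lines.append("## RS by group and condition (mean z)")
    summary = rs_df.groupby(["condition", "group"])["mean_z"].mean()
    lines.append(summary.to_string())
    lines.append("")
    lines.append("## ANCOVA (log RS ~ group + PDS)")
    for cond, r in infer["ancova"].items():
        lines.append(f"- {cond}: F(1, {r['df2']}) = {r['F']:.2f}, "
                     f"p = {r['p']:.3f}, eta^2 = {r['eta_sq']:.3f}")
    if infer["searchlight"]:
        lines.append("")
        lines.append("## Searchlight permutation inference")
        for name, r in infer["searchlight"].items():
            lines.append(f"- {name}: min FWE p = {r['min_fwe_p']:.3f}, "
                         f"{r['n_significant']} significant voxels")
    lines.append("")
    lines.append("## Clinical associations")
    lines.append(assoc["pcorr"].to_string(index=False))
    path = out / "report.md"
    path.write_text("\n".join(lines) + "\n")
    return path
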