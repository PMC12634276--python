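"""Synthetic fMRI cohorts with controllable trial-to-trial reliability.

The generator emulates the study's data: two sessions per adolescent
participant (one with anxiety words, one with neutral words), 60 trials
per session with 50% random reward, TR 1 s, 487 volumes, a phantom brain
carrying the labeled reward-circuit ROIs, plus participant (group, PDS)
and longitudinal clinical tables.

Reliability model: within a condition, trial i's multivoxel feedback
amplitude over ROI voxels is

    p_i = sqrt(rho) * c + sqrt(1 - rho) * eps_i

with c a per-subject condition template and eps_i fresh standard-normal
noise, both unit-variance, so the expected trial-pair Pearson correlation
equals rho -- the generative quantity whose recovery validates the whole
RS pipeline. Rewarded templates of the two sessions share a correlation
kappa, giving an analytic cross-condition RS of kappa*sqrt(rho_A*rho_B).
Feedback responses are HRF-convolved; fractal and word phases contribute
separate nuisance responses; AR(1) voxel noise, a constant baseline and
optional global intensity spikes complete the run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .design import SessionDesign, TaskConfig, generate_session_design, \
    write_events_tsv
from .hrf import HRFSpec
from .glm import convolve_events
from .phantom import Phantom, PhantomSpec, build_phantom, \
    default_phantom_spec, save_phantom
from .words import default_word_pool, select_stimuli

CONDITIONS = ("anxiety_rewarded", "anxiety_nonrewarded",
              "neutral_rewarded", "neutral_nonrewarded")

SESSIONS = ("anxiety", "neutral")


@dataclass
class SimConfig:
    """Signal/noise parameters of the BOLD simulator."""

    signal_scale: float = 1.0        # sd of feedback amplitudes (a.u.)
    nuisance_scale: float = 0.5      # sd of fractal/word phase amplitudes
    baseline: float = 1000.0         # constant image intensity
    ar_coef: float = 0.3             # AR(1) coefficient of voxel noise
    spike_magnitude: float = 12.0    # global intensity jump of spike volumes
    hrf: HRFSpec = field(default_factory=HRFSpec)


@dataclass
class SubjectTruth:
    """Generative ground truth for one simulated participant."""

    subject_id: str
    group: str                                  # AN | CON
    pds: float                                  # pubertal development, 5-20
    reliability_by_condition: dict[str, float]  # condition -> rho in [0, 1]
    noise_sd: float = 2.0
    spike_volumes: dict[str, list[int]] = field(default_factory=dict)
    cross_template_corr: float = 0.5            # kappa between rewarded templates
    template_seed: int = 0

    def __post_init__(self) -> None:
        if self.group not in ("AN", "CON"):
            raise ValueError(f"group must be AN or CON, got {self.group!r}")
        if not 5 <= self.pds <= 20:
            raise ValueError("PDS must lie in [5, 20]")
        for cond, rho in self.reliability_by_condition.items():
            if not 0 <= rho <= 1:
                raise ValueError(f"reliability rho for {cond} outside [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def make_subject_templates(n_voxels: int, kappa: float,
                           seed: int) -> dict[str, np.ndarray]:
    """Per-condition unit-variance template patterns for one subject.

    The two rewarded-condition templates share correlation ``kappa``;
    non-rewarded templates are independent of everything else.
    """
    if not -1 <= kappa <= 1:
        raise ValueError("kappa must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    base = rng.standard_normal(n_voxels)
    other = rng.standard_normal(n_voxels)
    templates = {
        "anxiety_rewarded": base,
        "neutral_rewarded": kappa * base + np.sqrt(1 - kappa ** 2) * other,
        "anxiety_nonrewarded": rng.standard_normal(n_voxels),
        "neutral_nonrewarded": rng.standard_normal(n_voxels),
    }
    return templates


def draw_trial_patterns(template: np.ndarray, rho: float, n_trials: int,
                        rng: np.random.Generator) -> np.ndarray:
    """(n_trials, n_voxels) patterns with E[trial-pair r] = rho."""
    if not 0 <= rho <= 1:
        raise ValueError("rho must lie in [0, 1]")
    eps = rng.standard_normal((n_trials, template.size))
    return np.sqrt(rho) * template + np.sqrt(1 - rho) * eps


def _ar1_noise(rng: np.random.Generator, shape_vox: int, n_volumes: int,
               sd: float, phi: float) -> np.ndarray:
    """(n_voxels, n_volumes) stationary AR(1) noise with marginal sd."""
    if sd == 0:
        return np.zeros((shape_vox, n_volumes), dtype=np.float32)
    innov_sd = sd * np.sqrt(1 - phi ** 2)
    noise = np.empty((shape_vox, n_volumes), dtype=np.float32)
    noise[:, 0] = sd * rng.standard_normal(shape_vox)
    innov = innov_sd * rng.standard_normal((shape_vox, n_volumes - 1))
    for t in range(1, n_volumes):
        noise[:, t] = phi * noise[:, t - 1] + innov[:, t - 1]
    return noise


def simulate_session_bold(design: SessionDesign, phantom: Phantom,
                          truth: SubjectTruth, seed: int,
                          sim: SimConfig = SimConfig(),
                          templates: dict[str, np.ndarray] | None = None):
    """Simulate one 4-D session run.

    Returns ``(data, info)`` where data is float32 (x, y, z, t) and info
    records the per-trial amplitude patterns, ROI voxel indices and the
    condition of every trial -- the ground truth that downstream recovery
    tests compare against.
    """
    rng = np.random.default_rng(seed)
    roi_idx = phantom.union_indices()
    n_roi = len(roi_idx)
    if templates is None:
        templates = make_subject_templates(n_roi, truth.cross_template_corr,
                                           truth.template_seed)
    word = design.word_type
    n_vol, tr = design.n_volumes, design.tr
    grid = phantom.labels.shape

    signal_roi = np.zeros((n_roi, n_vol))
    patterns: dict[str, np.ndarray] = {}
    trial_order: dict[str, list[int]] = {}
    for rewarded in (True, False):
        cond = f"{word}_{'rewarded' if rewarded else 'nonrewarded'}"
        rho = truth.reliability_by_condition.get(cond, 0.0)
        events = design.feedback_events(rewarded)
        if not events:
            continue
        events = sorted(events, key=lambda e: e.trial_index)
        pats = draw_trial_patterns(templates[cond][:n_roi], rho,
                                   len(events), rng)
        patterns[cond] = pats
        trial_order[cond] = [e.trial_index for e in events]
        for pat, ev in zip(pats, events):
            reg = convolve_events([ev], n_vol, tr, sim.hrf)
            signal_roi += np.outer(pat, reg) * sim.signal_scale

    # nuisance responses shared across ROI voxels with random amplitudes
    for phase in ("fractal", "word"):
        amp = sim.nuisance_scale * rng.standard_normal(n_roi)
        reg = convolve_events(design.phase_events(phase), n_vol, tr, sim.hrf)
        signal_roi += np.outer(amp, reg)

    data = np.empty(grid + (n_vol,), dtype=np.float32)
    data[:] = sim.baseline
    noise = _ar1_noise(rng, int(np.prod(grid)), n_vol, truth.noise_sd,
                       sim.ar_coef)
    data += noise.reshape(grid + (n_vol,))
    data[tuple(roi_idx.T)] += signal_roi.astype(np.float32)

    spikes = (truth.spike_volumes.get(word, [])
              if isinstance(truth.spike_volumes, dict)
              else list(truth.spike_volumes))
    for t in spikes:
        data[..., t] += sim.spike_magnitude

    info = {"patterns": patterns, "trial_order": trial_order,
            "roi_indices": roi_idx, "templates": templates,
            "spike_volumes": list(spikes), "seed": seed}
    return data, info


# ---------------------------------------------------------------------------
# Cohort generation


@dataclass
class GroupSpec:
    """Per-group generative parameters (means, spreads)."""

    n: int
    rho_mean: dict[str, float]
    rho_sd: float = 0.04
    pds_mean: float = 16.0
    pds_sd: float = 2.0
    bmi_entry_mean: float = 50.0
    bmi_entry_sd: float = 15.0
    ede_entry_mean: float = 1.0
    ede_entry_sd: float = 0.7
    cdrs_mean: float = 25.0
    cdrs_sd: float = 8.0
    hama_mean: float = 8.0
    hama_sd: float = 4.0
    ybc_mean: float = 3.0
    ybc_sd: float = 3.0


def _default_groups() -> dict[str, GroupSpec]:
    # Sample structure and covariate/clinical distributions follow the
    # study cohort: 25 AN (PDS 14.2 +/- 4.3, adjusted-BMI percentile
    # 27 +/- 18, elevated symptom scores) and 22 controls (PDS
    # 17.9 +/- 1.4, adjusted-BMI 63 +/- 23). Reliability means encode the
    # group difference confined to the neutral-word rewarded condition.
    an = GroupSpec(
        n=25,
        rho_mean={"anxiety_rewarded": 0.18, "anxiety_nonrewarded": 0.16,
                  "neutral_rewarded": 0.12, "neutral_nonrewarded": 0.16},
        pds_mean=14.2, pds_sd=4.3,
        bmi_entry_mean=27.0, bmi_entry_sd=18.0,
        ede_entry_mean=3.5, ede_entry_sd=1.6,
        cdrs_mean=42.0, cdrs_sd=18.0, hama_mean=14.3, hama_sd=7.8,
        ybc_mean=24.0, ybc_sd=10.0)
    con = GroupSpec(
        n=22,
        rho_mean={"anxiety_rewarded": 0.18, "anxiety_nonrewarded": 0.16,
                  "neutral_rewarded": 0.20, "neutral_nonrewarded": 0.16},
        pds_mean=17.9, pds_sd=1.4,
        bmi_entry_mean=63.0, bmi_entry_sd=23.0,
        ede_entry_mean=0.5, ede_entry_sd=0.7,
        cdrs_mean=23.0, cdrs_sd=5.5, hama_mean=7.2, hama_sd=4.5,
        ybc_mean=1.5, ybc_sd=3.0)
    return {"AN": an, "CON": con}


@dataclass
class CohortSpec:
    """Everything the cohort generator needs."""

    groups: dict[str, GroupSpec] = field(default_factory=_default_groups)
    task: TaskConfig = field(default_factory=TaskConfig)
    sim: SimConfig = field(default_factory=SimConfig)
    phantom: PhantomSpec = field(default_factory=default_phantom_spec)
    noise_sd: float = 2.0
    spike_rate: float = 12.0         # mean spike volumes per run (Poisson)
    max_spikes: int = 65
    cross_template_corr: float = 0.5
    bmi_slope_per_month: float = 3.0  # AN recovery slope, percentile/month
    bmi_slope_per_rs: float = 0.0     # optional RS dependence of the slope
    clinical_noise_sd: float = 3.0


@dataclass
class ClinicalTruth:
    subject_id: str
    adjusted_bmi_series: list[float]   # entry + 6 monthly values
    ede_entry: float
    ede_6mo: float
    bas_entry: float
    bas_6mo: float

    def __post_init__(self) -> None:
        if len(self.adjusted_bmi_series) != 7:
            raise ValueError("adjusted-BMI series must hold 7 values")
        if not all(0 <= v <= 100 for v in self.adjusted_bmi_series):
            raise ValueError("adjusted-BMI percentiles must lie in [0, 100]")


def _truncated_normal(rng, mean, sd, lo, hi, size=None):
    x = rng.normal(mean, sd, size=size)
    return np.clip(x, lo, hi)


def draw_subject_truths(spec: CohortSpec, seed: int) -> list[SubjectTruth]:
    """Sample per-subject generative parameters for the whole cohort."""
    rng = np.random.default_rng(seed)
    truths = []
    i = 0
    for group, gs in spec.groups.items():
        for _ in range(gs.n):
            i += 1
            sid = f"sub-{i:03d}"
            rel = {c: float(_truncated_normal(rng, m, gs.rho_sd, 0.0, 1.0))
                   for c, m in gs.rho_mean.items()}
            pds = float(_truncated_normal(rng, gs.pds_mean, gs.pds_sd, 5, 20))
            spikes = {}
            for sess in SESSIONS:
                k = min(int(rng.poisson(spec.spike_rate)), spec.max_spikes)
                spikes[sess] = sorted(
                    rng.choice(np.arange(1, spec.task.n_volumes), size=k,
                               replace=False).tolist()) if k else []
            truths.append(SubjectTruth(
                sid, group, pds, rel, spec.noise_sd, spikes,
                spec.cross_template_corr,
                template_seed=int(rng.integers(2 ** 31))))
    return truths


def generate_clinical(truths: list[SubjectTruth], spec: CohortSpec,
                      rs_cross: dict[str, float], seed: int
                      ) -> tuple[pd.DataFrame, list[ClinicalTruth]]:
    """Longitudinal clinical table (long format) plus ground truth.

    AN adjusted-BMI percentiles rise by ``bmi_slope_per_month`` (+ an
    optional ``bmi_slope_per_rs`` * centered cross-condition RS term, for
    mixed-model power studies); controls stay flat. EDE declines in AN
    over 6 months; BAS is stable in both groups. Baseline-only measures
    (CDRS, HAM-A, YBC-EDS) support the partial-correlation analyses.
    """
    rng = np.random.default_rng(seed)
    rows = []
    truth_rows = []
    rs_vals = np.array([rs_cross[t.subject_id] for t in truths])
    rs_center = float(rs_vals.mean())
    for t in truths:
        gs = spec.groups[t.group]
        entry = float(_truncated_normal(rng, gs.bmi_entry_mean,
                                        gs.bmi_entry_sd, 1, 99))
        slope = 0.0
        if t.group == "AN":
            slope = spec.bmi_slope_per_month + spec.bmi_slope_per_rs * (
                rs_cross[t.subject_id] - rs_center)
        bmi = [float(np.clip(entry + slope * m
                             + rng.normal(0, spec.clinical_noise_sd), 0, 100))
               for m in range(7)]
        ede0 = float(max(rng.normal(gs.ede_entry_mean, gs.ede_entry_sd), 0))
        ede_drop = rng.normal(1.0, 0.5) if t.group == "AN" else 0.0
        ede1 = float(max(ede0 - ede_drop + rng.normal(0, 0.3), 0))
        bas0 = float(rng.normal(16.5, 2.2))
        bas1 = float(bas0 + rng.normal(0, 1.0))
        cdrs = float(max(rng.normal(gs.cdrs_mean, gs.cdrs_sd), 17))
        hama = float(max(rng.normal(gs.hama_mean, gs.hama_sd), 0))
        ybc = float(max(rng.normal(gs.ybc_mean, gs.ybc_sd), 0))

        truth_rows.append(ClinicalTruth(t.subject_id, bmi, ede0, ede1,
                                        bas0, bas1))
        for m, v in enumerate(bmi):
            tp = "entry" if m == 0 else f"month{m}"
            rows.append((t.subject_id, "adjusted_bmi", tp, v))
        rows.append((t.subject_id, "ede", "entry", ede0))
        rows.append((t.subject_id, "ede", "6mo", ede1))
        rows.append((t.subject_id, "bas", "entry", bas0))
        rows.append((t.subject_id, "bas", "6mo", bas1))
        for name, v in (("cdrs", cdrs), ("ham_a", hama), ("ybc_eds", ybc)):
            rows.append((t.subject_id, name, "entry", v))
    table = pd.DataFrame(rows, columns=["subject_id", "measure",
                                        "timepoint", "value"])
    return table, truth_rows


@dataclass
class Cohort:
    """In-memory handle on a generated cohort tree."""

    root: Path
    phantom: Phantom
    truths: list[SubjectTruth]
    participants: pd.DataFrame
    clinical: pd.DataFrame
    manifest: dict


def generate_cohort(spec: CohortSpec, seed: int, out_dir,
                    write_bold: bool = True) -> Cohort:
    """Generate the full synthetic study tree.

    Layout: ``phantom_labels.nii.gz``, ``participants.csv``,
    ``clinical.csv``, ``manifest.json`` and per subject
    ``sub-XXX/ses-{anxiety,neutral}/`` holding ``events.tsv`` and
    ``bold.nii.gz`` (BOLD writing can be disabled to generate designs
    and tables only). Bit-reproducible for a fixed seed.
    """
    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)
    rng_root = np.random.SeedSequence(seed)
    truth_seed, clin_seed, sess_seed = (
        int(s.generate_state(1)[0] % (2 ** 31))
        for s in rng_root.spawn(3))

    phantom = build_phantom(spec.phantom)
    save_phantom(phantom, root / "phantom_labels.nii.gz")
    truths = draw_subject_truths(spec, truth_seed)

    word_pool = default_word_pool(seed=truth_seed)
    sess_rng = np.random.default_rng(sess_seed)
    participants = pd.DataFrame(
        [(t.subject_id, t.group, t.pds) for t in truths],
        columns=["subject_id", "group", "pds"])
    participants.to_csv(root / "participants.csv", index=False)

    manifest = {"seed": seed, "spec": _spec_summary(spec),
                "roi_roles": sorted(phantom.legend),
                "subjects": {}, "stimuli": {}}
    rs_cross_truth: dict[str, float] = {}
    for t in truths:
        stim = select_stimuli(word_pool, t.group)
        manifest["stimuli"][t.subject_id] = {
            "anxiety": list(stim.anxiety_words),
            "neutral": list(stim.neutral_words)}
        sub_entry = {"pds": t.pds, "group": t.group,
                     "reliability": t.reliability_by_condition,
                     "noise_sd": t.noise_sd,
                     "template_seed": t.template_seed,
                     "cross_template_corr": t.cross_template_corr,
                     "spike_volumes": t.spike_volumes, "sessions": {}}
        rho_a = t.reliability_by_condition.get("anxiety_rewarded", 0.0)
        rho_n = t.reliability_by_condition.get("neutral_rewarded", 0.0)
        rs_cross_truth[t.subject_id] = (
            t.cross_template_corr * float(np.sqrt(rho_a * rho_n)))
        for sess in SESSIONS:
            ses_dir = root / t.subject_id / f"ses-{sess}"
            ses_dir.mkdir(parents=True, exist_ok=True)
            dseed = int(sess_rng.integers(2 ** 31))
            bseed = int(sess_rng.integers(2 ** 31))
            design = generate_session_design(sess, dseed, spec.task)
            write_events_tsv(design, ses_dir / "events.tsv")
            sub_entry["sessions"][sess] = {"design_seed": dseed,
                                           "bold_seed": bseed}
            if write_bold:
                data, _ = simulate_session_bold(design, phantom, t, bseed,
                                                spec.sim)
                img = nib.Nifti1Image(data, phantom.affine)
                nib.save(img, ses_dir / "bold.nii.gz")
        manifest["subjects"][t.subject_id] = sub_entry

    clinical, _ = generate_clinical(truths, spec, rs_cross_truth, clin_seed)
    clinical.to_csv(root / "clinical.csv", index=False)
    manifest["expected_rs_cross"] = rs_cross_truth
    (root / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                   sort_keys=True))
    return Cohort(root, phantom, truths, participants, clinical, manifest)


def load_cohort(root) -> Cohort:
    """Rebuild a Cohort handle from a generated tree on disk."""
    root = Path(root)
    manifest = json.loads((root / "manifest.json").read_text())
    labels_img = nib.load(str(root / "phantom_labels.nii.gz"))
    labels = np.asarray(labels_img.dataobj).astype(np.int16)
    # legend follows the deterministic (sorted-role) labeling of build_phantom
    roles = sorted(_roi_roles(labels, manifest))
    phantom = Phantom(labels, {r: i + 1 for i, r in enumerate(roles)},
                      labels_img.affine)
    participants = pd.read_csv(root / "participants.csv")
    clinical = pd.read_csv(root / "clinical.csv")
    truths = []
    for sid, entry in sorted(manifest["subjects"].items()):
        truths.append(SubjectTruth(
            sid, entry["group"], entry["pds"], entry["reliability"],
            entry["noise_sd"], entry["spike_volumes"],
            entry["cross_template_corr"], entry["template_seed"]))
    return Cohort(root, phantom, truths, participants, clinical, manifest)


def _roi_roles(labels: np.ndarray, manifest: dict) -> list[str]:
    """Role names for a label volume; stored in the manifest when present,
    else the default reward-mask roles."""
    roles = manifest.get("roi_roles")
    if roles:
        return list(roles)
    from .phantom import ROI_ROLES

    n = int(labels.max())
    return sorted(ROI_ROLES)[:n]


def _spec_summary(spec: CohortSpec) -> dict:
    return {
        "groups": {g: asdict(gs) for g, gs in spec.groups.items()},
        "task": asdict(spec.task),
        "sim": asdict(spec.sim),
        "grid_shape": list(spec.phantom.grid_shape),
        "noise_sd": spec.noise_sd,
        "spike_rate": spec.spike_rate,
        "cross_template_corr": spec.cross_template_corr,
        "bmi_slope_per_month": spec.bmi_slope_per_month,
        "bmi_slope_per_rs": spec.bmi_slope_per_rs,
    }
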