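"""Single-trial beta estimation with least-squares-sum (LSS) GLMs.

For every feedback event, a separate GLM is fit whose regressors are
(1) the HRF-convolved indicator of that single target trial, (2) the
HRF-convolved sum of all other feedback events, (3) one summed nuisance
regressor each for the fractal and word phases, (4) a cosine high-pass
drift basis, and (5) an intercept. The target coefficient across voxels
forms that trial's multivoxel pattern; stacking all trials of a run gives
the trial x voxel matrix that the representational-similarity stage
consumes.

Censored volumes are handled by row deletion, which is equivalent to
spike regressors for ordinary-least-squares point estimates.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import linalg

from .design import SessionDesign, TrialEvent
from .hrf import HRFSpec, hrf_kernel
from .qc import CensorSet

logger = logging.getLogger(__name__)

#: oversampling factor for boxcar/HRF convolution
_OVERSAMPLE = 10

#: default high-pass cutoff for the cosine drift basis (seconds)
DEFAULT_HIGHPASS_S = 100.0


def convolve_events(events: list[TrialEvent], n_volumes: int, tr: float,
                    hrf_spec: HRFSpec = HRFSpec()) -> np.ndarray:
    """HRF-convolved summed boxcar of a set of events, sampled at the TR.

    The boxcar is built on a grid oversampled 10x relative to the TR, so
    onsets and durations that are not TR multiples are represented
    faithfully before downsampling.
    """
    if not events:
        return np.zeros(n_volumes)
    dt = tr / _OVERSAMPLE
    n_fine = n_volumes * _OVERSAMPLE
    box = np.zeros(n_fine)
    for e in events:
        i0 = int(round(e.onset / dt))
        i1 = int(round((e.onset + e.duration) / dt))
        box[i0:min(i1, n_fine)] = 1.0
    kernel = hrf_kernel(hrf_spec, dt)
    reg = np.convolve(box, kernel)[:n_fine]
    return reg[::_OVERSAMPLE].copy()


def cosine_drift_basis(n_volumes: int, tr: float,
                       cutoff_s: float = DEFAULT_HIGHPASS_S) -> np.ndarray:
    """DCT-II high-pass basis with periods longer than ``cutoff_s``."""
    duration = n_volumes * tr
    order = int(np.floor(2 * duration / cutoff_s))
    t = np.arange(n_volumes) + 0.5
    cols = [np.sqrt(2.0 / n_volumes) * np.cos(np.pi * k * t / n_volumes)
            for k in range(1, order + 1)]
    if not cols:
        return np.zeros((n_volumes, 0))
    return np.column_stack(cols)


@dataclass
class DesignMatrix:
    matrix: np.ndarray          # (kept volumes, regressors)
    names: list[str]
    rows: np.ndarray            # original volume indices of the kept rows
    target_col: int = 0

    def __post_init__(self) -> None:
        if self.matrix.shape[1] != len(self.names):
            raise ValueError("column count does not match names")


def _dependent_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Names of columns beyond the numerical rank, via pivoted QR."""
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return []
    _, _, piv = linalg.qr(X, mode="economic", pivoting=True)
    return [names[j] for j in sorted(piv[rank:])]


def build_lss_design(design: SessionDesign, target_trial: int,
                     censor: CensorSet | None = None,
                     hrf_spec: HRFSpec = HRFSpec(),
                     highpass_s: float = DEFAULT_HIGHPASS_S) -> DesignMatrix:
    """LSS design matrix for one target feedback event.

    Raises if the matrix is rank-deficient after censoring (e.g. when all
    volumes supporting the target response are censored), naming the
    offending columns.
    """
    n_vol, tr = design.n_volumes, design.tr
    feedback = design.feedback_events()
    targets = [e for e in feedback if e.trial_index == target_trial]
    if not targets:
        raise ValueError(f"trial {target_trial} has no feedback event")
    others = [e for e in feedback if e.trial_index != target_trial]

    cols = [convolve_events(targets, n_vol, tr, hrf_spec)]
    names = ["target"]

    def add_if_nonzero(events, name):
        col = convolve_events(events, n_vol, tr, hrf_spec)
        if np.abs(col).max() > 0:
            cols.append(col)
            names.append(name)

    # empty or absent event classes contribute no regressor
    add_if_nonzero(others, "other_trials")
    add_if_nonzero(design.phase_events("fractal"), "fractal")
    add_if_nonzero(design.phase_events("word"), "word")
    drift = cosine_drift_basis(n_vol, tr, highpass_s)
    for k in range(drift.shape[1]):
        cols.append(drift[:, k])
        names.append(f"drift_{k + 1}")
    cols.append(np.ones(n_vol))
    names.append("intercept")

    X = np.column_stack(cols)
    rows = np.arange(n_vol) if censor is None else censor.kept_volumes()
    X = X[rows]
    if np.allclose(X[:, 0], 0):
        raise ValueError(
            f"trial {target_trial}: censoring removed the whole target-event "
            "support; design is rank deficient in columns ['target']")
    bad = _dependent_columns(X, names)
    if bad:
        raise ValueError(
            f"trial {target_trial}: design rank deficient after censoring "
            f"in columns {bad}")
    return DesignMatrix(X, names, rows, target_col=0)


@dataclass
class TrialBetaStack:
    """Per-trial beta patterns restricted to a voxel set.

    ``betas`` has one row per retained trial in the order of ``meta``;
    columns follow ``voxel_indices`` (n_voxels, 3).
    """

    betas: np.ndarray
    meta: pd.DataFrame          # trial_index, word_type, rewarded, session
    voxel_indices: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.betas.shape[0] != len(self.meta):
            raise ValueError("betas rows must match metadata rows")
        if self.betas.shape[1] != len(self.voxel_indices):
            raise ValueError("betas columns must match voxel index list")

    def select(self, word_type: str | None = None,
               rewarded: bool | None = None) -> "TrialBetaStack":
        keep = np.ones(len(self.meta), dtype=bool)
        if word_type is not None:
            keep &= (self.meta["word_type"] == word_type).to_numpy()
        if rewarded is not None:
            keep &= (self.meta["rewarded"].astype(bool) == rewarded).to_numpy()
        return TrialBetaStack(self.betas[keep],
                              self.meta.loc[keep].reset_index(drop=True),
                              self.voxel_indices, self.subject_id)

    def concat(self, other: "TrialBetaStack") -> "TrialBetaStack":
        if not np.array_equal(self.voxel_indices, other.voxel_indices):
            raise ValueError("voxel bases differ; cannot concatenate stacks")
        return TrialBetaStack(
            np.vstack([self.betas, other.betas]),
            pd.concat([self.meta, other.meta], ignore_index=True),
            self.voxel_indices, self.subject_id)

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        np.savetxt(out / "betas.tsv", self.betas, delimiter="\t")
        self.meta.to_csv(out / "trials.tsv", sep="\t", index=False)
        sidecar = {"subject_id": self.subject_id,
                   "voxel_indices": self.voxel_indices.tolist()}
        (out / "stack.json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, in_dir) -> "TrialBetaStack":
        p = Path(in_dir)
        sidecar = json.loads((p / "stack.json").read_text())
        return cls(np.atleast_2d(np.loadtxt(p / "betas.tsv", delimiter="\t")),
                   pd.read_csv(p / "trials.tsv", sep="\t"),
                   np.asarray(sidecar["voxel_indices"], dtype=int),
                   sidecar["subject_id"])


def estimate_trial_betas(run: np.ndarray, design: SessionDesign,
                         mask: np.ndarray,
                         censor: CensorSet | None = None,
                         rewarded_only: bool | None = None,
                         hrf_spec: HRFSpec = HRFSpec(),
                         highpass_s: float = DEFAULT_HIGHPASS_S,
                         subject_id: str = "",
                         session: str = "",
                         on_error: str = "raise") -> TrialBetaStack:
    """Fit one LSS GLM per feedback event and stack the target betas.

    ``rewarded_only`` restricts estimation to rewarded (True) or
    non-rewarded (False) feedback events; None keeps all trials.
    ``on_error="skip"`` drops trials whose design is unestimable after
    censoring (e.g. the whole response support was flagged) with a logged
    warning, mirroring the per-condition trial counts of real censored
    data; the default propagates the error with the trial identity.
    """
    if on_error not in ("raise", "skip"):
        raise ValueError("on_error must be 'raise' or 'skip'")
    mask = np.asarray(mask, dtype=bool)
    voxel_indices = np.argwhere(mask)
    Y_all = run[mask, :].T.astype(float)    # (n_volumes, n_voxels)

    events = design.feedback_events(rewarded_only)
    rows_meta = []
    betas = []
    for e in sorted(events, key=lambda ev: ev.trial_index):
        try:
            dm = build_lss_design(design, e.trial_index, censor, hrf_spec,
                                  highpass_s)
        except ValueError as err:
            if on_error == "skip":
                logger.warning("%s %s: dropping trial %d: %s", subject_id,
                               session, e.trial_index, err)
                continue
            raise ValueError(f"trial {e.trial_index}: {err}") from err
        Y = Y_all[dm.rows]
        coef, *_ = np.linalg.lstsq(dm.matrix, Y, rcond=None)
        betas.append(coef[dm.target_col])
        rows_meta.append((e.trial_index, e.word_type, bool(e.rewarded),
                          session))
    meta = pd.DataFrame(rows_meta, columns=["trial_index", "word_type",
                                            "rewarded", "session"])
    return TrialBetaStack(np.asarray(betas), meta, voxel_indices, subject_id)
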