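"""Representational-similarity (RS) statistics over trial beta patterns.

RS here is trial-to-trial neural consistency: the mean Pearson
correlation between the multivoxel patterns of all trial pairs of one
condition. It is computed either over the whole ROI mask at once
("pairwise" mode) or voxelwise with a moving spherical searchlight whose
per-voxel values are Fisher z-transformed and averaged over the mask
("searchlight" mode, the default). Cross-condition RS correlates every
trial of one condition with every trial of the other.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import nibabel as nib
import numpy as np

from .glm import TrialBetaStack
from .phantom import DEFAULT_AFFINE

logger = logging.getLogger(__name__)

#: clipping bound keeping atanh finite on degenerate |r| = 1 inputs
FISHER_EPS = 1e-7

#: searchlight spheres smaller than this yield a missing value
MIN_SPHERE_VOXELS = 5

AGG_MODES = ("searchlight", "pairwise")


def fisher_z(r):
    """Variance-stabilizing r-to-z transform, clipped away from |r| = 1."""
    r = np.clip(np.asarray(r, dtype=float), -1 + FISHER_EPS, 1 - FISHER_EPS)
    return np.arctanh(r)


@dataclass
class SimilarityMatrix:
    """N x N Pearson correlations between trial patterns of one condition."""

    values: np.ndarray
    condition: str = ""
    trial_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("similarity matrix must be square")

    @property
    def n(self) -> int:
        return self.values.shape[0]


def similarity_matrix(patterns: np.ndarray,
                      condition: str = "") -> SimilarityMatrix:
    """Trial x trial Pearson correlation matrix of a pattern stack.

    Zero-variance trial patterns cannot be correlated; they are dropped
    with a logged warning and the retained trial ids recorded.
    """
    patterns = np.asarray(patterns, dtype=float)
    if patterns.ndim != 2 or patterns.shape[0] < 2:
        raise ValueError("need a (>=2 trials, voxels) pattern matrix")
    if patterns.shape[1] < 3:
        raise ValueError("need at least 3 voxels to correlate patterns")
    sd = patterns.std(axis=1)
    keep = sd > 0
    if not keep.all():
        logger.warning("excluding %d zero-variance trial pattern(s)",
                       int((~keep).sum()))
    if keep.sum() < 2:
        raise ValueError("fewer than 2 trials with nonzero variance")
    vals = np.corrcoef(patterns[keep])
    return SimilarityMatrix(vals, condition, np.flatnonzero(keep))


def mean_pairwise_rs(simmat: SimilarityMatrix | np.ndarray) -> float:
    """Mean of the N(N-1)/2 strictly-lower-triangle correlations."""
    values = simmat.values if isinstance(simmat, SimilarityMatrix) else simmat
    n = values.shape[0]
    if n < 2:
        raise ValueError("need at least 2 trials")
    return float(values[np.tril_indices(n, k=-1)].mean())


def sphere_offsets(radius: float) -> np.ndarray:
    """Integer offset triples with Euclidean norm <= radius.

    Radius 2 gives the 33-voxel searchlight sphere; radius 0 the center
    voxel only.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    r = int(np.floor(radius))
    g = np.arange(-r, r + 1)
    offs = np.stack(np.meshgrid(g, g, g, indexing="ij"), -1).reshape(-1, 3)
    return offs[(offs ** 2).sum(axis=1) <= radius ** 2]


@dataclass
class SearchlightMap:
    """Per-voxel mean trial-pair correlation (r) on a mask; NaN off-mask."""

    values: np.ndarray
    mask: np.ndarray
    radius: float
    condition: str = ""

    def masked_values(self) -> np.ndarray:
        return self.values[self.mask]

    def to_nifti(self, affine: np.ndarray | None = None) -> nib.Nifti1Image:
        aff = DEFAULT_AFFINE if affine is None else affine
        return nib.Nifti1Image(self.values.astype(np.float32), aff)


def _sphere_members(mask: np.ndarray, radius: float):
    """For each mask voxel, the flat pattern-column ids inside its sphere."""
    mask = np.asarray(mask, dtype=bool)
    vox = np.argwhere(mask)
    col_of = -np.ones(mask.shape, dtype=int)
    col_of[tuple(vox.T)] = np.arange(len(vox))
    offs = sphere_offsets(radius)
    shape = np.asarray(mask.shape)
    members = []
    for center in vox:
        pts = center + offs
        ok = ((pts >= 0) & (pts < shape)).all(axis=1)
        cols = col_of[tuple(pts[ok].T)]
        members.append(cols[cols >= 0])
    return vox, members


def _mean_cross_r(a: np.ndarray, b: np.ndarray) -> float:
    """Mean Pearson correlation over all rows(a) x rows(b) pairs."""
    az = (a - a.mean(1, keepdims=True))
    bz = (b - b.mean(1, keepdims=True))
    asd = az.std(1)
    bsd = bz.std(1)
    if (asd == 0).any() or (bsd == 0).any():
        raise ValueError("zero-variance pattern in cross-correlation")
    c = (az / asd[:, None]) @ (bz / bsd[:, None]).T / a.shape[1]
    return float(c.mean())


def searchlight_rs(stack: TrialBetaStack, mask: np.ndarray,
                   radius: float = 2.0, condition: str = "",
                   min_voxels: int = MIN_SPHERE_VOXELS) -> SearchlightMap:
    """Searchlight map of mean trial-pair correlation.

    Spheres are intersected with the mask, so boundary spheres hold fewer
    voxels; spheres below ``min_voxels`` yield NaN. The stack must carry
    the trials of a single condition (select before calling).
    """
    if stack.betas.shape[0] < 2:
        raise ValueError(f"condition {condition!r} has fewer than 2 trials")
    mask = np.asarray(mask, dtype=bool)
    stack_cols = -np.ones(mask.shape, dtype=int)
    stack_cols[tuple(stack.voxel_indices.T)] = np.arange(
        len(stack.voxel_indices))
    if (stack_cols[mask] < 0).any():
        raise ValueError("mask contains voxels absent from the beta stack")

    vox, members = _sphere_members(mask, radius)
    remap = stack_cols[tuple(vox.T)]
    values = np.full(mask.shape, np.nan)
    pat = stack.betas
    for center, cols in zip(vox, members):
        if len(cols) < max(min_voxels, 2):
            continue
        sub = pat[:, remap[cols]]
        sd = sub.std(axis=1)
        if (sd == 0).any():
            continue
        r = np.corrcoef(sub)
        values[tuple(center)] = r[np.tril_indices(r.shape[0], k=-1)].mean()
    return SearchlightMap(values, mask, radius, condition)


@dataclass
class RsSummary:
    subject_id: str
    condition: str
    mean_z: float
    mode: str
    log_value: float = np.nan

    def __post_init__(self) -> None:
        if not np.isfinite(self.mean_z):
            raise ValueError("mean_z must be finite")


def mask_rs_summary(source, mask: np.ndarray, mode: str = "searchlight",
                    radius: float = 2.0, subject_id: str = "",
                    condition: str = "", with_log: bool = False,
                    log_shift: float | None = None) -> RsSummary:
    """One RS value per participant/condition, aggregated over the mask.

    searchlight mode: z-transform each voxel's searchlight r and average
    over defined mask voxels. pairwise mode: one similarity matrix over
    all mask voxels, averaging z-transformed trial pairs. ``with_log``
    adds ln(mean_z) (optionally after a configured shift) for the ANCOVA
    stage.
    """
    if mode not in AGG_MODES:
        raise ValueError(f"mode must be one of {AGG_MODES}")
    if mode == "searchlight":
        sl = (source if isinstance(source, SearchlightMap)
              else searchlight_rs(source, mask, radius, condition))
        vals = sl.masked_values()
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError("no defined searchlight values on the mask")
        mean_z = float(fisher_z(vals).mean())
    else:
        if not isinstance(source, TrialBetaStack):
            raise ValueError("pairwise mode needs a TrialBetaStack")
        cols = _stack_columns_for_mask(source, mask)
        sim = similarity_matrix(source.betas[:, cols], condition)
        z = fisher_z(sim.values[np.tril_indices(sim.n, k=-1)])
        mean_z = float(z.mean())

    log_value = np.nan
    if with_log:
        shifted = mean_z if log_shift is None else mean_z + log_shift
        if shifted <= 0:
            raise ValueError(
                "mean_z <= 0: log transform undefined without a configured "
                "shift")
        log_value = float(np.log(shifted))
    return RsSummary(subject_id, condition, mean_z, mode, log_value)


def _stack_columns_for_mask(stack: TrialBetaStack,
                            mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    col_of = -np.ones(mask.shape, dtype=int)
    col_of[tuple(stack.voxel_indices.T)] = np.arange(len(stack.voxel_indices))
    cols = col_of[mask]
    if (cols < 0).any():
        raise ValueError("mask contains voxels absent from the beta stack")
    return cols


def cross_condition_rs(stack_a: TrialBetaStack, stack_b: TrialBetaStack,
                       mask: np.ndarray, mode: str = "searchlight",
                       radius: float = 2.0,
                       min_voxels: int = MIN_SPHERE_VOXELS) -> float:
    """Mean z of all cross-pair correlations between two conditions.

    Pairs every trial of A with every trial of B; aggregation over the
    mask follows the same mode conventions as :func:`mask_rs_summary`.
    Higher values mean reward representations generalize across the two
    (anxiety/neutral) contexts.
    """
    if not np.array_equal(stack_a.voxel_indices, stack_b.voxel_indices):
        raise ValueError("stacks use different voxel bases")
    if len(stack_a.meta) < 1 or len(stack_b.meta) < 1:
        raise ValueError("both conditions need at least one trial")
    if mode not in AGG_MODES:
        raise ValueError(f"mode must be one of {AGG_MODES}")
    cols = _stack_columns_for_mask(stack_a, mask)
    if mode == "pairwise":
        r = _pairwise_cross_matrix(stack_a.betas[:, cols],
                                   stack_b.betas[:, cols])
        return float(fisher_z(r).mean())
    # searchlight mode: per-sphere mean cross r, z, averaged over mask
    mask = np.asarray(mask, dtype=bool)
    vox, members = _sphere_members(mask, radius)
    a = stack_a.betas[:, cols]
    b = stack_b.betas[:, cols]
    zs = []
    for cols_m in members:
        if len(cols_m) < max(min_voxels, 2):
            continue
        try:
            r = _mean_cross_r(a[:, cols_m], b[:, cols_m])
        except ValueError:
            continue
        zs.append(fisher_z(r))
    if not zs:
        raise ValueError("no defined searchlight values on the mask")
    return float(np.mean(zs))


def _pairwise_cross_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    az = a - a.mean(1, keepdims=True)
    bz = b - b.mean(1, keepdims=True)
    asd = az.std(1)
    bsd = bz.std(1)
    if (asd == 0).any() or (bsd == 0).any():
        raise ValueError("zero-variance pattern in cross-correlation")
    return (az / asd[:, None]) @ (bz / bsd[:, None]).T / a.shape[1]


def log_transform_cohort(values: np.ndarray,
                         delta: float = 0.01) -> tuple[np.ndarray, float]:
    """ln of cohort RS values, shifting when any value is non-positive.

    Returns (log values, shift used); shift is 0 when all values are
    positive, else ``-min + delta`` so the smallest value maps to
    ln(delta). The shift is recorded in output metadata downstream.
    """
    values = np.asarray(values, dtype=float)
    shift = 0.0
    if (values <= 0).any():
        shift = -values.min() + delta
    return np.log(values + shift), shift
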