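"""Nonparametric permutation inference on subject-level RS maps.

Group differences are tested with a covariate-adjusted two-sample model
under Freedman-Lane permutation: the data are residualized on the
nuisance covariate, residual rows are permuted, the nuisance fit is
added back, and the full model is refit. Each permuted t map is TFCE
enhanced and its maximum enters the null distribution; voxelwise FWE
p-values are the proportion of permutations (observed included) whose
maximum reaches the observed enhancement. Within-group effects use the
same machinery with sign-flipping of covariate-residualized maps.
Two-tailed inference runs separate positive/negative TFCE passes with a
Bonferroni factor over tails.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging
import math

import numpy as np

from .tfce import TfceParams, _tfce_one_tail

logger = logging.getLogger(__name__)


@dataclass
class PermResult:
    stat_map: np.ndarray        # t map (3-D, NaN off mask)
    tfce_map: np.ndarray        # signed TFCE of the observed t map
    fwe_p_map: np.ndarray       # voxelwise FWE-corrected p (1 off mask)
    n_permutations: int
    seed: int
    mask: np.ndarray
    max_null_pos: np.ndarray = field(default=None, repr=False)
    max_null_neg: np.ndarray = field(default=None, repr=False)

    def significant(self, alpha: float = 0.05) -> np.ndarray:
        return self.mask & (self.fwe_p_map <= alpha)


def _flatten_maps(maps, mask: np.ndarray) -> np.ndarray:
    """Stack subject maps into (n_subjects, n_mask_voxels)."""
    mask = np.asarray(mask, dtype=bool)
    rows = []
    for m in maps:
        m = np.asarray(m, dtype=float)
        if m.shape != mask.shape:
            raise ValueError("subject map shape differs from the mask")
        rows.append(m[mask])
    Y = np.asarray(rows)
    if not np.isfinite(Y).all():
        raise ValueError("non-finite values inside the mask")
    return Y


def _t_for_column(X: np.ndarray, Y: np.ndarray, col: int) -> np.ndarray:
    """Vectorized OLS t statistics for one column of X across map columns."""
    pinv = np.linalg.pinv(X)
    coef = pinv @ Y
    resid = Y - X @ coef
    df = X.shape[0] - X.shape[1]
    sigma2 = (resid ** 2).sum(axis=0) / df
    var_col = (pinv @ pinv.T)[col, col]
    se = np.sqrt(np.maximum(sigma2 * var_col, 1e-300))
    return coef[col] / se


def _fwe_from_null(obs_pos: np.ndarray, obs_neg: np.ndarray,
                   max_pos: np.ndarray, max_neg: np.ndarray,
                   n_perm: int, two_tailed: bool) -> np.ndarray:
    """Voxelwise FWE p from max-statistic null distributions."""
    # observed is included in its own null: counts start at 1
    p_pos = (1 + (max_pos[:, None] >= obs_pos[None, :]).sum(0)) / (n_perm + 1)
    p_neg = (1 + (max_neg[:, None] >= obs_neg[None, :]).sum(0)) / (n_perm + 1)
    if two_tailed:
        p = np.where(obs_pos > 0, p_pos, np.where(obs_neg > 0, p_neg, 1.0))
        return np.minimum(2.0 * p, 1.0)
    return p_pos


def _enhanced_tails(flat: np.ndarray, mask: np.ndarray,
                    params: TfceParams):
    vol = np.zeros(mask.shape)
    vol[mask] = flat
    pos = _tfce_one_tail(vol, mask, params)
    neg = _tfce_one_tail(-vol, mask, params)
    return pos[mask], neg[mask]


def _run_perm(Y: np.ndarray, X_full: np.ndarray, col: int, Z: np.ndarray,
              mask: np.ndarray, n_perm: int, seed: int,
              tfce_params: TfceParams, two_tailed: bool,
              draw_perm, freedman_lane: bool) -> PermResult:
    """Shared permutation engine.

    ``draw_perm(rng, n)`` yields either a permutation index array
    (label shuffling) or a sign vector (one-sample flips).
    """
    n = Y.shape[0]
    t_obs = _t_for_column(X_full, Y, col)
    # fix dh from the observed map so permuted maxima are comparable
    tmax = np.abs(t_obs).max()
    if tfce_params.dh is None and tmax > 0:
        tfce_params = TfceParams(tfce_params.E, tfce_params.H,
                                 tmax / tfce_params.n_steps,
                                 tfce_params.n_steps,
                                 tfce_params.connectivity)
    obs_pos, obs_neg = _enhanced_tails(t_obs, mask, tfce_params)

    if freedman_lane and Z.shape[1] > 0:
        Hz = Z @ np.linalg.pinv(Z)
        fitted = Hz @ Y
        resid = Y - fitted
    else:
        fitted = np.zeros_like(Y)
        resid = Y

    rng = np.random.default_rng(seed)
    max_pos = np.empty(n_perm)
    max_neg = np.empty(n_perm)
    for b in range(n_perm):
        draw = draw_perm(rng, n)
        if draw.dtype == bool:
            Y_star = fitted + resid * np.where(draw, 1.0, -1.0)[:, None]
        else:
            Y_star = fitted + resid[draw]
        t_b = _t_for_column(X_full, Y_star, col)
        p_b, n_b = _enhanced_tails(t_b, mask, tfce_params)
        max_pos[b] = p_b.max() if p_b.size else 0.0
        max_neg[b] = n_b.max() if n_b.size else 0.0

    fwe_flat = _fwe_from_null(obs_pos, obs_neg, max_pos, max_neg,
                              n_perm, two_tailed)
    stat_map = np.full(mask.shape, np.nan)
    stat_map[mask] = t_obs
    tfce_map = np.zeros(mask.shape)
    tfce_map[mask] = obs_pos - obs_neg
    fwe_map = np.ones(mask.shape)
    fwe_map[mask] = fwe_flat
    return PermResult(stat_map, tfce_map, fwe_map, n_perm, seed, mask,
                      max_pos, max_neg)


def cluster_table(result: PermResult, alpha: float = 0.05,
                  connectivity: int = 26):
    """Clusters of FWE-significant voxels, with peak statistics.

    Returns a DataFrame (cluster, size_voxels, t_max, peak_x, peak_y,
    peak_z, fwe_p_min) with 0-based voxel coordinates, ordered by size.
    """
    import pandas as pd
    from scipy import ndimage

    from .tfce import _STRUCTURES

    sig = result.significant(alpha)
    labels, n = ndimage.label(sig, structure=_STRUCTURES[connectivity])
    rows = []
    t = np.nan_to_num(result.stat_map)
    for lab in range(1, n + 1):
        vox = np.argwhere(labels == lab)
        tvals = np.abs(t[labels == lab])
        peak = vox[np.argmax(tvals)]
        rows.append((lab, len(vox), float(t[tuple(peak)]),
                     int(peak[0]), int(peak[1]), int(peak[2]),
                     float(result.fwe_p_map[labels == lab].min())))
    cols = ["cluster", "size_voxels", "t_max", "peak_x", "peak_y",
            "peak_z", "fwe_p_min"]
    return pd.DataFrame(sorted(rows, key=lambda r: -r[1]),
                        columns=cols).assign(
                            cluster=lambda d: np.arange(1, len(d) + 1))


def permutation_group_test(maps, group, covariate, mask: np.ndarray,
                           n_perm: int = 5000, seed: int = 0,
                           tfce_params: TfceParams = TfceParams(),
                           two_tailed: bool = True,
                           freedman_lane: bool = True) -> PermResult:
    """Covariate-adjusted two-sample permutation test with TFCE + FWE.

    ``maps`` is an iterable of subject 3-D maps; ``group`` a two-level
    label vector; the covariate (e.g. PDS) is a nuisance regressor.
    Freedman-Lane permutation is the default; ``freedman_lane=False``
    permutes raw rows, ignoring the covariate in the null construction.
    """
    mask = np.asarray(mask, dtype=bool)
    Y = _flatten_maps(maps, mask)
    group = np.asarray(group)
    levels = np.unique(group)
    if len(levels) != 2:
        raise ValueError("need exactly two groups")
    if min((group == l).sum() for l in levels) < 2:
        raise ValueError("need >= 2 subjects per group")
    g = (group == levels[1]).astype(float)
    c = np.asarray(covariate, dtype=float)
    n = len(g)
    X_full = np.column_stack([np.ones(n), g, c])
    Z = np.column_stack([np.ones(n), c])

    n_distinct = math.comb(n, int(g.sum()))
    if n_perm > n_distinct:
        logger.warning("n_perm=%d exceeds the %d distinct group relabelings",
                       n_perm, n_distinct)

    def draw(rng, n):
        return rng.permutation(n)

    return _run_perm(Y, X_full, 1, Z, mask, n_perm, seed, tfce_params,
                     two_tailed, draw, freedman_lane)


def one_sample_perm_test(maps, covariate, mask: np.ndarray,
                         n_perm: int = 5000, seed: int = 0,
                         tfce_params: TfceParams = TfceParams(),
                         two_tailed: bool = True) -> PermResult:
    """One-sample (intercept) permutation test with sign flipping.

    Tests whether the covariate-adjusted mean map differs from zero; the
    covariate is mean-centered so the intercept is the adjusted mean.
    The null is built by randomly sign-flipping covariate-residualized
    maps; TFCE and max-statistic FWE as in the two-sample test.
    """
    mask = np.asarray(mask, dtype=bool)
    Y = _flatten_maps(maps, mask)
    n = Y.shape[0]
    if n < 3:
        raise ValueError("need >= 3 subjects")
    c = np.asarray(covariate, dtype=float)
    c = c - c.mean()
    X_full = np.column_stack([np.ones(n), c])
    Z = c[:, None] if c.std() > 0 else np.zeros((n, 0))
    if n_perm > 2 ** n:
        logger.warning("n_perm=%d exceeds the %d distinct sign flips",
                       n_perm, 2 ** n)

    def draw(rng, n):
        return rng.random(n) < 0.5

    return _run_perm(Y, X_full, 0, Z, mask, n_perm, seed, tfce_params,
                     two_tailed, draw, freedman_lane=True)
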