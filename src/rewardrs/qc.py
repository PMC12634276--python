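"""Volume-quality control: DVARS and outlier-volume censoring.

DVARS is the root-mean-square of volume-to-volume intensity change within
a brain mask. Volumes whose DVARS exceeds the boxplot fence
(75th percentile + 1.5 x IQR of the run's DVARS values) are censored,
mirroring the default of the common motion-outlier tooling. Runs are
first rescaled so the within-mask median intensity equals 1000, making
the metric invariant to global intensity scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MEDIAN_TARGET = 1000.0


@dataclass
class DvarsSeries:
    values: np.ndarray  # length n_volumes, values[0] == 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("DVARS series must be 1-D")
        if (self.values < 0).any():
            raise ValueError("DVARS values must be nonnegative")


@dataclass
class CensorSet:
    run_id: str
    excluded_volumes: tuple[int, ...]
    n_volumes: int

    def __post_init__(self) -> None:
        ex = tuple(sorted(set(int(i) for i in self.excluded_volumes)))
        if ex and (ex[0] < 0 or ex[-1] >= self.n_volumes):
            raise ValueError("excluded volume index outside the run")
        self.excluded_volumes = ex

    @property
    def n_excluded(self) -> int:
        return len(self.excluded_volumes)

    @property
    def fraction_excluded(self) -> float:
        return self.n_excluded / self.n_volumes

    @property
    def percent_excluded(self) -> float:
        return 100.0 * self.fraction_excluded

    def kept_volumes(self) -> np.ndarray:
        keep = np.ones(self.n_volumes, dtype=bool)
        keep[list(self.excluded_volumes)] = False
        return np.flatnonzero(keep)


def compute_dvars(run: np.ndarray, mask: np.ndarray) -> DvarsSeries:
    """DVARS of a 4-D run within a boolean mask.

    value[t] = sqrt(mean over mask voxels of (I_t - I_{t-1})^2) after the
    run is rescaled to a within-mask median of 1000; value[0] = 0.
    """
    run = np.asarray(run)
    mask = np.asarray(mask, dtype=bool)
    if run.ndim != 4:
        raise ValueError("run must be 4-D (x, y, z, t)")
    if run.shape[3] < 2:
        raise ValueError("run must hold at least 2 volumes")
    if not mask.any():
        raise ValueError("mask is empty")
    data = run[mask, :].astype(float)  # (n_voxels, n_volumes)
    med = np.median(data)
    if med <= 0:
        raise ValueError("non-positive median intensity; cannot normalize")
    data = data * (MEDIAN_TARGET / med)
    diffs = np.diff(data, axis=1)
    values = np.zeros(run.shape[3])
    values[1:] = np.sqrt(np.mean(diffs ** 2, axis=0))
    return DvarsSeries(values)


def flag_outlier_volumes(dvars: DvarsSeries, run_id: str = "run") -> CensorSet:
    """Censor volumes above the boxplot fence Q75 + 1.5 x IQR.

    Quantiles are computed over the whole series (including the leading
    zero) with linear interpolation; only values strictly above the fence
    are flagged, so a constant series censors nothing.
    """
    v = dvars.values
    if v.size == 0:
        raise ValueError("empty DVARS series")
    q25, q75 = np.percentile(v, [25, 75])
    fence = q75 + 1.5 * (q75 - q25)
    excluded = np.flatnonzero(v > fence)
    return CensorSet(run_id, tuple(int(i) for i in excluded), v.size)
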