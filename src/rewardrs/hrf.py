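"""Canonical double-gamma hemodynamic response function."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class HRFSpec:
    """Double-gamma parameters (times in seconds).

    Defaults give the canonical shape: response gamma with mode near 5 s,
    undershoot gamma with mode near 15 s at 1/6 amplitude.
    """

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    length_s: float = 32.0


def hrf_kernel(spec: HRFSpec = HRFSpec(), tr: float = 1.0) -> np.ndarray:
    """Sample the double-gamma kernel on the TR grid.

    The kernel is the difference of two gamma densities, normalized to
    unit peak. ``kernel[0] == 0`` and the kernel integrates to a positive
    value for the default undershoot ratio.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    t = np.arange(0.0, spec.length_s, tr)
    peak = stats.gamma.pdf(t, spec.peak_delay / spec.peak_dispersion,
                           scale=spec.peak_dispersion)
    under = stats.gamma.pdf(t, spec.undershoot_delay / spec.undershoot_dispersion,
                            scale=spec.undershoot_dispersion)
    h = peak - spec.undershoot_ratio * under
    return h / np.abs(h).max()
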