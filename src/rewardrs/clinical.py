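"""Clinical associations: longitudinal mixed models, covariate-adjusted
partial correlations, and Benjamini-Hochberg FDR adjustment.

Three preset linear mixed models mirror the longitudinal analyses run on
the patient group: adjusted-BMI percentile over 7 monthly timepoints with
a cross-condition RS x time interaction; EDE global score over two
timepoints; and BAS reward responsiveness over two timepoints with
neutral-reward RS as a main effect only. PDS enters every preset as a
covariate. Random effects are subject intercept and time slope with an
unstructured covariance where the timepoint count identifies a slope,
otherwise intercept-only (logged).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

TIMEPOINT_CODES = {"entry": 0, "month1": 1, "month2": 2, "month3": 3,
                   "month4": 4, "month5": 5, "month6": 6, "6mo": 6}


# ---------------------------------------------------------------------------
# Benjamini-Hochberg FDR


def bh_fdr(pvals) -> np.ndarray:
    """Step-up Benjamini-Hochberg adjusted p-values.

    adjusted_(i) = min_{j >= i} ( m * p_(j) / j ), capped at 1;
    order-preserving and idempotent.
    """
    p = np.asarray(pvals, dtype=float)
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


# ---------------------------------------------------------------------------
# Partial correlations


@dataclass
class PartialCorrResult:
    method: str
    coefficient: float
    p: float
    n: int
    covariate: str = "pds"
    p_adjusted: float = np.nan


def _residualize(v: np.ndarray, c: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones_like(c), c])
    coef, *_ = np.linalg.lstsq(X, v, rcond=None)
    return v - X @ coef


def partial_corr(x, y, covariate, method: str = "pearson",
                 covariate_name: str = "pds") -> PartialCorrResult:
    """Partial correlation of x and y controlling for one covariate.

    Residualize x and y on [1, covariate] and correlate the residuals
    (ranks are taken first for the Spearman variant); the p-value uses
    the t transform with n - 3 degrees of freedom.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    c = np.asarray(covariate, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y) & np.isfinite(c)
    x, y, c = x[ok], y[ok], c[ok]
    n = x.size
    if n < 5:
        raise ValueError("need at least 5 complete observations")
    if method == "spearman":
        x, y, c = (stats.rankdata(v) for v in (x, y, c))
    rx = _residualize(x, c)
    ry = _residualize(y, c)
    tol = 1e-10
    if rx.std() <= tol * max(1.0, x.std()) or \
            ry.std() <= tol * max(1.0, y.std()):
        raise ValueError("constant input after residualization")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 3
    t = r * np.sqrt(df / max(1 - r ** 2, 1e-300))
    p = float(2 * stats.t.sf(abs(t), df))
    return PartialCorrResult(method, r, p, n, covariate_name)


def adjust_family(results: list[PartialCorrResult]) -> list[PartialCorrResult]:
    """BH-adjust a family of partial-correlation tests run together.

    Family membership is an explicit input: pass exactly the tests that
    form one exploratory family.
    """
    adj = bh_fdr([r.p for r in results])
    for r, a in zip(results, adj):
        r.p_adjusted = float(a)
    return results


# ---------------------------------------------------------------------------
# Linear mixed models


@dataclass
class LmmSpec:
    dependent: str                   # measure name in the long table
    rs_column: str                   # rs_cross or rs_neutral
    interaction: bool = True
    covariate: str = "pds"
    random_slope: bool = True


LMM_PRESETS: dict[str, LmmSpec] = {
    "adjusted_bmi": LmmSpec("adjusted_bmi", "rs_cross", interaction=True),
    "ede": LmmSpec("ede", "rs_cross", interaction=True),
    "bas": LmmSpec("bas", "rs_neutral", interaction=False),
}


@dataclass
class LmmResult:
    model: str
    fixed_effects: pd.DataFrame      # term, estimate, se, p
    cov_re: np.ndarray
    converged: bool
    random_structure: str = "intercept+slope"

    def term(self, name: str) -> pd.Series:
        row = self.fixed_effects[self.fixed_effects["term"] == name]
        if row.empty:
            raise KeyError(name)
        return row.iloc[0]


def fit_lmm(table: pd.DataFrame, spec: LmmSpec | str) -> LmmResult:
    """REML fit of one longitudinal preset on a long clinical table.

    ``table`` columns: subject_id, measure, timepoint, value, plus the
    per-subject RS column and the covariate. Fixed effects are time, RS,
    their interaction (when the preset includes one) and the covariate;
    random effects are subject intercept and time slope (unstructured
    2 x 2 covariance), reduced to intercept-only when fewer than three
    distinct timepoints make a slope unidentifiable.
    """
    import statsmodels.formula.api as smf
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    if isinstance(spec, str):
        spec = LMM_PRESETS[spec]
    df = table[table["measure"] == spec.dependent].copy()
    if df.empty:
        raise ValueError(f"no rows for measure {spec.dependent!r}")
    df["time"] = df["timepoint"].map(TIMEPOINT_CODES)
    if df["time"].isna().any():
        bad = sorted(df.loc[df["time"].isna(), "timepoint"].unique())
        raise ValueError(f"unknown timepoints {bad}")
    df = df.rename(columns={spec.rs_column: "rs", spec.covariate: "cov"})
    df = df.dropna(subset=["value", "time", "rs", "cov"])
    counts = df.groupby("subject_id")["time"].nunique()
    if (counts < 2).any():
        raise ValueError("every subject needs >= 2 timepoints")

    n_tp = df["time"].nunique()
    random_slope = spec.random_slope and n_tp >= 3
    structure = "intercept+slope" if random_slope else "intercept"
    if spec.random_slope and not random_slope:
        logger.warning("preset %s: only %d timepoints; reducing random "
                       "effects to intercept-only", spec.dependent, n_tp)

    fixed = "value ~ time * rs + cov" if spec.interaction \
        else "value ~ time + rs + cov"
    re_formula = "~time" if random_slope else "~1"

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = smf.mixedlm(fixed, df, groups=df["subject_id"],
                            re_formula=re_formula)
        fit = model.fit(reml=True)
        converged = bool(getattr(fit, "converged", True)) and not any(
            issubclass(w.category, ConvergenceWarning) for w in caught)

    terms = []
    rename = {"Intercept": "intercept", "time:rs": "time:rs"}
    for name in fit.fe_params.index:
        terms.append((rename.get(name, name), float(fit.fe_params[name]),
                      float(fit.bse_fe[name]), float(fit.pvalues[name])))
    fe = pd.DataFrame(terms, columns=["term", "estimate", "se", "p"])
    cov_re = np.asarray(fit.cov_re)
    return LmmResult(spec.dependent, fe, cov_re, converged, structure)
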