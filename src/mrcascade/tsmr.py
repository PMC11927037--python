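"""Two-sample Mendelian randomization estimators and sensitivity logic.

Exposed both as a statsmodels-flavoured model object — ``TwoSampleMR(pairs)``
with ``fit(method=...)`` returning an :class:`MREstimate` — and as the plain
functions used by the pipeline.  Estimators:

* ``wald_ratio`` — single-instrument ratio (first-order SE).
* ``ivw`` — inverse-variance-weighted regression through the origin, fixed
  or multiplicative-random-effects (MRE) standard errors.  IVW-MRE is the
  primary estimate throughout the pipeline.
* ``egger`` / ``egger_bootstrap`` — MR-Egger regression with intercept (the
  intercept is the directional-pleiotropy test); the bootstrap variant
  resamples instruments.
* ``weighted_median`` — consistent when instruments carrying ≥ 50% of the
  weight are valid; SE by parametric bootstrap.
* ``cochran_q`` — heterogeneity of the per-instrument ratios about IVW-fixed.

``sensitivity_suite`` reproduces the recommendation rule: MR-Egger
(bootstrap) when the Egger intercept indicates pleiotropy, otherwise
IVW with multiplicative random effects (which is also the primary method
under heterogeneity and in the clean case).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import HarmonizedPairs

__all__ = [
    "MREstimate",
    "SensitivityReport",
    "TwoSampleMR",
    "InsufficientInstrumentsError",
    "wald_ratio",
    "ivw",
    "egger",
    "egger_bootstrap",
    "weighted_median",
    "cochran_q",
    "sensitivity_suite",
]


class InsufficientInstrumentsError(ValueError):
    """Too few instruments for the requested estimator."""


@dataclass
class MREstimate:
    """One MR estimate: method, causal effect, SE, p, instrument count."""

    method: str
    beta: float
    se: float
    pvalue: float
    n_snps: int
    extras: dict = field(default_factory=dict)

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        z = stats.norm.ppf(0.5 + level / 2)
        return self.beta - z * self.se, self.beta + z * self.se

    def summary(self) -> pd.Series:
        s = pd.Series(
            {
                "method": self.method,
                "beta": self.beta,
                "se": self.se,
                "pvalue": self.pvalue,
                "n_snps": self.n_snps,
                **self.extras,
            }
        )
        return s


def _ratios(pairs: HarmonizedPairs) -> tuple[np.ndarray, np.ndarray]:
    bx, by = pairs.beta_exp, pairs.beta_out
    if np.any(bx == 0):
        raise ZeroDivisionError("zero exposure beta; Wald ratio undefined")
    ratio = by / bx
    se_ratio = pairs.se_out / np.abs(bx)
    return ratio, se_ratio


def wald_ratio(pairs: HarmonizedPairs) -> MREstimate:
    """Single-instrument Wald ratio: β_out/β_exp, first-order SE."""
    if len(pairs) != 1:
        raise InsufficientInstrumentsError("wald_ratio requires exactly 1 instrument")
    ratio, se_ratio = _ratios(pairs)
    beta, se = float(ratio[0]), float(se_ratio[0])
    p = float(2 * stats.norm.sf(abs(beta / se)))
    return MREstimate("wald_ratio", beta, se, p, 1)


def ivw(pairs: HarmonizedPairs, model: str = "mre") -> MREstimate:
    """IVW regression of β_out on β_exp through the origin, weights 1/se_out².

    ``model="fixed"`` takes the SE from the weight sum; ``model="mre"``
    (multiplicative random effects) scales it by the residual standard
    deviation of the weighted regression, without flooring the scale at 1.
    """
    if model not in {"fixed", "mre"}:
        raise ValueError(f"unknown IVW model {model!r}")
    k = len(pairs)
    if k < 2:
        raise InsufficientInstrumentsError("ivw requires >= 2 instruments")
    bx, by = pairs.beta_exp, pairs.beta_out
    w = 1.0 / pairs.se_out**2
    sxx = np.sum(w * bx * bx)
    beta = np.sum(w * bx * by) / sxx
    se_fixed = np.sqrt(1.0 / sxx)
    if model == "fixed":
        se = se_fixed
    else:
        resid = by - beta * bx
        sigma2 = np.sum(w * resid**2) / (k - 1)
        se = se_fixed * np.sqrt(sigma2)
    p = float(2 * stats.norm.sf(abs(beta / se)))
    return MREstimate(f"ivw_{model}", float(beta), float(se), p, k)


def _orient(pairs: HarmonizedPairs) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flip instrument rows so every exposure beta is non-negative."""
    bx, by = pairs.beta_exp.copy(), pairs.beta_out.copy()
    flip = bx < 0
    bx[flip] *= -1
    by[flip] *= -1
    return bx, by, pairs.se_out.copy()


def egger(pairs: HarmonizedPairs) -> MREstimate:
    """MR-Egger: weighted regression of β_out on β_exp with intercept.

    Rows are first oriented so all exposure betas are non-negative.  The
    intercept and its p-value (t with k−2 df) form the directional-pleiotropy
    test, reported in ``extras``.
    """
    k = len(pairs)
    if k < 3:
        raise InsufficientInstrumentsError("egger requires >= 3 instruments")
    bx, by, se_out = _orient(pairs)
    w = 1.0 / se_out**2
    X = np.column_stack([np.ones(k), bx])
    XtW = X.T * w
    xtx = XtW @ X
    coef = np.linalg.solve(xtx, XtW @ by)
    resid = by - X @ coef
    sigma2 = float(np.sum(w * resid**2) / (k - 2))
    # multiplicative random effects, not floored below 1
    cov = np.linalg.inv(xtx) * sigma2
    se_int, se_slope = np.sqrt(np.diag(cov))
    t = stats.t(df=k - 2)
    p_slope = float(2 * t.sf(abs(coef[1] / se_slope)))
    p_int = float(2 * t.sf(abs(coef[0] / se_int)))
    return MREstimate(
        "egger",
        float(coef[1]),
        float(se_slope),
        p_slope,
        k,
        extras={"intercept": float(coef[0]), "se_intercept": float(se_int), "p_intercept": p_int},
    )


def egger_bootstrap(
    pairs: HarmonizedPairs, n_boot: int = 1000, seed: int = 0
) -> MREstimate:
    """MR-Egger with instrument-resampling bootstrap.

    Resamples instrument rows with replacement ``n_boot`` times and reports
    the median slope with the empirical SD as SE.  Deterministic for a fixed
    seed.  Degenerate resamples (all rows identical exposure beta) are
    refitted on the original data.
    """
    k = len(pairs)
    if k < 3:
        raise InsufficientInstrumentsError("egger requires >= 3 instruments")
    base = egger(pairs)
    rng = np.random.default_rng(seed)
    bx, by, se_out = _orient(pairs)
    w = 1.0 / se_out**2
    slopes = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, k, size=k)
        xb, yb, wb = bx[idx], by[idx], w[idx]
        X = np.column_stack([np.ones(k), xb])
        XtW = X.T * wb
        xtx = XtW @ X
        if np.linalg.matrix_rank(xtx) < 2 or np.ptp(xb) < 1e-12:
            slopes[b] = base.beta
            continue
        coef = np.linalg.solve(xtx, XtW @ yb)
        slopes[b] = coef[1]
    beta = float(np.median(slopes))
    se = float(np.std(slopes, ddof=1)) if n_boot > 1 else base.se
    p = float(2 * stats.norm.sf(abs(beta / se))) if se > 0 else 1.0
    return MREstimate(
        "egger_bootstrap",
        beta,
        se,
        p,
        k,
        extras={**base.extras, "n_boot": n_boot, "seed": seed},
    )


def _weighted_median_point(ratio: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(ratio, kind="stable")
    r, wt = ratio[order], w[order]
    csum = np.cumsum(wt) - 0.5 * wt
    csum = csum / np.sum(wt)
    if csum[0] >= 0.5:
        return float(r[0])
    if csum[-1] <= 0.5:
        return float(r[-1])
    j = int(np.searchsorted(csum, 0.5))
    # linear interpolation between the bracketing ratios
    lo, hi = csum[j - 1], csum[j]
    frac = (0.5 - lo) / (hi - lo)
    return float(r[j - 1] + frac * (r[j] - r[j - 1]))


def weighted_median(
    pairs: HarmonizedPairs, n_boot: int = 1000, seed: int = 0
) -> MREstimate:
    """Weighted-median MR estimate with parametric-bootstrap SE.

    Wald ratios are ordered; the estimate interpolates the inverse-variance
    cumulative weight function at 0.5.  The SE is the SD of the estimate over
    ``n_boot`` parametric resamples of (β_exp, β_out) from their reported
    sampling distributions (seeded).
    """
    k = len(pairs)
    if k < 3:
        raise InsufficientInstrumentsError("weighted_median requires >= 3 instruments")
    ratio, se_ratio = _ratios(pairs)
    w = 1.0 / se_ratio**2
    beta = _weighted_median_point(ratio, w)

    rng = np.random.default_rng(seed)
    bx, by = pairs.beta_exp, pairs.beta_out
    sx, sy = pairs.se_exp, pairs.se_out
    est = np.empty(n_boot)
    for b in range(n_boot):
        bxs = rng.normal(bx, sx)
        bys = rng.normal(by, sy)
        bxs[bxs == 0] = 1e-300
        r = bys / bxs
        wr = (np.abs(bxs) / sy) ** 2
        est[b] = _weighted_median_point(r, wr)
    se = float(np.std(est, ddof=1)) if n_boot > 1 else float("nan")
    p = float(2 * stats.norm.sf(abs(beta / se))) if se > 0 else 1.0
    return MREstimate(
        "weighted_median", beta, se, p, k, extras={"n_boot": n_boot, "seed": seed}
    )


def cochran_q(pairs: HarmonizedPairs) -> tuple[float, float]:
    """Cochran's Q heterogeneity of the per-instrument ratios about IVW-fixed.

    Q = Σ wᵢ (ratioᵢ − β_IVW)², wᵢ = 1/se_ratioᵢ²; p from χ²(k−1).
    """
    k = len(pairs)
    if k < 2:
        raise InsufficientInstrumentsError("cochran_q requires >= 2 instruments")
    ratio, se_ratio = _ratios(pairs)
    w = 1.0 / se_ratio**2
    beta = np.sum(w * ratio) / np.sum(w)
    q = float(np.sum(w * (ratio - beta) ** 2))
    p = float(stats.chi2.sf(q, df=k - 1))
    return q, p


@dataclass
class SensitivityReport:
    """Full estimator panel plus heterogeneity/pleiotropy diagnostics."""

    estimates: dict[str, MREstimate]
    q: float
    p_q: float
    egger_intercept: float
    p_intercept: float
    recommended_method: str

    @property
    def recommended(self) -> MREstimate:
        return self.estimates[self.recommended_method]

    def summary(self) -> pd.DataFrame:
        rows = [e.summary() for e in self.estimates.values()]
        df = pd.DataFrame(rows).set_index("method")
        df.attrs["Q"] = self.q
        df.attrs["p_Q"] = self.p_q
        df.attrs["egger_intercept"] = self.egger_intercept
        df.attrs["p_intercept"] = self.p_intercept
        df.attrs["recommended"] = self.recommended_method
        return df


def sensitivity_suite(
    pairs: HarmonizedPairs,
    alpha: float = 0.05,
    n_boot: int = 1000,
    seed: int = 0,
) -> SensitivityReport:
    """Run the five-estimator panel and pick the recommended method.

    Recommendation rule: MR-Egger (bootstrap) when the Egger intercept is
    significant at ``alpha`` (directional pleiotropy); otherwise IVW with
    multiplicative random effects — which covers both the significant-
    heterogeneity case and the clean case, where it is the primary method.
    Pleiotropy takes precedence over heterogeneity when both are flagged.
    """
    if len(pairs) < 3:
        raise InsufficientInstrumentsError("sensitivity suite requires >= 3 instruments")
    est = {
        "ivw_fixed": ivw(pairs, "fixed"),
        "ivw_mre": ivw(pairs, "mre"),
        "egger": egger(pairs),
        "egger_bootstrap": egger_bootstrap(pairs, n_boot=n_boot, seed=seed),
        "weighted_median": weighted_median(pairs, n_boot=n_boot, seed=seed + 1),
    }
    q, p_q = cochran_q(pairs)
    p_int = est["egger"].extras["p_intercept"]
    recommended = "egger_bootstrap" if p_int < alpha else "ivw_mre"
    return SensitivityReport(
        estimates=est,
        q=q,
        p_q=p_q,
        egger_intercept=est["egger"].extras["intercept"],
        p_intercept=p_int,
        recommended_method=recommended,
    )


class TwoSampleMR:
    """Two-sample MR model over a harmonized instrument table.

    Parameters
    ----------
    pairs : HarmonizedPairs
        Allele-aligned exposure/outcome instrument table.

    ``fit(method=...)`` dispatches to the named estimator and returns an
    :class:`MREstimate`; with a single instrument every method falls back to
    the Wald ratio.  ``fit_all()`` returns the full
    :class:`SensitivityReport`.
    """

    METHODS = ("ivw_fixed", "ivw_mre", "egger", "egger_bootstrap", "weighted_median")

    def __init__(self, pairs: HarmonizedPairs):
        self.pairs = pairs

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "TwoSampleMR":
        """Build from a DataFrame with columns snp, beta_exp, se_exp, beta_out, se_out."""
        tab = df.copy()
        if "eaf" not in tab.columns:
            tab["eaf"] = np.nan
        if "action" not in tab.columns:
            tab["action"] = "kept"
        return cls(HarmonizedPairs(tab))

    def fit(self, method: str = "ivw_mre", **kwargs) -> MREstimate:
        if len(self.pairs) == 1:
            return wald_ratio(self.pairs)
        if method == "ivw_fixed":
            return ivw(self.pairs, "fixed")
        if method == "ivw_mre":
            return ivw(self.pairs, "mre")
        if method == "egger":
            return egger(self.pairs)
        if method == "egger_bootstrap":
            return egger_bootstrap(self.pairs, **kwargs)
        if method == "weighted_median":
            return weighted_median(self.pairs, **kwargs)
        raise ValueError(f"unknown method {method!r}")

    def fit_all(self, alpha: float = 0.05, n_boot: int = 1000, seed: int = 0) -> SensitivityReport:
        return sensitivity_suite(self.pairs, alpha=alpha, n_boot=n_boot, seed=seed)

    def heterogeneity(self) -> tuple[float, float]:
        return cochran_q(self.pairs)
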