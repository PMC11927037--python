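"""Multivariable IVW Mendelian randomization.

Estimates each exposure's direct effect on the outcome conditional on the
other exposures by weighted multiple regression of the outcome betas on the
matrix of exposure betas through the origin (weights 1/se_out²).  The
pipeline uses the pairwise form — one gene plus the mediator — so the gene's
coefficient is its direct (non-mediated) effect on the outcome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["MVMRResult", "MVMR", "mvmr_ivw", "CollinearityError"]


class CollinearityError(np.linalg.LinAlgError):
    """The exposure-beta matrix is rank deficient."""


@dataclass
class MVMRResult:
    """Per-exposure direct effects from a multivariable IVW fit."""

    exposures: list[str]
    betas: np.ndarray
    ses: np.ndarray
    pvalues: np.ndarray
    n_snps: int

    def __getitem__(self, exposure: str) -> tuple[float, float, float]:
        i = self.exposures.index(exposure)
        return float(self.betas[i]), float(self.ses[i]), float(self.pvalues[i])

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "exposure": self.exposures,
                "beta": self.betas,
                "se": self.ses,
                "pvalue": self.pvalues,
                "n_snps": self.n_snps,
            }
        ).set_index("exposure")


def mvmr_ivw(
    beta_exposures: np.ndarray | pd.DataFrame,
    beta_out: np.ndarray,
    se_out: np.ndarray,
    exposure_names: list[str] | None = None,
) -> MVMRResult:
    """Multivariable IVW: weighted no-intercept regression of β_out on exposures.

    Parameters
    ----------
    beta_exposures : (n_snps, k) array or DataFrame
        Per-SNP effects on each exposure (columns), harmonized to a common
        allele frame with the outcome.
    beta_out, se_out : (n_snps,) arrays
        Outcome effects and standard errors (weights are 1/se_out²).

    Requires at least k+1 SNPs for k exposures.  Normal-approximation
    p-values.  Raises :class:`CollinearityError` naming the offending
    columns when the weighted exposure matrix is rank deficient.
    """
    if isinstance(beta_exposures, pd.DataFrame):
        exposure_names = exposure_names or list(beta_exposures.columns)
        X = beta_exposures.to_numpy(dtype=float)
    else:
        X = np.asarray(beta_exposures, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        exposure_names = exposure_names or [f"x{i}" for i in range(X.shape[1])]
    y = np.asarray(beta_out, dtype=float)
    s = np.asarray(se_out, dtype=float)
    n, k = X.shape
    if n < k + 1:
        raise ValueError(f"MVMR requires at least {k + 1} SNPs for {k} exposures, got {n}")
    if np.any(s <= 0):
        raise ValueError("outcome standard errors must be positive")

    w = 1.0 / s**2
    XtW = X.T * w
    xtx = XtW @ X
    rank = np.linalg.matrix_rank(xtx, tol=1e-10 * max(1.0, float(np.abs(xtx).max())))
    if rank < k:
        # name columns whose removal restores full rank
        offending = []
        for j in range(k):
            sub = np.delete(np.delete(xtx, j, axis=0), j, axis=1)
            if np.linalg.matrix_rank(sub) == k - 1:
                offending.append(exposure_names[j])
        raise CollinearityError(
            f"exposure matrix is rank deficient (rank {rank} < {k}); "
            f"offending columns: {offending or exposure_names}"
        )
    coef = np.linalg.solve(xtx, XtW @ y)
    cov = np.linalg.inv(xtx)
    ses = np.sqrt(np.diag(cov))
    z = coef / ses
    p = 2 * stats.norm.sf(np.abs(z))
    return MVMRResult(list(exposure_names), coef, ses, p, n)


class MVMR:
    """Multivariable MR model: exposure-beta matrix plus outcome betas.

    ``MVMR.from_dataframe(df, exposures=[...])`` expects one row per SNP with
    the named exposure-beta columns plus ``beta_out`` and ``se_out``;
    ``fit()`` returns an :class:`MVMRResult`.
    """

    def __init__(
        self,
        beta_exposures: pd.DataFrame | np.ndarray,
        beta_out: np.ndarray,
        se_out: np.ndarray,
        exposure_names: list[str] | None = None,
    ):
        self.beta_exposures = beta_exposures
        self.beta_out = np.asarray(beta_out, dtype=float)
        self.se_out = np.asarray(se_out, dtype=float)
        self.exposure_names = exposure_names

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, exposures: list[str]) -> "MVMR":
        return cls(df[exposures], df["beta_out"].to_numpy(), df["se_out"].to_numpy(), exposures)

    def fit(self) -> MVMRResult:
        return mvmr_ivw(
            self.beta_exposures, self.beta_out, self.se_out, self.exposure_names
        )
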