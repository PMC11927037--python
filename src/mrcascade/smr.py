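"""Summary-based MR (Wald-ratio χ² test) and the HEIDI linkage test.

The SMR statistic combines a variant's eQTL and GWAS z-scores into a test of
the expression→trait effect b_xy = β_GWAS/β_eQTL:

    T_SMR = z²_eQTL · z²_GWAS / (z²_eQTL + z²_GWAS)  ~  χ²(1)

A small SMR p-value is compatible with causality/pleiotropy at a single
shared variant, but also with two distinct causal variants in LD (linkage).
HEIDI distinguishes the two by testing whether b_xy is constant across
variants in LD with the top eQTL: under a single shared causal variant every
d_i = b_xy(snp_i) − b_xy(top) is zero in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import LDMatrix, SumStats

__all__ = ["SMRResult", "smr_test", "heidi_test", "smr_screen", "HeidiSelection"]


class UndefinedRatioError(ZeroDivisionError):
    """The eQTL effect is zero; the Wald ratio is undefined."""


@dataclass
class SMRResult:
    """Per-gene SMR outcome: Wald-ratio effect, SMR p, HEIDI p."""

    gene_id: str
    top_snp: str
    b_xy: float
    se_xy: float
    p_smr: float
    p_heidi: float | None
    n_heidi_snps: int
    gene_symbol: str = ""


def smr_test(
    beta_eqtl: float, se_eqtl: float, beta_gwas: float, se_gwas: float
) -> tuple[float, float, float]:
    """SMR Wald-ratio test at a single variant.

    Returns ``(b_xy, se_xy, p_smr)`` with b_xy = β_GWAS/β_eQTL and
    p_smr the upper χ²(1) tail of T_SMR.  When β_GWAS = 0, T_SMR = 0 and
    p_smr = 1.  se_xy is defined through the statistic, |b_xy|/√T_SMR,
    degrading gracefully to the first-order delta SE for strong eQTLs.
    """
    if se_eqtl <= 0 or se_gwas <= 0:
        raise ValueError("standard errors must be positive")
    if beta_eqtl == 0:
        raise UndefinedRatioError("beta_eqtl is zero; Wald ratio undefined")
    z_e = beta_eqtl / se_eqtl
    z_g = beta_gwas / se_gwas
    b_xy = beta_gwas / beta_eqtl
    t_smr = (z_e**2 * z_g**2) / (z_e**2 + z_g**2)
    p_smr = float(stats.chi2.sf(t_smr, df=1))
    if t_smr > 0:
        se_xy = abs(b_xy) / np.sqrt(t_smr)
    else:  # beta_gwas == 0: fall back to the delta-method SE
        se_xy = se_gwas / abs(beta_eqtl)
    return float(b_xy), float(se_xy), p_smr


@dataclass
class HeidiSelection:
    """HEIDI variant-selection thresholds (defaults of the originating tool)."""

    p_eqtl_max: float = 1.57e-3  # z² > 10 on the eQTL association
    r2_min: float = 0.05
    r2_max: float = 0.9
    max_snps: int = 20
    min_snps: int = 3


def _bxy_cov(
    b_e: np.ndarray, se_e: np.ndarray, b_g: np.ndarray, se_g: np.ndarray, r: np.ndarray
) -> np.ndarray:
    """First-order covariance of the per-variant Wald ratios b_xy = b_g/b_e.

    The eQTL and GWAS estimates come from independent samples; within each
    study the sampling correlation between variants equals the LD r.
    """
    cov_g = r * np.outer(se_g, se_g)
    cov_e = r * np.outer(se_e, se_e)
    inv_e = 1.0 / b_e
    cov = np.outer(inv_e, inv_e) * cov_g + np.outer(
        b_g * inv_e**2, b_g * inv_e**2
    ) * cov_e
    return cov


def heidi_test(
    eqtl: SumStats,
    gwas: SumStats,
    ld: LDMatrix,
    selection: HeidiSelection | None = None,
    n_draws: int = 20_000,
    seed: int = 0,
    method: str = "monte_carlo",
) -> tuple[float | None, int]:
    """HEIDI heterogeneity test at one locus.

    Selects variants in LD with the top eQTL variant (``selection``
    thresholds), forms d_i = b_xy(snp_i) − b_xy(top), and tests
    T_HEIDI = Σ (d_i/sd(d_i))² against its null distribution — a weighted sum
    of χ²(1) variables with weights from the eigenvalues of the correlation
    matrix of the d_i.  The null tail is evaluated by seeded Monte Carlo
    (default) or a Satterthwaite two-moment χ² approximation
    (``method="satterthwaite"``).

    Returns ``(p_heidi, n_heidi_snps)``; p is ``None`` when fewer than
    ``selection.min_snps`` non-top variants qualify.
    """
    sel = selection or HeidiSelection()
    etab = eqtl.table.set_index("snp")
    gtab = gwas.table.set_index("snp")
    shared = [s for s in etab.index if s in gtab.index and s in ld._index]
    if not shared:
        return None, 0
    etab = etab.loc[shared]

    # top variant: smallest eQTL p, ties broken by snp id
    order = sorted(shared, key=lambda s: (etab.loc[s, "p"], s))
    top = order[0]

    chosen = []
    for s in order[1:]:
        if etab.loc[s, "p"] >= sel.p_eqtl_max:
            continue
        r2 = ld.r2(top, s)
        if not (sel.r2_min <= r2 <= sel.r2_max):
            continue
        chosen.append(s)
        if len(chosen) >= sel.max_snps:
            break
    if len(chosen) < sel.min_snps:
        return None, len(chosen)

    snps = [top] + chosen
    b_e = etab.loc[snps, "beta"].to_numpy(dtype=float)
    se_e = etab.loc[snps, "se"].to_numpy(dtype=float)
    b_g = gtab.loc[snps, "beta"].to_numpy(dtype=float)
    se_g = gtab.loc[snps, "se"].to_numpy(dtype=float)
    r = ld.submatrix(snps)

    cov = _bxy_cov(b_e, se_e, b_g, se_g, r)
    b_xy = b_g / b_e
    d = b_xy[1:] - b_xy[0]
    # var(d_i) = var(b_xy_i) + var(top) − 2 cov
    k = len(d)
    var_d = np.empty(k)
    cov_d = np.empty((k, k))
    for i in range(k):
        var_d[i] = cov[i + 1, i + 1] + cov[0, 0] - 2 * cov[0, i + 1]
        for j in range(k):
            cov_d[i, j] = cov[i + 1, j + 1] + cov[0, 0] - cov[0, i + 1] - cov[0, j + 1]
    sd = np.sqrt(var_d)
    t_heidi = float(np.sum((d / sd) ** 2))

    corr = cov_d / np.outer(sd, sd)
    eigvals = np.linalg.eigvalsh((corr + corr.T) / 2)
    eigvals = np.clip(eigvals, 0.0, None)

    if method == "satterthwaite":
        s1, s2 = eigvals.sum(), (eigvals**2).sum()
        if s2 == 0:
            return 1.0, k
        scale = s2 / s1
        df = s1**2 / s2
        p = float(stats.chi2.sf(t_heidi / scale, df))
    elif method == "monte_carlo":
        rng = np.random.default_rng(seed)
        z = rng.standard_normal((n_draws, k))
        draws = (z**2) @ eigvals
        p = float((np.count_nonzero(draws >= t_heidi) + 1) / (n_draws + 1))
    else:
        raise ValueError(f"unknown HEIDI method {method!r}")
    return p, k


def smr_screen(
    results: list[SMRResult],
    p_smr_thresh: float = 0.05,
    p_heidi_thresh: float = 0.05,
    require_symbol: bool = True,
) -> pd.DataFrame:
    """Apply the three-stage SMR screen to a batch of gene-level results.

    A gene passes when p_smr < ``p_smr_thresh``, p_heidi > ``p_heidi_thresh``
    (a missing HEIDI p fails), and — when ``require_symbol`` — the gene has a
    non-empty symbol.  Returns a table with per-gene verdicts and the stage
    (``smr`` / ``heidi`` / ``symbol``) at which each failing gene dropped;
    attrs carry the per-stage drop counts.
    """
    rows = []
    drops = {"smr": 0, "heidi": 0, "symbol": 0}
    for res in results:
        stage = ""
        if not (res.p_smr < p_smr_thresh):
            stage = "smr"
        elif res.p_heidi is None or not (res.p_heidi > p_heidi_thresh):
            stage = "heidi"
        elif require_symbol and not res.gene_symbol:
            stage = "symbol"
        if stage:
            drops[stage] += 1
        rows.append(
            {
                "gene_id": res.gene_id,
                "gene_symbol": res.gene_symbol,
                "top_snp": res.top_snp,
                "b_xy": res.b_xy,
                "se_xy": res.se_xy,
                "p_smr": res.p_smr,
                "p_heidi": np.nan if res.p_heidi is None else res.p_heidi,
                "n_heidi_snps": res.n_heidi_snps,
                "passed": stage == "",
                "failed_stage": stage,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["drop_counts"] = drops
    return out
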