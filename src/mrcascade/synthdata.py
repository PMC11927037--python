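"""Synthetic GWAS/eQTL summary statistics under a known causal graph.

Generates per-variant association estimates directly on the summary-statistic
scale (no individual-level genotypes): for each gene g, instrument i,

    β̂_eQTL,i   = β_i            + ε,   se = 1/√(2·maf·(1−maf)·n_eqtl)
    β̂_med,i    = a_g·β_i + π_i  + ε,   se = √(4/(n_eff·2·maf·(1−maf)))
    β̂_out,i    = b·β_med,true,i + δ_g·β_i + ε (× heterogeneity)

with π_i an optional pleiotropy term, n_eff the case-control effective
sample size 4/(1/n_cases + 1/n_controls), and all sampling noise drawn from
the multivariate normal implied by the local LD (AR(1) blocks).  The
mediator additionally has its own genome-wide instruments, from which the
mediator→outcome effect b is estimable.  Marginal effects under LD follow
β_marginal = R·β_causal.

Default sample sizes emulate a blood cis-eQTL panel (n≈31.7k), a large
biobank case-control mediator GWAS (10 154/454 764), and a 216 528-subject
outcome GWAS of a rare outcome.  A :class:`TruthTable` records each gene's
true paths and expected cascade category.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import LDMatrix, SumStats, STANDARD_COLUMNS

__all__ = ["SimConfig", "StudyBundle", "simulate_study", "simulate_heidi_locus", "standard_scenario"]

_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T")]  # never palindromic


def effective_n(n_cases: float, n_controls: float) -> float:
    """Case-control effective sample size 4/(1/n_cases + 1/n_controls)."""
    return 4.0 / (1.0 / n_cases + 1.0 / n_controls)


@dataclass
class SimConfig:
    """Generator configuration; the defaults define the study conditions.

    Per-gene causal parameters ``a`` (gene→mediator), ``delta``
    (gene→outcome direct) and ``linkage`` (second, mediator-only causal
    variant at the locus) are scalars broadcast to ``n_genes`` or per-gene
    sequences.  ``b`` is the single mediator→outcome effect.

    Each gene locus consists of ``n_instruments`` mutually unlinked blocks of
    ``block_size`` variants with AR(1) LD (``ar1_rho``) inside a block, so
    standard clumping retains one variant per block.  The first block carries
    a dominant lead eQTL of magnitude ``lead_beta``; the remaining blocks
    draw |β| from ``eqtl_beta_range``.
    """

    n_genes: int = 10
    a: float | Sequence[float] = 0.25
    delta: float | Sequence[float] = 0.0
    b: float = 1.8
    n_instruments: int = 30
    block_size: int = 5
    ar1_rho: float = 0.8
    lead_beta: float = 0.5
    eqtl_beta_range: tuple[float, float] = (0.08, 0.20)
    maf_range: tuple[float, float] = (0.1, 0.5)
    n_mediator_instruments: int = 30
    med_beta_range: tuple[float, float] = (0.12, 0.30)
    pleiotropy_mode: str = "off"  # off | balanced | directional
    pleiotropy_scale: float = 0.0
    heterogeneity: float = 1.0  # multiplier on outcome-beta sampling noise
    linkage: bool | Sequence[bool] = False
    linkage_r: float = 0.7
    n_eqtl: int = 31_684
    n_mediator_cases: int = 10_154
    n_mediator_controls: int = 454_764
    n_outcome_cases: int = 25
    n_outcome_controls: int = 216_503
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.n_genes < 1:
            problems.append("n_genes must be >= 1")
        if not (0 < self.maf_range[0] <= self.maf_range[1] <= 0.5):
            problems.append("maf_range must lie in (0, 0.5]")
        for name in ("n_eqtl", "n_mediator_cases", "n_mediator_controls",
                     "n_outcome_cases", "n_outcome_controls"):
            if getattr(self, name) <= 0:
                problems.append(f"{name} must be > 0")
        if self.pleiotropy_mode not in {"off", "balanced", "directional"}:
            problems.append("pleiotropy_mode must be off/balanced/directional")
        if not (0 <= abs(self.ar1_rho) < 1):
            problems.append("ar1_rho must satisfy |rho| < 1")
        if self.block_size < 1 or self.n_instruments < 1:
            problems.append("block_size and n_instruments must be >= 1")
        if self.heterogeneity <= 0:
            problems.append("heterogeneity must be > 0")
        if self.seed is None:
            problems.append("seed is mandatory")
        if problems:
            raise ValueError("invalid SimConfig: " + "; ".join(problems))

    def per_gene(self, value) -> np.ndarray:
        arr = np.asarray(value)
        if arr.ndim == 0:
            return np.full(self.n_genes, arr.item())
        if len(arr) != self.n_genes:
            raise ValueError("per-gene parameter length != n_genes")
        return arr


@dataclass
class StudyBundle:
    """Everything one cascade run consumes, plus the generating truth."""

    gene_sumstats: dict[str, SumStats]
    mediator: SumStats
    outcome: SumStats
    ld: dict[str, LDMatrix]
    mediator_ld: LDMatrix
    truth: pd.DataFrame  # gene_id, gene_symbol, a, delta, mediated, expected_category
    config: SimConfig | None = None

    def save(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        genes = []
        for gid, ss in self.gene_sumstats.items():
            ss.table[STANDARD_COLUMNS].to_csv(out / f"eqtl_{gid}.tsv", sep="\t", index=False, float_format="%.10g")
            self.ld[gid].write(out / f"ld_{gid}.tsv")
            genes.append({"gene_id": gid, "gene_symbol": ss.gene_symbol})
        pd.DataFrame(genes).to_csv(out / "genes.tsv", sep="\t", index=False)
        self.mediator.table.to_csv(out / "mediator.tsv", sep="\t", index=False, float_format="%.10g")
        self.outcome.table.to_csv(out / "outcome.tsv", sep="\t", index=False, float_format="%.10g")
        self.mediator_ld.write(out / "mediator_ld.tsv")
        self.truth.to_csv(out / "truth.tsv", sep="\t", index=False, float_format="%.10g")

    @classmethod
    def load(cls, in_dir) -> "StudyBundle":
        from pathlib import Path

        src = Path(in_dir)
        genes = pd.read_csv(src / "genes.tsv", sep="\t").fillna("")
        gene_sumstats, ld = {}, {}
        for _, row in genes.iterrows():
            gid = row["gene_id"]
            tab = pd.read_csv(src / f"eqtl_{gid}.tsv", sep="\t", dtype={"snp": str, "chr": str})
            gene_sumstats[gid] = SumStats(gid, "eqtl_gene", tab, str(row["gene_symbol"]))
            ld[gid] = LDMatrix.read(src / f"ld_{gid}.tsv")
        med = pd.read_csv(src / "mediator.tsv", sep="\t", dtype={"snp": str, "chr": str})
        out = pd.read_csv(src / "outcome.tsv", sep="\t", dtype={"snp": str, "chr": str})
        return cls(
            gene_sumstats=gene_sumstats,
            mediator=SumStats("mediator", "mediator", med),
            outcome=SumStats("outcome", "outcome", out),
            ld=ld,
            mediator_ld=LDMatrix.read(src / "mediator_ld.tsv"),
            truth=pd.read_csv(src / "truth.tsv", sep="\t").fillna(""),
        )


def _block_ar1(n_blocks: int, block_size: int, rho: float) -> np.ndarray:
    k = np.arange(block_size)
    block = rho ** np.abs(k[:, None] - k[None, :])
    R = np.zeros((n_blocks * block_size, n_blocks * block_size))
    for b in range(n_blocks):
        s = b * block_size
        R[s : s + block_size, s : s + block_size] = block
    return R


def _assoc_frame(snps, chrom, pos, eaf, beta, se, n) -> pd.DataFrame:
    z = beta / se
    p = 2 * stats.norm.sf(np.abs(z))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    m = len(snps)
    ea = [_ALLELE_PAIRS[i % len(_ALLELE_PAIRS)][0] for i in range(m)]
    oa = [_ALLELE_PAIRS[i % len(_ALLELE_PAIRS)][1] for i in range(m)]
    return pd.DataFrame(
        {
            "snp": snps,
            "chr": chrom,
            "pos": pos,
            "ea": ea,
            "oa": oa,
            "eaf": eaf,
            "beta": beta,
            "se": se,
            "p": p,
            "n": n,
        }
    )


def simulate_study(config: SimConfig) -> StudyBundle:
    """Generate the full three-trait study defined by ``config``.

    Returns a :class:`StudyBundle` with per-gene eQTL summary statistics
    (each also carrying null associations at the mediator's instruments, as
    a real genome-wide eQTL scan would), mediator and outcome summary
    statistics over all variants, per-locus LD matrices, and the truth table.
    Deterministic for a fixed ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    a_g = config.per_gene(config.a).astype(float)
    delta_g = config.per_gene(config.delta).astype(float)
    linkage_g = config.per_gene(config.linkage).astype(bool)

    n_eff_med = effective_n(config.n_mediator_cases, config.n_mediator_controls)
    n_eff_out = effective_n(config.n_outcome_cases, config.n_outcome_controls)
    n_med_total = config.n_mediator_cases + config.n_mediator_controls
    n_out_total = config.n_outcome_cases + config.n_outcome_controls

    m = config.n_instruments * config.block_size
    R = _block_ar1(config.n_instruments, config.block_size, config.ar1_rho)
    L = np.linalg.cholesky(R + 1e-12 * np.eye(m))
    causal_idx = np.arange(config.n_instruments) * config.block_size + config.block_size // 2
    lead_idx = causal_idx[0]

    # mediator's own genome-wide instruments (mutually unlinked)
    n_mi = config.n_mediator_instruments
    mi_snps = [f"rs_med_{j:04d}" for j in range(n_mi)]
    mi_chrom = [str((j % 22) + 1) for j in range(n_mi)]
    mi_pos = [400_000_000 + 20_000_000 * (j // 22) for j in range(n_mi)]
    mi_maf = rng.uniform(*config.maf_range, size=n_mi)
    mi_beta_med_true = rng.choice([-1.0, 1.0], n_mi) * rng.uniform(*config.med_beta_range, n_mi)
    mi_se_eqtl = 1.0 / np.sqrt(2 * mi_maf * (1 - mi_maf) * config.n_eqtl)
    mi_se_med = np.sqrt(4.0 / (n_eff_med * 2 * mi_maf * (1 - mi_maf)))
    mi_se_out = np.sqrt(4.0 / (n_eff_out * 2 * mi_maf * (1 - mi_maf)))
    mi_beta_med = mi_beta_med_true + rng.normal(0, mi_se_med)
    mi_beta_out = config.b * mi_beta_med_true + config.heterogeneity * rng.normal(0, mi_se_out)

    med_frames = [
        _assoc_frame(mi_snps, mi_chrom, mi_pos, mi_maf, mi_beta_med, mi_se_med, n_med_total)
    ]
    out_frames = [
        _assoc_frame(mi_snps, mi_chrom, mi_pos, mi_maf, mi_beta_out, mi_se_out, n_out_total)
    ]

    gene_sumstats: dict[str, SumStats] = {}
    ld: dict[str, LDMatrix] = {}
    truth_rows = []

    for g in range(config.n_genes):
        gid = f"GENE{g:03d}"
        symbol = f"SYM{g:03d}"
        chrom = str((g % 22) + 1)
        base = 1_000_000 + 40_000_000 * (g // 22)
        pos = np.array(
            [
                base + blk * 200_000 + (i % config.block_size) * 2_000
                for blk in range(config.n_instruments)
                for i in range(config.block_size)
            ]
        )
        snps = [f"rs_{gid}_{i:04d}" for i in range(m)]
        maf = rng.uniform(*config.maf_range, size=m)

        causal_eqtl = np.zeros(m)
        signs = rng.choice([-1.0, 1.0], config.n_instruments)
        mags = rng.uniform(*config.eqtl_beta_range, config.n_instruments)
        mags[0] = config.lead_beta
        causal_eqtl[causal_idx] = signs * mags

        pleio = np.zeros(m)
        if config.pleiotropy_mode != "off" and config.pleiotropy_scale > 0:
            mu = config.pleiotropy_scale if config.pleiotropy_mode == "directional" else 0.0
            pleio[causal_idx] = rng.normal(mu, config.pleiotropy_scale, config.n_instruments)

        causal_med = a_g[g] * causal_eqtl + pleio
        if linkage_g[g]:
            # second causal variant, mediator only, in LD with the lead eQTL
            offset = max(1, int(round(np.log(config.linkage_r) / np.log(config.ar1_rho))))
            partner = min(lead_idx + offset, config.block_size - 1)  # stay in the lead block
            causal_med[partner] += 0.5

        marg_eqtl = R @ causal_eqtl
        marg_med = R @ causal_med
        marg_out = config.b * marg_med + delta_g[g] * marg_eqtl

        se_eqtl = 1.0 / np.sqrt(2 * maf * (1 - maf) * config.n_eqtl)
        se_med = np.sqrt(4.0 / (n_eff_med * 2 * maf * (1 - maf)))
        se_out = np.sqrt(4.0 / (n_eff_out * 2 * maf * (1 - maf)))

        bh_eqtl = marg_eqtl + se_eqtl * (L @ rng.standard_normal(m))
        bh_med = marg_med + se_med * (L @ rng.standard_normal(m))
        bh_out = marg_out + config.heterogeneity * se_out * (L @ rng.standard_normal(m))

        locus_eqtl = _assoc_frame(snps, chrom, pos, maf, bh_eqtl, se_eqtl, config.n_eqtl)
        # the same scan also reports (null) associations at the mediator instruments
        mi_bh_eqtl = rng.normal(0, mi_se_eqtl)
        extra = _assoc_frame(mi_snps, mi_chrom, mi_pos, mi_maf, mi_bh_eqtl, mi_se_eqtl, config.n_eqtl)
        gene_sumstats[gid] = SumStats(
            gid, "eqtl_gene", pd.concat([locus_eqtl, extra], ignore_index=True), symbol
        )
        ld[gid] = LDMatrix(snps, R)

        med_frames.append(_assoc_frame(snps, chrom, pos, maf, bh_med, se_med, n_med_total))
        out_frames.append(_assoc_frame(snps, chrom, pos, maf, bh_out, se_out, n_out_total))

        if delta_g[g] != 0:
            expected = "total_significant"
        elif a_g[g] != 0:
            expected = "mediation_only"
        else:
            expected = "none"
        truth_rows.append(
            {
                "gene_id": gid,
                "gene_symbol": symbol,
                "a": a_g[g],
                "delta": delta_g[g],
                "b": config.b,
                "mediated": a_g[g] * config.b,
                "expected_category": expected,
            }
        )

    mediator = SumStats("mediator", "mediator", pd.concat(med_frames, ignore_index=True))
    outcome = SumStats("outcome", "outcome", pd.concat(out_frames, ignore_index=True))
    mediator_ld = LDMatrix(mi_snps, np.eye(n_mi))
    return StudyBundle(
        gene_sumstats=gene_sumstats,
        mediator=mediator,
        outcome=outcome,
        ld=ld,
        mediator_ld=mediator_ld,
        truth=pd.DataFrame(truth_rows),
        config=config,
    )


def standard_scenario(seed: int = 0, n_mediation: int = 5, n_total: int = 2, n_null: int = 3) -> SimConfig:
    """The reference recovery scenario: mediation-only, total-effect and null genes.

    Mediation-only genes act on the outcome purely through the mediator
    (a=0.25, δ=0); total-effect genes add a dominant direct path (δ=1.8);
    null genes have no effect at all.
    """
    n = n_mediation + n_total + n_null
    a = [0.25] * n_mediation + [0.25] * n_total + [0.0] * n_null
    delta = [0.0] * n_mediation + [1.8] * n_total + [0.0] * n_null
    return SimConfig(n_genes=n, a=a, delta=delta, seed=seed)


def simulate_heidi_locus(
    scenario: str = "pleiotropy",
    n_snps: int = 30,
    rho: float = 0.9,
    linkage_r: float = 0.7,
    b_xy: float = 0.5,
    beta_lead: float = 0.8,
    maf: float = 0.3,
    n_eqtl: int = 31_684,
    n_gwas: int = 400_000,
    noise: float = 1.0,
    seed: int = 0,
) -> tuple[SumStats, SumStats, LDMatrix]:
    """One dense AR(1) locus for exercising the HEIDI test.

    ``pleiotropy``: a single causal variant drives both the expression and the
    trait (effects exactly proportional, ratio ``b_xy``) — the HEIDI null.
    ``linkage``: a second variant in LD ``linkage_r`` with the eQTL drives the
    trait instead, so per-variant Wald ratios disagree.  ``noise=0`` returns
    the expectation (zero HEIDI statistic under pleiotropy).
    """
    if scenario not in {"pleiotropy", "linkage"}:
        raise ValueError("scenario must be 'pleiotropy' or 'linkage'")
    if n_snps < 10:
        raise ValueError("need at least 10 SNPs")
    rng = np.random.default_rng(seed)
    k = np.arange(n_snps)
    R = rho ** np.abs(k[:, None] - k[None, :])
    L = np.linalg.cholesky(R + 1e-12 * np.eye(n_snps))
    lead = n_snps // 2

    causal_e = np.zeros(n_snps)
    causal_e[lead] = beta_lead
    causal_g = np.zeros(n_snps)
    if scenario == "pleiotropy":
        causal_g[lead] = b_xy * beta_lead
    else:
        offset = max(1, int(round(np.log(linkage_r) / np.log(rho))))
        causal_g[lead + offset] = b_xy * beta_lead

    marg_e = R @ causal_e
    marg_g = R @ causal_g
    se_e = np.full(n_snps, 1.0 / np.sqrt(2 * maf * (1 - maf) * n_eqtl))
    se_g = np.full(n_snps, 1.0 / np.sqrt(2 * maf * (1 - maf) * n_gwas))
    bh_e = marg_e + noise * se_e * (L @ rng.standard_normal(n_snps))
    bh_g = marg_g + noise * se_g * (L @ rng.standard_normal(n_snps))

    snps = [f"rs_locus_{i:03d}" for i in range(n_snps)]
    pos = 1_000_000 + 2_000 * k
    eqtl = SumStats(
        "locus_gene",
        "eqtl_gene",
        _assoc_frame(snps, "1", pos, np.full(n_snps, maf), bh_e, se_e, n_eqtl),
        "LOCUSGENE",
    )
    gwas = SumStats(
        "trait", "mediator", _assoc_frame(snps, "1", pos, np.full(n_snps, maf), bh_g, se_g, n_gwas)
    )
    return eqtl, gwas, LDMatrix(snps, R)
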