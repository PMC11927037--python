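"""End-to-end screening cascade with stage-wise Bonferroni correction.

Stage order, with the multiplicity denominator of every corrected stage
computed from the realized count of the stage before it (never hard-coded):

1. ``smr_screen``     — per-gene SMR + HEIDI + symbol filter on the
                        gene→mediator association.
2. ``tsmr_mediator``  — per-gene two-sample MR of expression on the
                        mediator (clumped instruments, sensitivity suite);
                        Bonferroni 0.05/n_screened.
3. ``mediator_outcome`` — single two-sample MR of the mediator on the
                        outcome (the b path).
4. ``total_effect``   — per-gene TSMR of expression on the outcome;
                        Bonferroni 0.05/n_validated.
5. ``direct_effect``  — per-gene multivariable MR (gene + mediator on the
                        outcome); Bonferroni 0.05/n_validated.
6. ``mediation``      — product-of-coefficients decomposition with
                        distribution-of-product CIs and the
                        total/direct/mediation-only classification.
7. ``druggability``   — optional cross-database triage of the
                        mediation-only genes (direction = sign of a·b).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import drugdb as drugdb_mod
from .mediation import MediationDecomposition
from .mvmr import MVMR
from .smr import HeidiSelection, SMRResult, heidi_test, smr_screen, smr_test
from .sumstats import HarmonizedPairs, NoInstrumentsError, clump, harmonize
from .synthdata import StudyBundle
from .tsmr import TwoSampleMR, ivw, sensitivity_suite, wald_ratio

__all__ = ["CascadeConfig", "StageReport", "CascadeResult", "run_cascade"]

_FLOAT_FMT = "%.10g"


@dataclass
class CascadeConfig:
    """All thresholds, seeds and toggles of one cascade run."""

    p_smr: float = 0.05
    p_heidi: float = 0.05
    clump_p: float = 5e-8
    clump_kb: float = 10_000
    clump_r2: float = 0.001
    alpha: float = 0.05
    run_heidi: bool = True
    require_symbol: bool = True
    heidi_draws: int = 20_000
    n_boot: int = 1000
    ci_level: float = 0.95
    ci_method: str = "analytic"
    variance_formula: str = "exact"
    run_druggability: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_smr", "p_heidi", "alpha", "clump_p"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if not (0 < self.ci_level < 1):
            raise ValueError("ci_level must be in (0, 1)")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    @classmethod
    def from_yaml(cls, path) -> "CascadeConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class StageReport:
    """Audit record of one cascade stage."""

    stage: str
    n_in: int
    n_out: int
    threshold: float | None
    bonferroni_denominator: int | None
    verdicts: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.n_out > self.n_in:
            raise ValueError(f"stage {self.stage}: n_out {self.n_out} > n_in {self.n_in}")


@dataclass
class CascadeResult:
    reports: list[StageReport]
    final_table: pd.DataFrame
    decompositions: list[MediationDecomposition]
    b_estimate: object  # MREstimate for the mediator→outcome path
    b_report: object  # SensitivityReport
    drug_calls: pd.DataFrame | None
    manifest: dict

    def stage(self, name: str) -> StageReport:
        for r in self.reports:
            if r.stage == name:
                return r
        raise KeyError(name)

    def write(self, out_dir) -> None:
        """Write per-stage TSVs, the forest-plot table and the run manifest."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for rep in self.reports:
            rep.verdicts.to_csv(
                out / f"stage_{rep.stage}.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
            )
        self.final_table.to_csv(
            out / "final_genes.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
        )
        if self.b_report is not None:
            forest = self.b_report.summary().reset_index()
            forest.to_csv(out / "mediator_outcome_forest.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
        if self.drug_calls is not None:
            self.drug_calls.to_csv(out / "drug_calls.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)


def _clumped_pairs(gene_ss, other_ss, ld, config) -> HarmonizedPairs | None:
    """Clump the gene's variants and harmonize the kept instruments with the other trait."""
    covered = gene_ss.subset(ld.snp_ids)
    kept = clump(covered, ld, config.clump_p, config.clump_kb, config.clump_r2)
    if not kept:
        return None
    try:
        return harmonize(gene_ss.subset(kept), other_ss)
    except NoInstrumentsError:
        return None


def _estimate(pairs: HarmonizedPairs, config: CascadeConfig, seed: int):
    """Primary estimate: IVW-MRE for >= 2 instruments, Wald ratio for one."""
    if len(pairs) == 1:
        return wald_ratio(pairs)
    return ivw(pairs, "mre")


def run_cascade(bundle: StudyBundle, config: CascadeConfig | None = None) -> CascadeResult:
    """Run the full screening cascade on a study bundle.

    Deterministic for fixed ``bundle`` and ``config`` (all stochastic
    components are seeded from ``config.seed``).  Any stage with zero
    survivors stops the cascade cleanly, returning the reports so far.
    """
    config = config or CascadeConfig()
    reports: list[StageReport] = []
    genes = list(bundle.gene_sumstats)

    # ---- stage 1: SMR + HEIDI + symbol screen (gene → mediator) ----------
    smr_results: list[SMRResult] = []
    for i, gid in enumerate(genes):
        gss = bundle.gene_sumstats[gid]
        ld = bundle.ld[gid]
        pairs = harmonize(gss.subset(ld.snp_ids), bundle.mediator)
        tab = pairs.table.merge(
            gss.table[["snp", "p"]].rename(columns={"p": "p_eqtl"}), on="snp"
        )
        top = tab.sort_values(["p_eqtl", "snp"], kind="stable").iloc[0]
        b_xy, se_xy, p_smr = smr_test(
            top["beta_exp"], top["se_exp"], top["beta_out"], top["se_out"]
        )
        if config.run_heidi:
            p_heidi, n_heidi = heidi_test(
                gss.subset(ld.snp_ids),
                bundle.mediator.subset(ld.snp_ids),
                ld,
                selection=HeidiSelection(),
                n_draws=config.heidi_draws,
                seed=config.seed + 1000 + i,
            )
        else:
            p_heidi, n_heidi = 1.0, 0
        smr_results.append(
            SMRResult(gid, top["snp"], b_xy, se_xy, p_smr, p_heidi, n_heidi, gss.gene_symbol)
        )
    screen = smr_screen(
        smr_results,
        p_smr_thresh=config.p_smr,
        p_heidi_thresh=config.p_heidi,
        require_symbol=config.require_symbol,
    )
    screened = screen[screen["passed"]]["gene_id"].tolist()
    reports.append(StageReport("smr_screen", len(genes), len(screened), config.p_smr, None, screen))
    manifest = {"config": asdict(config), "config_digest": config.digest()}
    if not screened:
        return _finish(reports, [], None, None, None, manifest)

    # ---- stage 2: TSMR gene → mediator, Bonferroni 0.05/n_screened -------
    n_screened = len(screened)
    thresh2 = config.alpha / n_screened
    rows2, validated, gene_pairs_med, a_paths = [], [], {}, {}
    for i, gid in enumerate(screened):
        pairs = _clumped_pairs(
            bundle.gene_sumstats[gid], bundle.mediator, bundle.ld[gid], config
        )
        if pairs is None:
            rows2.append({"gene_id": gid, "n_snps": 0, "beta": np.nan, "se": np.nan,
                          "pvalue": np.nan, "method": "none", "passed": False})
            continue
        gene_pairs_med[gid] = pairs
        if len(pairs) >= 3:
            rep = sensitivity_suite(pairs, alpha=config.alpha, n_boot=config.n_boot,
                                    seed=config.seed + 2000 + i)
            est = rep.recommended
        else:
            est = _estimate(pairs, config, config.seed + 2000 + i)
        a_est = est if est.method.startswith("ivw") or est.method == "wald_ratio" else _estimate(pairs, config, 0)
        a_paths[gid] = a_est  # a path is always the IVW-MRE (or Wald) estimate
        ok = est.pvalue < thresh2
        if ok:
            validated.append(gid)
        rows2.append({"gene_id": gid, "n_snps": est.n_snps, "beta": est.beta, "se": est.se,
                      "pvalue": est.pvalue, "method": est.method, "passed": ok})
    reports.append(StageReport("tsmr_mediator", n_screened, len(validated), thresh2,
                               n_screened, pd.DataFrame(rows2)))
    if not validated:
        return _finish(reports, [], None, None, None, manifest)

    # ---- stage 3: mediator → outcome (the b path), estimated once --------
    med_candidates = bundle.mediator.subset(bundle.mediator_ld.snp_ids)
    med_kept = clump(med_candidates, bundle.mediator_ld, config.clump_p, config.clump_kb, config.clump_r2)
    if not med_kept:
        return _finish(reports, [], None, None, None, manifest)
    b_pairs = harmonize(bundle.mediator.subset(med_kept), bundle.outcome)
    b_report = sensitivity_suite(b_pairs, alpha=config.alpha, n_boot=config.n_boot,
                                 seed=config.seed + 3000) if len(b_pairs) >= 3 else None
    b_est = ivw(b_pairs, "mre") if len(b_pairs) >= 2 else wald_ratio(b_pairs)
    reports.append(StageReport(
        "mediator_outcome", 1, 1, None, None,
        pd.DataFrame([{"beta": b_est.beta, "se": b_est.se, "pvalue": b_est.pvalue,
                       "n_snps": b_est.n_snps, "method": b_est.method}]),
    ))

    # ---- stages 4-5: total (TSMR) and direct (MVMR) effects on the outcome
    n_validated = len(validated)
    thresh_total = config.alpha / n_validated
    thresh_direct = config.alpha / n_validated
    rows4, rows5 = [], []
    totals, directs = {}, {}
    for i, gid in enumerate(validated):
        pairs_out = _clumped_pairs(
            bundle.gene_sumstats[gid], bundle.outcome, bundle.ld[gid], config
        )
        if pairs_out is None:
            continue
        t_est = _estimate(pairs_out, config, config.seed + 4000 + i)
        totals[gid] = (t_est.beta, t_est.se, t_est.pvalue)
        rows4.append({"gene_id": gid, "beta": t_est.beta, "se": t_est.se,
                      "pvalue": t_est.pvalue, "n_snps": t_est.n_snps,
                      "passed": t_est.pvalue < thresh_total})

        # MVMR instrument set: union of the gene's and the mediator's instruments
        union = list(dict.fromkeys(list(gene_pairs_med[gid].table["snp"]) + med_kept))
        gss = bundle.gene_sumstats[gid]
        exp_out = harmonize(gss.subset(union), bundle.outcome)
        exp_med = harmonize(gss.subset(union), bundle.mediator)
        joined = exp_out.table.merge(
            exp_med.table[["snp", "beta_out"]].rename(columns={"beta_out": "beta_med"}),
            on="snp",
        )
        mv = MVMR(
            joined[["beta_exp", "beta_med"]].rename(columns={"beta_exp": gid, "beta_med": "mediator"}),
            joined["beta_out"].to_numpy(),
            joined["se_out"].to_numpy(),
        ).fit()
        d_beta, d_se, d_p = mv[gid]
        directs[gid] = (d_beta, d_se, d_p)
        rows5.append({"gene_id": gid, "beta": d_beta, "se": d_se, "pvalue": d_p,
                      "n_snps": mv.n_snps, "passed": d_p < thresh_direct})
    reports.append(StageReport("total_effect", n_validated, len(rows4), thresh_total,
                               n_validated, pd.DataFrame(rows4)))
    reports.append(StageReport("direct_effect", n_validated, len(rows5), thresh_direct,
                               n_validated, pd.DataFrame(rows5)))

    # ---- stage 6: mediation decomposition + classification ---------------
    decomps = []
    for i, gid in enumerate(validated):
        if gid not in totals or gid not in directs:
            continue
        a_est = a_paths[gid]
        decomps.append(
            MediationDecomposition.from_paths(
                gene_id=gid,
                a=a_est.beta,
                se_a=a_est.se,
                b=b_est.beta,
                se_b=b_est.se,
                total=totals[gid],
                direct=directs[gid],
                bonferroni_n_total=n_validated,
                bonferroni_n_direct=n_validated,
                level=config.ci_level,
                variance_formula=config.variance_formula,
                ci_method=config.ci_method,
                seed=config.seed + 5000 + i,
                gene_symbol=bundle.gene_sumstats[gid].gene_symbol,
            )
        )
    final = pd.DataFrame([d.summary() for d in decomps])
    n_med_only = int((final["category"] == "mediation_only").sum()) if len(final) else 0
    reports.append(StageReport("mediation", len(decomps), n_med_only, None, n_validated,
                               final.copy() if len(final) else pd.DataFrame()))

    # ---- stage 7: druggability triage of the mediation-only genes --------
    drug_calls = None
    if config.run_druggability and n_med_only:
        med_only = final[final["category"] == "mediation_only"]
        targets = {
            row["gene_symbol"] or row["gene_id"]: ("positive" if row["mediated"] > 0 else "negative")
            for _, row in med_only.iterrows()
        }
        calls = drugdb_mod.annotate_targets(targets, drugdb_mod.bundled_drug_tables())
        drug_calls = drugdb_mod.calls_to_frame(calls)
        reports.append(StageReport("druggability", n_med_only,
                                   int(drug_calls["validated"].sum()), None, None, drug_calls))

    return _finish(reports, decomps, b_est, b_report, drug_calls, manifest)


def _finish(reports, decomps, b_est, b_report, drug_calls, manifest) -> CascadeResult:
    final = pd.DataFrame([d.summary() for d in decomps])
    manifest = dict(manifest)
    manifest["stage_counts"] = {r.stage: [r.n_in, r.n_out] for r in reports}
    manifest["bonferroni_denominators"] = {
        r.stage: r.bonferroni_denominator for r in reports if r.bonferroni_denominator
    }
    return CascadeResult(
        reports=reports,
        final_table=final,
        decompositions=decomps,
        b_estimate=b_est,
        b_report=b_report,
        drug_calls=drug_calls,
        manifest=manifest,
    )
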