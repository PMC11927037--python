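"""GWAS / eQTL summary-statistics containers, TSV I/O, allele harmonization, LD clumping.

The unit of data is a per-variant association record (SNP id, position,
alleles, effect-allele frequency, beta, SE, p, n).  A :class:`SumStats` is one
trait's table of such records; downstream MR estimators consume
:class:`HarmonizedPairs`, the allele-aligned exposure/outcome instrument table.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SumStats",
    "LDMatrix",
    "HarmonizedPairs",
    "SumStatsFormatError",
    "EmptyInputError",
    "NoInstrumentsError",
    "STANDARD_COLUMNS",
    "read_sumstats",
    "write_sumstats",
    "harmonize",
    "clump",
]

#: canonical column order for summary-statistics TSV files
STANDARD_COLUMNS = ["snp", "chr", "pos", "ea", "oa", "eaf", "beta", "se", "p", "n"]

_VALID_ALLELES = {"A", "C", "G", "T"}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class SumStatsFormatError(ValueError):
    """A summary-statistics file is missing mandatory columns."""


class EmptyInputError(ValueError):
    """A summary-statistics table contained no usable rows."""


class NoInstrumentsError(ValueError):
    """Exposure and outcome share no variants after filtering."""


@dataclass
class SumStats:
    """One trait's per-variant association table.

    Parameters
    ----------
    trait_id : str
        Identifier of the trait (gene id, mediator name, outcome name).
    trait_type : {"eqtl_gene", "mediator", "outcome"}
    table : pandas.DataFrame
        Columns ``snp, chr, pos, ea, oa, eaf, beta, se, p, n`` (``eaf`` may be
        NaN).  ``snp`` values are unique.
    gene_symbol : str
        HGNC-style symbol for eQTL traits; empty string when the probe has no
        annotated symbol (such genes are dropped by the screening stage).
    """

    trait_id: str
    trait_type: str = "eqtl_gene"
    table: pd.DataFrame = field(default_factory=pd.DataFrame)
    gene_symbol: str = ""

    def __post_init__(self) -> None:
        if self.trait_type not in {"eqtl_gene", "mediator", "outcome"}:
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        if len(self.table) and self.table["snp"].duplicated().any():
            raise ValueError(f"duplicate snp ids in SumStats {self.trait_id!r}")

    def __len__(self) -> int:
        return len(self.table)

    def subset(self, snp_ids: Sequence[str]) -> "SumStats":
        keep = self.table[self.table["snp"].isin(set(snp_ids))].reset_index(drop=True)
        return SumStats(self.trait_id, self.trait_type, keep, self.gene_symbol)


@dataclass
class LDMatrix:
    """Pairwise LD correlations (r, not r²) for an ordered set of variants."""

    snp_ids: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        k = len(self.snp_ids)
        if self.r.shape != (k, k):
            raise ValueError("LD matrix shape does not match snp_ids")
        if not np.allclose(self.r, self.r.T, atol=1e-8):
            raise ValueError("LD matrix must be symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-6):
            raise ValueError("LD matrix must have unit diagonal")
        if np.any(np.abs(self.r) > 1 + 1e-8):
            raise ValueError("LD correlations must satisfy |r| <= 1")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def submatrix(self, snp_ids: Sequence[str]) -> np.ndarray:
        try:
            idx = [self._index[s] for s in snp_ids]
        except KeyError as exc:
            raise KeyError(f"LD matrix does not cover snp {exc.args[0]!r}") from exc
        return self.r[np.ix_(idx, idx)]

    def r2(self, snp_a: str, snp_b: str) -> float:
        return float(self.r[self._index[snp_a], self._index[snp_b]] ** 2)

    @classmethod
    def read(cls, path) -> "LDMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.columns), df.to_numpy(dtype=float))

    def write(self, path) -> None:
        pd.DataFrame(self.r, index=self.snp_ids, columns=self.snp_ids).to_csv(
            path, sep="\t", float_format="%.10g"
        )


@dataclass
class HarmonizedPairs:
    """Allele-aligned exposure/outcome instrument table.

    Every row refers to the same effect allele in both traits; outcome betas
    have been sign-flipped (and EAF complemented) where the outcome study coded
    the other allele.  ``action`` records what was done per SNP
    (``kept`` / ``flipped`` / palindromic handling).
    """

    table: pd.DataFrame  # snp, beta_exp, se_exp, beta_out, se_out, eaf, action

    def __post_init__(self) -> None:
        if len(self.table):
            if (self.table["se_exp"] <= 0).any() or (self.table["se_out"] <= 0).any():
                raise ValueError("harmonized pairs require positive SEs")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def beta_exp(self) -> np.ndarray:
        return self.table["beta_exp"].to_numpy(dtype=float)

    @property
    def se_exp(self) -> np.ndarray:
        return self.table["se_exp"].to_numpy(dtype=float)

    @property
    def beta_out(self) -> np.ndarray:
        return self.table["beta_out"].to_numpy(dtype=float)

    @property
    def se_out(self) -> np.ndarray:
        return self.table["se_out"].to_numpy(dtype=float)


def _is_palindromic(ea: str, oa: str) -> bool:
    return _COMPLEMENT.get(ea) == oa


def read_sumstats(
    path,
    column_map: Mapping[str, str] | None = None,
    trait_id: str = "",
    trait_type: str = "eqtl_gene",
    gene_symbol: str = "",
) -> tuple[SumStats, dict[str, int]]:
    """Read a summary-statistics TSV, dropping rows that violate invariants.

    Returns the validated :class:`SumStats` and a QC tally of dropped rows
    keyed by reason (``bad_se``, ``bad_p``, ``bad_alleles``, ``dup``,
    ``bad_n``).

    ``column_map`` maps standard names (see :data:`STANDARD_COLUMNS`) to the
    file's column names when they differ.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if column_map:
        rename = {v: k for k, v in column_map.items()}
        df = df.rename(columns=rename)
    missing = [c for c in STANDARD_COLUMNS if c not in df.columns and c != "eaf"]
    if missing:
        raise SumStatsFormatError(f"missing mandatory columns: {missing}")
    if "eaf" not in df.columns:
        df["eaf"] = np.nan
    if len(df) == 0:
        raise EmptyInputError(f"no rows in {path}")

    df = df[STANDARD_COLUMNS].copy()
    df["snp"] = df["snp"].astype(str)
    df["chr"] = df["chr"].astype(str)
    for col in ("pos", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("eaf", "beta", "se", "p"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["ea"] = df["ea"].astype(str).str.upper()
    df["oa"] = df["oa"].astype(str).str.upper()

    tally = {"bad_se": 0, "bad_p": 0, "bad_alleles": 0, "bad_n": 0, "dup": 0}
    bad_se = ~(df["se"] > 0) | df["se"].isna() | df["beta"].isna()
    tally["bad_se"] = int(bad_se.sum())
    df = df[~bad_se]
    bad_p = ~((df["p"] > 0) & (df["p"] <= 1))
    tally["bad_p"] = int(bad_p.sum())
    df = df[~bad_p]
    bad_alleles = (
        ~df["ea"].isin(_VALID_ALLELES)
        | ~df["oa"].isin(_VALID_ALLELES)
        | (df["ea"] == df["oa"])
    )
    tally["bad_alleles"] = int(bad_alleles.sum())
    df = df[~bad_alleles]
    bad_n = ~(df["n"] > 0)
    tally["bad_n"] = int(bad_n.sum())
    df = df[~bad_n]
    dup = df["snp"].duplicated(keep="first")
    tally["dup"] = int(dup.sum())
    df = df[~dup]

    df["pos"] = df["pos"].astype(np.int64)
    df = df.reset_index(drop=True)
    ss = SumStats(trait_id or str(path), trait_type, df, gene_symbol)
    return ss, tally


def write_sumstats(ss: SumStats, path) -> None:
    """Write a SumStats table as a standard-column TSV (round-trip safe)."""
    ss.table[STANDARD_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.10g")


def harmonize(
    exposure: SumStats,
    outcome: SumStats,
    palindrome_policy: str = "drop_ambiguous",
    eaf_threshold: float = 0.42,
) -> HarmonizedPairs:
    """Align outcome effects to the exposure effect allele.

    For shared SNPs, outcome betas are sign-flipped (and EAF complemented)
    when the outcome's effect allele is the exposure's other allele; strand
    flips (allele complements) are resolved the same way.  Palindromic (A/T,
    C/G) variants are ambiguous under ``drop_ambiguous`` (the default) when
    the minor-allele frequency exceeds ``eaf_threshold`` or the EAF is
    missing; ``keep`` retains them untouched, ``drop_all`` removes every
    palindromic SNP.

    Raises
    ------
    NoInstrumentsError
        If the two traits share no SNPs.
    """
    if palindrome_policy not in {"drop_ambiguous", "keep", "drop_all"}:
        raise ValueError(f"unknown palindrome_policy {palindrome_policy!r}")
    if len(exposure) == 0 or len(outcome) == 0:
        raise EmptyInputError("harmonize requires non-empty exposure and outcome")

    exp = exposure.table.set_index("snp")
    out = outcome.table.set_index("snp")
    shared = exp.index.intersection(out.index)
    if len(shared) == 0:
        raise NoInstrumentsError(
            f"no shared SNPs between {exposure.trait_id!r} and {outcome.trait_id!r}"
        )

    rows = []
    for snp in shared:
        e, o = exp.loc[snp], out.loc[snp]
        ea_e, oa_e = e["ea"], e["oa"]
        ea_o, oa_o = o["ea"], o["oa"]
        beta_o, eaf_o = float(o["beta"]), o["eaf"]
        palindromic = _is_palindromic(ea_e, oa_e)

        if palindromic:
            if palindrome_policy == "drop_all":
                continue
            if palindrome_policy == "drop_ambiguous":
                eaf = e["eaf"] if pd.notna(e["eaf"]) else eaf_o
                if pd.isna(eaf) or min(eaf, 1.0 - eaf) > eaf_threshold:
                    continue

        if (ea_o, oa_o) == (ea_e, oa_e):
            action = "kept"
        elif (ea_o, oa_o) == (oa_e, ea_e):
            beta_o = -beta_o
            eaf_o = 1.0 - eaf_o if pd.notna(eaf_o) else np.nan
            action = "flipped"
        elif not palindromic and (
            _COMPLEMENT.get(ea_o),
            _COMPLEMENT.get(oa_o),
        ) == (ea_e, oa_e):
            action = "strand"
        elif not palindromic and (
            _COMPLEMENT.get(ea_o),
            _COMPLEMENT.get(oa_o),
        ) == (oa_e, ea_e):
            beta_o = -beta_o
            eaf_o = 1.0 - eaf_o if pd.notna(eaf_o) else np.nan
            action = "strand_flipped"
        else:
            continue  # incompatible allele pair

        rows.append(
            {
                "snp": snp,
                "beta_exp": float(e["beta"]),
                "se_exp": float(e["se"]),
                "beta_out": beta_o,
                "se_out": float(o["se"]),
                "eaf": float(e["eaf"]) if pd.notna(e["eaf"]) else np.nan,
                "action": action,
            }
        )

    if not rows:
        raise NoInstrumentsError(
            f"no harmonizable SNPs between {exposure.trait_id!r} and {outcome.trait_id!r}"
        )
    table = pd.DataFrame(rows).sort_values("snp", kind="stable").reset_index(drop=True)
    return HarmonizedPairs(table)


def clump(
    ss: SumStats,
    ld: LDMatrix,
    p_thresh: float = 5e-8,
    window_kb: float = 10_000,
    r2_thresh: float = 0.001,
) -> list[str]:
    """Greedy p-value clumping of one trait's variants.

    Repeatedly keeps the remaining variant with the smallest p-value and
    discards every variant on the same chromosome within ``window_kb``
    kilobases whose LD r² with it is at least ``r2_thresh``.  Only variants
    with p < ``p_thresh`` are candidates.  Ties on p are broken by
    lexicographic snp id, making the selection deterministic.

    Returns the retained snp ids (may be empty — an instrument-less trait is
    not an error).
    """
    df = ss.table
    cand = df[df["p"] < p_thresh][["snp", "chr", "pos", "p"]].copy()
    if len(cand) == 0:
        return []
    missing = [s for s in cand["snp"] if s not in ld._index]
    if missing:
        raise KeyError(f"LD matrix does not cover candidate SNPs: {missing[:5]}")

    cand = cand.sort_values(["p", "snp"], kind="stable")
    window_bp = window_kb * 1000.0
    kept: list[str] = []
    remaining = cand.to_dict("records")
    while remaining:
        best = remaining.pop(0)
        kept.append(best["snp"])
        survivors = []
        for rec in remaining:
            if (
                rec["chr"] == best["chr"]
                and abs(rec["pos"] - best["pos"]) <= window_bp
                and ld.r2(best["snp"], rec["snp"]) >= r2_thresh
            ):
                continue
            survivors.append(rec)
        remaining = survivors
    return kept
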