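"""Cross-database druggability validation and direction-compatibility triage.

A candidate gene is *validated* as a drug target when it has at least one
drug record in each of the three annotation tables (DrugBank-, ChEMBL- and
DGIdb-style TSVs).  Direction compatibility then asks whether the available
pharmacology can push the target the therapeutic way: a gene whose
(mediated) causal effect on the outcome is positive needs an inhibitor, a
negative one needs an agonist.  Modulators, cofactors and unknown mechanisms
never satisfy compatibility.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

__all__ = [
    "DrugTargetRecord",
    "DruggabilityCall",
    "DATABASES",
    "MECHANISMS",
    "read_drug_table",
    "bundled_drug_tables",
    "annotate_targets",
    "direction_compatibility",
]

logger = logging.getLogger(__name__)

DATABASES = ("drugbank", "chembl", "dgidb")
MECHANISMS = ("inhibitor", "agonist", "modulator", "cofactor", "unknown")

#: normalization of free-text mechanism labels to the closed vocabulary
_MECHANISM_ALIASES = {
    "inhibitor": "inhibitor",
    "antagonist": "inhibitor",
    "blocker": "inhibitor",
    "agonist": "agonist",
    "activator": "agonist",
    "modulator": "modulator",
    "cofactor": "cofactor",
    "unknown": "unknown",
    "": "unknown",
}


def normalize_mechanism(raw: str) -> str:
    key = re.sub(r"[^a-z]", "", str(raw).strip().lower())
    mech = _MECHANISM_ALIASES.get(key)
    if mech is None:
        logger.warning("unrecognized drug mechanism %r mapped to 'unknown'", raw)
        mech = "unknown"
    return mech


@dataclass(frozen=True)
class DrugTargetRecord:
    """One drug–target annotation row from one database."""

    target: str
    database: str
    drug_id: str
    formula: str = ""
    mechanism: str = "unknown"

    def __post_init__(self):
        if self.database not in DATABASES:
            raise ValueError(f"unknown database {self.database!r}")
        object.__setattr__(self, "mechanism", normalize_mechanism(self.mechanism))


@dataclass
class DruggabilityCall:
    """Per-gene druggability verdict.

    ``validated`` is true exactly when all three databases carry at least one
    record for the gene; ``direction_compatible`` when the drug mechanisms on
    offer match the gene's causal direction.
    """

    gene: str
    causal_direction: str  # "positive" | "negative"
    databases_hit: set[str] = field(default_factory=set)
    validated: bool = False
    direction_compatible: bool = False
    rationale: str = ""

    def __post_init__(self):
        if self.causal_direction not in {"positive", "negative"}:
            raise ValueError(f"causal_direction must be positive/negative, got {self.causal_direction!r}")


def read_drug_table(path, database: str) -> list[DrugTargetRecord]:
    """Read one database's TSV (columns: target, database, accession_id, formula, mechanism)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    records = []
    for _, row in df.iterrows():
        records.append(
            DrugTargetRecord(
                target=row["target"],
                database=row.get("database", database) or database,
                drug_id=row.get("accession_id", ""),
                formula=row.get("formula", ""),
                mechanism=row.get("mechanism", "unknown"),
            )
        )
    return records


def bundled_drug_tables() -> dict[str, list[DrugTargetRecord]]:
    """Load the packaged example annotation tables for the candidate targets."""
    out = {}
    for db in DATABASES:
        path = resources.files("mrcascade.data") / f"{db}.tsv"
        out[db] = read_drug_table(path, db)
    return out


def annotate_targets(
    genes: dict[str, str],
    tables: dict[str, list[DrugTargetRecord]],
) -> list[DruggabilityCall]:
    """Cross-database druggability calls for a set of genes.

    Parameters
    ----------
    genes : mapping of gene symbol -> causal direction ("positive"/"negative")
    tables : mapping of database name -> its records

    Matching on gene symbol is case-insensitive.  A gene is validated iff it
    has at least one record in every one of the three databases.  Direction
    compatibility is filled in by :func:`direction_compatibility`.
    """
    unknown = set(tables) - set(DATABASES)
    if unknown:
        raise ValueError(f"unknown databases: {sorted(unknown)}")
    by_db = {
        db: {} for db in DATABASES
    }  # db -> gene(lower) -> records
    for db in DATABASES:
        for rec in tables.get(db, []):
            by_db[db].setdefault(rec.target.lower(), []).append(rec)

    calls = []
    for gene, direction in genes.items():
        key = gene.lower()
        hit = {db for db in DATABASES if key in by_db[db]}
        call = DruggabilityCall(
            gene=gene,
            causal_direction=direction,
            databases_hit=hit,
            validated=hit == set(DATABASES),
        )
        records = [r for db in hit for r in by_db[db][key]]
        calls.append(direction_compatibility(call, records))
    return calls


def direction_compatibility(
    call: DruggabilityCall, records: list[DrugTargetRecord]
) -> DruggabilityCall:
    """Fill in whether available mechanisms can counter the causal direction.

    Positive causal direction (raises outcome risk) + any inhibitor-class
    record → compatible; negative direction + any agonist-class record →
    compatible.  Other mechanisms never qualify.
    """
    mechanisms = {r.mechanism for r in records}
    if call.causal_direction == "positive":
        compatible = "inhibitor" in mechanisms
        want = "inhibitor"
    else:
        compatible = "agonist" in mechanisms
        want = "agonist"
    call.direction_compatible = compatible
    if compatible:
        call.rationale = (
            f"{call.causal_direction} causal direction with {want} available"
        )
    else:
        call.rationale = (
            f"{call.causal_direction} causal direction but no {want} on record "
            f"(mechanisms seen: {sorted(mechanisms) or 'none'})"
        )
    return call


def calls_to_frame(calls: list[DruggabilityCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [c.gene for c in calls],
            "causal_direction": [c.causal_direction for c in calls],
            "databases_hit": ["|".join(sorted(c.databases_hit)) for c in calls],
            "validated": [c.validated for c in calls],
            "direction_compatible": [c.direction_compatible for c in calls],
            "rationale": [c.rationale for c in calls],
        }
    )
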