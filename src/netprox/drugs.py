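"""Drug → annotated-gene-association catalogues.

The catalogue format is a simplified TSV export of a drug database: one row
per drug with a semicolon-joined list of ``GENE_relation_action`` tokens
(e.g. ``IL2RA_target_antibody``, ``CYP3A4_enzyme_substrate``).  The relation
says how the gene relates to the drug (pharmacological target, metabolizing
enzyme, transporter, carrier); the action is the free-text mechanism.  By
default all four relation kinds contribute to a drug's proximity target set —
screens at the strict cutoff surface drugs whose only printed associations
are enzymes and transporters, so restricting to pharmacological targets would
change the analysis.  Actions of the inhibitor/antagonist/antibody kind are
classified as down-regulating, i.e. plausibly therapeutic when the disease
gene is a risk factor whose expression should fall.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import pandas as pd

__all__ = [
    "RELATIONS",
    "TargetAnnotation",
    "DrugRecord",
    "parse_target_annotation",
    "parse_annotation_field",
    "load_drug_table",
    "save_drug_table",
    "target_genes",
    "classify_direction",
]

RELATIONS = ("target", "enzyme", "transporter", "carrier")

DRUG_COLUMNS = ("drug_id", "name", "annotations", "licensed", "medicinal", "indication")


@dataclass(frozen=True)
class TargetAnnotation:
    """One gene association of a drug: gene, relation kind, mechanism."""

    gene: str
    relation: Literal["target", "enzyme", "transporter", "carrier"]
    action: str = "unknown"

    def __post_init__(self):
        if self.relation not in RELATIONS:
            raise ValueError(f"unknown relation {self.relation!r} (gene {self.gene})")
        if not self.gene:
            raise ValueError("annotation gene symbol is empty")

    def token(self) -> str:
        action = "" if self.action == "unknown" else self.action
        return f"{self.gene}_{self.relation}_{action}"


@dataclass(frozen=True)
class DrugRecord:
    drug_id: str
    name: str
    annotations: tuple[TargetAnnotation, ...] = ()
    licensed: bool = False
    medicinal: bool = True
    indication: str = ""


def parse_target_annotation(s: str) -> TargetAnnotation:
    """Parse one ``GENE_relation_action`` token.

    The first underscore field is the gene, the second the relation; any
    remaining fields are re-joined as the action (which may itself contain
    underscores), defaulting to ``unknown`` when absent.  Emphasis markup
    (``**``) is stripped.  Compound actions such as ``substrate|inhibitor``
    are NOT expanded here — see :func:`parse_annotation_field`.
    """
    cleaned = s.replace("**", "").strip()
    fields = cleaned.split("_")
    if len(fields) < 2:
        raise ValueError(f"annotation {s!r} has fewer than 2 underscore fields")
    gene = fields[0].strip().upper()
    relation = fields[1].strip().lower()
    action = "_".join(fields[2:]).strip().lower() or "unknown"
    return TargetAnnotation(gene=gene, relation=relation, action=action)


def parse_annotation_field(field: str) -> tuple[TargetAnnotation, ...]:
    """Parse a semicolon-joined annotation field, expanding compound actions.

    ``A_target_inhibitor;B_enzyme_substrate|inhibitor`` yields three
    annotations (B once as substrate, once as inhibitor).  Duplicates on
    (gene, relation, action) are removed, first occurrence kept.
    """
    out: list[TargetAnnotation] = []
    seen = set()
    for token in field.split(";"):
        token = token.strip()
        if not token:
            continue
        base = parse_target_annotation(token)
        actions = base.action.split("|") if "|" in base.action else [base.action]
        for action in actions:
            ann = TargetAnnotation(base.gene, base.relation, action.strip() or "unknown")
            key = (ann.gene, ann.relation, ann.action)
            if key not in seen:
                seen.add(key)
                out.append(ann)
    return tuple(out)


def load_drug_table(path) -> list[DrugRecord]:
    """Read a drug catalogue TSV (columns: drug_id, name, annotations,
    licensed, medicinal, indication)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in DRUG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    records = []
    seen_ids = set()
    for _, row in df.iterrows():
        drug_id = row["drug_id"].strip()
        if drug_id in seen_ids:
            raise ValueError(f"{path}: duplicate drug_id {drug_id!r}")
        seen_ids.add(drug_id)
        records.append(
            DrugRecord(
                drug_id=drug_id,
                name=row["name"].strip(),
                annotations=parse_annotation_field(row["annotations"]),
                licensed=row["licensed"].strip() in ("1", "True", "true"),
                medicinal=row["medicinal"].strip() in ("1", "True", "true"),
                indication=row["indication"].strip(),
            )
        )
    return records


def save_drug_table(records: Sequence[DrugRecord], path) -> None:
    rows = [
        {
            "drug_id": r.drug_id,
            "name": r.name,
            "annotations": ";".join(a.token() for a in r.annotations),
            "licensed": int(r.licensed),
            "medicinal": int(r.medicinal),
            "indication": r.indication,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(DRUG_COLUMNS)).to_csv(path, sep="\t", index=False)


def target_genes(
    d: DrugRecord, relations: Iterable[str] = RELATIONS
) -> frozenset[str]:
    """Unique genes of a drug whose relation is in ``relations``
    (default: all four kinds — targets, enzymes, transporters, carriers)."""
    relations = frozenset(relations)
    unknown = relations - frozenset(RELATIONS)
    if unknown:
        raise ValueError(f"unknown relation(s) {sorted(unknown)}")
    return frozenset(a.gene for a in d.annotations if a.relation in relations)


DOWN_REGULATING_ACTIONS = frozenset({"inhibitor", "antagonist", "antibody"})


def classify_direction(a: TargetAnnotation) -> str:
    """``down_regulating`` for inhibitor/antagonist/antibody actions, else
    ``other`` (agonists, substrates, binders, unknowns...)."""
    return "down_regulating" if a.action in DOWN_REGULATING_ACTIONS else "other"
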