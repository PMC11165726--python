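"""Curation of GWAS locus evidence into a disease gene set.

Input is a table of locus-level association records — each row one reported
finding, carrying a raw gene label (possibly naming several genes, e.g.
``TNFRSF14/MMEL1``), one or more p-values, the cytoband/chromosome, rsIDs and
a source citation key.  Curation (i) keeps records reaching genome-wide
significance (min p-value strictly below 5e-8 — the retention is per record,
so a locus supported by one significant SNP keeps its weaker companion SNPs),
(ii) drops HLA-region associations, whose complex linkage disequilibrium
makes gene assignment unreliable, and (iii) splits the surviving labels into
individual gene symbols and deduplicates them into the ordered disease gene
set used for proximity analysis.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import pandas as pd

__all__ = [
    "LocusRecord",
    "CurationConfig",
    "load_locus_table",
    "filter_significant",
    "exclude_hla",
    "split_gene_labels",
    "unique_gene_set",
    "curate",
]

_RSID = re.compile(r"^rs[0-9]+$")
_PARENTHETICAL = re.compile(r"\([^)]*\)")

LOCUS_COLUMNS = ("gene_label", "p_values", "locus", "snp_ids", "source_ref", "hla_flag")


@dataclass(frozen=True)
class LocusRecord:
    """One GWAS evidence row (a reported locus–disease association)."""

    gene_label: str
    p_values: tuple[float, ...]
    locus: str = ""
    snp_ids: tuple[str, ...] = ()
    source_ref: str = ""
    hla_flag: bool = False

    def __post_init__(self):
        if not self.p_values:
            raise ValueError(f"{self.gene_label}: record has no p-values")
        for p in self.p_values:
            if not (0 < p <= 1):
                raise ValueError(f"{self.gene_label}: p-value {p} outside (0, 1]")
        for rsid in self.snp_ids:
            if rsid and not _RSID.match(rsid):
                raise ValueError(f"{self.gene_label}: malformed rsID {rsid!r}")


@dataclass(frozen=True)
class CurationConfig:
    """Curation thresholds and rules.

    alpha is the genome-wide significance level (conventional 5e-8, strict
    inequality).  HLA exclusion is either driven by an explicit per-record
    flag (default — a blanket 6p21 rule would wrongly drop retained non-HLA
    loci in that band) or by the ``HLA-`` symbol prefix.
    """

    alpha: float = 5e-8
    hla_rule: Literal["flag_based", "symbol_prefix"] = "flag_based"
    split_separators: tuple[str, ...] = ("/", ",")

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")


def load_locus_table(path) -> list[LocusRecord]:
    """Read a locus evidence TSV (p_values and snp_ids semicolon-joined)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in LOCUS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    records = []
    for row_idx, row in df.iterrows():
        try:
            p_values = tuple(
                float(p) for p in str(row["p_values"]).split(";") if p.strip()
            )
        except ValueError as exc:
            raise ValueError(
                f"{path}: row {row_idx + 2}: non-numeric p-value "
                f"({row['p_values']!r})"
            ) from exc
        records.append(
            LocusRecord(
                gene_label=row["gene_label"],
                p_values=p_values,
                locus=row["locus"],
                snp_ids=tuple(s.strip() for s in row["snp_ids"].split(";") if s.strip()),
                source_ref=row["source_ref"],
                hla_flag=str(row["hla_flag"]).strip() in ("1", "True", "true"),
            )
        )
    return records


def filter_significant(
    records: Iterable[LocusRecord], config: CurationConfig = CurationConfig()
) -> list[LocusRecord]:
    """Keep records whose best p-value reaches genome-wide significance.

    Retention is per record with min(p) < alpha (strict): a locus backed by
    one significant SNP keeps its non-significant companion SNPs.
    """
    return [r for r in records if min(r.p_values) < config.alpha]


def exclude_hla(
    records: Iterable[LocusRecord], config: CurationConfig = CurationConfig()
) -> list[LocusRecord]:
    """Drop HLA-region records, by flag or by the ``HLA-`` symbol prefix."""
    if config.hla_rule == "flag_based":
        return [r for r in records if not r.hla_flag]
    kept = []
    for r in records:
        symbols = split_gene_labels(r.gene_label, config)
        if not all(s.startswith("HLA-") for s in symbols):
            kept.append(r)
    return kept


def split_gene_labels(
    label: str, config: CurationConfig = CurationConfig()
) -> list[str]:
    """Split a raw gene label into individual symbols.

    Splits on the configured separators (default ``/`` and ``,``), strips
    parenthetical annotations such as ``(2 SNPs)`` and surrounding
    whitespace, and uppercases.  Hyphenated readthrough symbols
    (``MSH5-SAPCD1``) are kept intact — the hyphen is not a separator.
    """
    cleaned = _PARENTHETICAL.sub("", label)
    parts = [cleaned]
    for sep in config.split_separators:
        parts = [piece for chunk in parts for piece in chunk.split(sep)]
    symbols = [p.strip().upper() for p in parts if p.strip()]
    if not symbols:
        raise ValueError(f"gene label {label!r} yields no symbols")
    return symbols


def unique_gene_set(
    records: Iterable[LocusRecord], config: CurationConfig = CurationConfig()
) -> list[str]:
    """Sorted, deduplicated union of gene symbols across records."""
    symbols: set[str] = set()
    for r in records:
        symbols.update(split_gene_labels(r.gene_label, config))
    return sorted(symbols)


def curate(
    records: Sequence[LocusRecord], config: CurationConfig = CurationConfig()
) -> tuple[list[str], pd.DataFrame]:
    """Full curation: significance filter, HLA exclusion, gene-set union.

    Returns the ordered disease gene set and a per-record audit table
    (gene_label, min_p, kept, reason).  The two filters commute, so the
    audit reports the first applicable drop reason.
    """
    audit_rows = []
    kept_records = []
    for r in records:
        if min(r.p_values) >= config.alpha:
            status, reason = False, "below genome-wide significance"
        elif (config.hla_rule == "flag_based" and r.hla_flag) or (
            config.hla_rule == "symbol_prefix"
            and all(
                s.startswith("HLA-") for s in split_gene_labels(r.gene_label, config)
            )
        ):
            status, reason = False, "HLA region"
        else:
            status, reason = True, ""
            kept_records.append(r)
        audit_rows.append(
            {
                "gene_label": r.gene_label,
                "min_p": min(r.p_values),
                "source_ref": r.source_ref,
                "kept": status,
                "reason": reason,
            }
        )
    genes = unique_gene_set(kept_records, config)
    return genes, pd.DataFrame(audit_rows)
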