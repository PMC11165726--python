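"""Batch proximity screening, cutoffs and cross-disease comparison.

``screen_all`` scores every drug in a catalogue against a disease gene set
and returns a ranked table; thresholding applies the validated broad cutoff
(z <= -0.15, "proximal, may exert a pharmacological effect") and a stricter
cutoff (z <= -2.0) used to pick the candidates most strongly tied to the
disease's genetic architecture.  ``cross_disease_overlap`` intersects two
screens — e.g. two cholestatic liver diseases — to find compounds proximal to
both.  Screen tables are plain pandas DataFrames so they compose with the
usual tooling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from netprox.drugs import RELATIONS, DrugRecord, classify_direction, target_genes
from netprox.interactome import degree_bins
from netprox.proximity import derive_seed, proximity_z

__all__ = [
    "Thresholds",
    "ScreenResult",
    "screen_all",
    "apply_threshold",
    "filter_medicinal",
    "cross_disease_overlap",
    "lookup_trialled",
    "normalize_drug_name",
    "drug_name_aliases",
]

log = logging.getLogger(__name__)

SCREEN_COLUMNS = [
    "drug_id",
    "name",
    "n_targets_mapped",
    "n_targets_total",
    "d_c",
    "mu",
    "sd",
    "z",
    "passes_broad",
    "passes_strict",
    "n_down_regulating",
    "licensed",
    "medicinal",
    "indication",
]


@dataclass(frozen=True)
class Thresholds:
    """Proximity cutoffs: broad (default -0.15) and strict (default -2.0),
    both inclusive (z <= cutoff passes)."""

    broad: float = -0.15
    strict: float = -2.0

    def __post_init__(self):
        if self.strict > self.broad:
            raise ValueError("strict cutoff must be <= broad cutoff")


@dataclass(frozen=True)
class ScreenResult:
    """Ranked screen table plus the drugs that could not be scored."""

    table: pd.DataFrame
    unscored: tuple[tuple[str, str], ...]  # (drug_id, reason)
    n_broad: int
    n_strict: int


def screen_all(
    g: nx.Graph,
    drugs: Sequence[DrugRecord],
    disease_genes: Iterable[str],
    thresholds: Thresholds = Thresholds(),
    n_random: int = 1000,
    seed: int = 0,
    min_bin_size: int | None = None,
    relations: Iterable[str] = RELATIONS,
) -> ScreenResult:
    """Score every drug against the disease gene set and rank by z.

    Each drug gets its own random stream derived from the root ``seed`` and
    its drug_id, so results do not depend on catalogue order.  Drugs whose
    genes do not map into the graph are reported in ``unscored`` with a
    reason rather than failing the batch.
    """
    drugs = list(drugs)
    if not drugs:
        raise ValueError("empty drug catalogue")
    disease_genes = frozenset(x for x in disease_genes)
    bins = degree_bins(g, min_bin_size)
    relations = frozenset(relations)

    rows = []
    unscored: list[tuple[str, str]] = []
    for d in drugs:
        targets = target_genes(d, relations)
        if not targets:
            unscored.append((d.drug_id, "no gene associations in requested relations"))
            continue
        try:
            res = proximity_z(
                g,
                targets,
                disease_genes,
                n_random=n_random,
                seed=derive_seed(seed, d.drug_id),
                bins=bins,
                drug_id=d.drug_id,
            )
        except ValueError as exc:
            unscored.append((d.drug_id, str(exc)))
            continue
        rows.append(
            {
                "drug_id": d.drug_id,
                "name": d.name,
                "n_targets_mapped": res.n_targets_mapped,
                "n_targets_total": res.n_targets_total,
                "d_c": res.d_c,
                "mu": res.mu,
                "sd": res.sigma,
                "z": res.z,
                "passes_broad": res.z <= thresholds.broad,
                "passes_strict": res.z <= thresholds.strict,
                "n_down_regulating": sum(
                    classify_direction(a) == "down_regulating" for a in d.annotations
                ),
                "licensed": d.licensed,
                "medicinal": d.medicinal,
                "indication": d.indication,
            }
        )
    if not rows:
        raise ValueError("no drug in the catalogue could be scored")
    table = (
        pd.DataFrame(rows, columns=SCREEN_COLUMNS)
        .sort_values(["z", "drug_id"], na_position="last")
        .reset_index(drop=True)
    )
    n_broad = int(table["passes_broad"].sum())
    n_strict = int(table["passes_strict"].sum())
    log.info(
        "screened %d drugs (%d unscorable): %d at z<=%g, %d at z<=%g",
        len(table),
        len(unscored),
        n_broad,
        thresholds.broad,
        n_strict,
        thresholds.strict,
    )
    return ScreenResult(
        table=table, unscored=tuple(unscored), n_broad=n_broad, n_strict=n_strict
    )


def apply_threshold(rows: pd.DataFrame, cutoff: float) -> pd.DataFrame:
    """Rows with z <= cutoff (inclusive), original order preserved."""
    return rows[rows["z"] <= cutoff].copy()


def filter_medicinal(rows: pd.DataFrame) -> pd.DataFrame:
    """Rows flagged as medicinal products (plausible systemic therapies)."""
    medicinal = rows["medicinal"].astype(bool)
    return rows[medicinal].copy()


def normalize_drug_name(name: str) -> str:
    """Canonical join key: lowercase, trimmed, internal whitespace collapsed."""
    return " ".join(name.strip().lower().split())


def drug_name_aliases(name: str) -> frozenset[str]:
    """Normalized aliases of a drug label; ``"Xifaxan - rifaximin"`` matches
    by either side.  Aliases split on a spaced hyphen or en-dash."""
    label = name.replace(" – ", " - ")
    parts = [p for p in label.split(" - ") if p.strip()]
    return frozenset(normalize_drug_name(p) for p in [label] + parts)


def cross_disease_overlap(
    rows_a: pd.DataFrame,
    rows_b: pd.DataFrame,
    cutoff: float = -2.0,
    require_status: bool = False,
) -> pd.DataFrame:
    """Compounds passing the cutoff in two screens, joined by drug name.

    Inner-joins the two tables on normalized (alias-aware) drug names, keeps
    rows with z <= cutoff in both, and — when ``require_status`` — requires a
    non-empty current-use / under-investigation status in either table's
    ``status`` column.  Result columns: name, z_a, z_b, status; sorted by
    z_a ascending.
    """
    b_pass = rows_b[rows_b["z"] <= cutoff]
    alias_to_b: dict[str, int] = {}
    for idx, name in b_pass["name"].items():
        for alias in drug_name_aliases(str(name)):
            alias_to_b.setdefault(alias, idx)

    out = []
    matched_b: set[int] = set()
    for _, row in rows_a[rows_a["z"] <= cutoff].iterrows():
        hit = None
        for alias in drug_name_aliases(str(row["name"])):
            if alias in alias_to_b:
                hit = alias_to_b[alias]
                break
        if hit is None or hit in matched_b:
            continue
        matched_b.add(hit)
        status = str(row.get("status", "") or "").strip()
        if not status:
            status = str(b_pass.loc[hit].get("status", "") or "").strip()
        if require_status and not status:
            continue
        out.append(
            {
                "name": row["name"],
                "z_a": row["z"],
                "z_b": b_pass.loc[hit, "z"],
                "status": status,
            }
        )
    return (
        pd.DataFrame(out, columns=["name", "z_a", "z_b", "status"])
        .sort_values("z_a")
        .reset_index(drop=True)
    )


def lookup_trialled(
    rows: pd.DataFrame, trial_list: Iterable[str]
) -> tuple[pd.DataFrame, list[str]]:
    """Annotate a screen with whether each drug appears in a trial list.

    Matching is case-insensitive and alias-aware.  Returns the annotated
    table (new boolean column ``trialled``) and the trial names that matched
    nothing.
    """
    trial_list = list(trial_list)
    trial_aliases = [(t, drug_name_aliases(t)) for t in trial_list]
    matched_trials: set[str] = set()
    flags = []
    for name in rows["name"]:
        aliases = drug_name_aliases(str(name))
        hit = False
        for trial_name, t_aliases in trial_aliases:
            if aliases & t_aliases:
                hit = True
                matched_trials.add(trial_name)
        flags.append(hit)
    annotated = rows.copy()
    annotated["trialled"] = flags
    unmatched = [t for t in trial_list if t not in matched_trials]
    return annotated, unmatched
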