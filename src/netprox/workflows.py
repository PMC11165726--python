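"""End-to-end runs: curate, screen, compare, simulate.

These functions tie the stages into the full analysis workflow — curate a
GWAS locus table into a disease gene list, screen a drug catalogue against it
on an interactome, compare two diseases' screens, or generate a synthetic
study directory.  Each is a thin, deterministic wrapper over the library
modules: all randomness flows from the single ``seed`` in :class:`RunConfig`,
and every output is a plain text file under ``out_dir``.  The scripts in
``examples/`` show each entry point in use.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from netprox import gwas
from netprox.drugs import RELATIONS, load_drug_table, save_drug_table
from netprox.interactome import (
    largest_connected_component,
    load_edge_list,
    save_edge_list,
)
from netprox.screening import (
    ScreenResult,
    Thresholds,
    cross_disease_overlap,
    screen_all,
)
from netprox.synthetic import SyntheticStudyConfig, generate_study

__all__ = ["RunConfig", "curate", "screen", "compare", "simulate"]


@dataclass(frozen=True)
class RunConfig:
    """Paths and settings for one screening run."""

    interactome_path: str | Path
    disease_path: str | Path  # locus evidence TSV or one-gene-per-line list
    drug_table_path: str | Path
    out_dir: str | Path = "netprox_out"
    thresholds: Thresholds = field(default_factory=Thresholds)
    n_random: int = 1000
    seed: int = 0
    min_bin_size: int | None = None
    relations: tuple[str, ...] = RELATIONS
    restrict_to_lcc: bool = True  # analysis runs on the largest component
    curation: gwas.CurationConfig = field(default_factory=gwas.CurationConfig)

    def validate(self) -> None:
        for p in (self.interactome_path, self.disease_path, self.drug_table_path):
            if not Path(p).exists():
                raise FileNotFoundError(p)


def _out(config_or_dir) -> Path:
    out = Path(getattr(config_or_dir, "out_dir", config_or_dir))
    out.mkdir(parents=True, exist_ok=True)
    return out


def curate(
    locus_path, out_dir, config: gwas.CurationConfig = gwas.CurationConfig()
) -> list[str]:
    """Curate a locus evidence table into a disease gene list.

    Writes ``disease_genes.txt`` (one symbol per line) and
    ``curation_audit.tsv`` (record → kept/dropped → reason) to ``out_dir``.
    """
    records = gwas.load_locus_table(locus_path)
    genes, audit = gwas.curate(records, config)
    if not genes:
        raise ValueError("curation produced an empty gene set")
    out = _out(out_dir)
    (out / "disease_genes.txt").write_text("\n".join(genes) + "\n")
    audit.to_csv(out / "curation_audit.tsv", sep="\t", index=False)
    return genes


def _read_disease_genes(path, config: RunConfig) -> list[str]:
    text = Path(path).read_text()
    if text.splitlines() and "\t" in text.splitlines()[0]:
        records = gwas.load_locus_table(path)
        genes, _ = gwas.curate(records, config.curation)
        return genes
    return [line.strip().upper() for line in text.splitlines() if line.strip()]


def screen(config: RunConfig) -> ScreenResult:
    """Run the full proximity screen and write the ranked table.

    Outputs under ``out_dir``: ``screen.tsv`` (ranked rows), ``summary.txt``
    (threshold counts and unscoreable drugs), and ``run_config.json``.
    """
    config.validate()
    g = load_edge_list(config.interactome_path)
    if config.restrict_to_lcc:
        g = largest_connected_component(g)
    genes = _read_disease_genes(config.disease_path, config)
    drugs = load_drug_table(config.drug_table_path)
    result = screen_all(
        g,
        drugs,
        genes,
        thresholds=config.thresholds,
        n_random=config.n_random,
        seed=config.seed,
        min_bin_size=config.min_bin_size,
        relations=config.relations,
    )
    out = _out(config)
    result.table.to_csv(out / "screen.tsv", sep="\t", index=False)
    summary = [
        f"drugs scored\t{len(result.table)}",
        f"z <= {config.thresholds.broad}\t{result.n_broad}",
        f"z <= {config.thresholds.strict}\t{result.n_strict}",
        f"unscoreable\t{len(result.unscored)}",
    ] + [f"unscored\t{drug_id}\t{reason}" for drug_id, reason in result.unscored]
    (out / "summary.txt").write_text("\n".join(summary) + "\n")
    (out / "run_config.json").write_text(
        json.dumps(
            {
                "seed": config.seed,
                "n_random": config.n_random,
                "broad": config.thresholds.broad,
                "strict": config.thresholds.strict,
                "relations": list(config.relations),
                "restrict_to_lcc": config.restrict_to_lcc,
            },
            indent=2,
        )
    )
    return result


def compare(
    screen_a,
    screen_b,
    out_dir,
    cutoff: float = -2.0,
    require_status: bool = False,
) -> pd.DataFrame:
    """Overlap two screen tables (paths or DataFrames) at a cutoff; writes
    ``overlap.tsv``.  Emits an empty table (with a warning in the file) when
    the name sets are disjoint."""
    rows_a = screen_a if isinstance(screen_a, pd.DataFrame) else pd.read_csv(screen_a, sep="\t")
    rows_b = screen_b if isinstance(screen_b, pd.DataFrame) else pd.read_csv(screen_b, sep="\t")
    overlap = cross_disease_overlap(rows_a, rows_b, cutoff, require_status)
    out = _out(out_dir)
    overlap.to_csv(out / "overlap.tsv", sep="\t", index=False)
    return overlap


def simulate(
    config: SyntheticStudyConfig = SyntheticStudyConfig(), out_dir="synthetic_study"
) -> dict[str, Path]:
    """Generate a synthetic study directory ready for :func:`screen`.

    Writes ``interactome.tsv`` (edge list), ``disease_genes.txt``,
    ``drugs.tsv`` and ``study.json`` (config + true planted profiles).
    Byte-identical given the same config.
    """
    study = generate_study(config)
    out = _out(out_dir)
    paths = {
        "interactome": out / "interactome.tsv",
        "disease_genes": out / "disease_genes.txt",
        "drugs": out / "drugs.tsv",
        "study": out / "study.json",
    }
    save_edge_list(study.graph, paths["interactome"])
    paths["disease_genes"].write_text("\n".join(sorted(study.disease_genes)) + "\n")
    save_drug_table(study.drugs, paths["drugs"])
    paths["study"].write_text(
        json.dumps(
            {
                "seed": config.seed,
                "n_nodes": config.n_nodes,
                "mean_degree": config.mean_degree,
                "degree_model": config.degree_model,
                "disease_module_size": config.disease_module_size,
                "true_profiles": {k: list(v) for k, v in study.true_profiles.items()},
            },
            indent=2,
        )
    )
    return paths
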