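"""Synthetic interactomes, planted disease modules and ground-truth drugs.

The generator emulates the structural features the proximity statistic cares
about: a sparse, connected, heavy-tailed (scale-free-like) interaction
network; a connected disease module (GWAS hits cluster in neighbourhoods,
they are not scattered uniformly); and drugs whose targets sit at controlled
hop distances from the module, so the true closest-measure distance d_c of a
planted drug is known exactly.  It does not emulate biological annotation,
edge confidence or literature bias — a green test on synthetic data
establishes the statistics, not the biology.

The module also exposes the packaged fixture tables: verbatim transcriptions
of the published PSC summary tables (candidate loci, strict-cutoff medicinal
candidates, trialled drugs, IBD drugs, PSC/PBC overlap).  See
``data/errata.md`` for transcription notes.
"""

from __future__ import annotations

import hashlib
import shutil
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from netprox.drugs import DrugRecord, TargetAnnotation
from netprox.gwas import LocusRecord, load_locus_table
from netprox.interactome import shortest_distances

__all__ = [
    "SyntheticStudyConfig",
    "SyntheticStudy",
    "generate_interactome",
    "plant_disease_module",
    "plant_drug",
    "generate_study",
    "fixture_path",
    "make_fixture_tables",
    "load_table1_records",
    "load_table2_catalog",
    "load_table2_screen",
    "load_table3_trialled",
    "load_table4_ibd",
    "load_table5_overlap",
    "cross_disease_inputs",
    "FIXTURE_FILES",
]


# --------------------------------------------------------------------------
# generators


@dataclass(frozen=True)
class SyntheticStudyConfig:
    """Stated world for a synthetic proximity study.

    Defaults: a 750-node preferential-attachment graph of mean degree ~4
    (sparse and heavy-tailed like curated interactomes), a 10-gene connected
    disease module, planted drugs covering adjacent-to-distal profiles, and
    ten random 3-target drugs as background.  The size is the smallest round
    graph whose BFS rings reliably reach distance 4 from the module, so every
    default profile is plantable at any seed.
    """

    n_nodes: int = 750
    degree_model: str = "preferential_attachment"  # or "configuration"
    mean_degree: float = 4.0
    disease_module_size: int = 10
    drug_profiles: tuple[tuple[int, ...], ...] = (
        (0, 1, 1),
        (1, 1, 2, 2),
        (2, 2),
        (3, 3, 3, 4),
    )
    n_random_drugs: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.disease_module_size >= self.n_nodes:
            raise ValueError("disease module must be smaller than the graph")
        if any(d < 0 for profile in self.drug_profiles for d in profile):
            raise ValueError("requested distances must be >= 0")


def _node_name(i: int) -> str:
    return f"G{i + 1:04d}"


def generate_interactome(
    n_nodes: int,
    mean_degree: float = 4.0,
    degree_model: str = "preferential_attachment",
    seed: int = 0,
) -> nx.Graph:
    """Connected simple graph with ~``mean_degree`` and heavy-tailed degrees.

    ``preferential_attachment`` grows a Barabási–Albert graph and then tops
    up edges (endpoints drawn degree-weighted) until the requested edge count
    is met, so dense requests saturate towards the complete graph.
    ``configuration`` draws a power-law degree sequence, builds a
    configuration-model graph, simplifies it and reconnects components.
    Nodes are named G0001, G0002, ...  Deterministic given ``seed``.
    """
    if n_nodes < 10:
        raise ValueError("n_nodes must be >= 10")
    max_edges = n_nodes * (n_nodes - 1) // 2
    target_edges = round(n_nodes * mean_degree / 2)
    if target_edges > max_edges or mean_degree <= 0:
        raise ValueError(
            f"mean degree {mean_degree} unattainable on {n_nodes} nodes"
        )
    rng = np.random.default_rng(seed)

    if degree_model == "preferential_attachment":
        m = min(max(1, round(mean_degree / 2)), n_nodes - 1)
        g = nx.barabasi_albert_graph(n_nodes, m, seed=int(rng.integers(2**31)))
    elif degree_model == "configuration":
        # Power-law-ish sequence (Zipf a=2.5) rescaled to the requested mean.
        raw = rng.zipf(2.5, size=n_nodes).astype(float)
        raw = np.clip(raw, 1, n_nodes - 1)
        seq = np.maximum(1, np.round(raw * mean_degree / raw.mean())).astype(int)
        seq = np.minimum(seq, n_nodes - 1)
        if seq.sum() % 2:
            seq[int(rng.integers(n_nodes))] += 1
        g = nx.Graph(
            nx.configuration_model(list(seq), seed=int(rng.integers(2**31)))
        )
        g.remove_edges_from(nx.selfloop_edges(g))
        comps = sorted(nx.connected_components(g), key=len, reverse=True)
        for comp in comps[1:]:
            a = sorted(comp)[int(rng.integers(len(comp)))]
            b = sorted(comps[0])[int(rng.integers(len(comps[0])))]
            g.add_edge(a, b)
            comps[0].update(comp)
    else:
        raise ValueError(f"unknown degree model {degree_model!r}")

    # top up to the requested density, preferring high-degree endpoints
    while g.number_of_edges() < target_edges:
        deficit = target_edges - g.number_of_edges()
        if g.number_of_edges() > 0.5 * max_edges:
            non_edges = sorted(nx.non_edges(g))
            idx = rng.choice(len(non_edges), size=deficit, replace=False)
            g.add_edges_from(non_edges[i] for i in idx)
        else:
            nodes, degs = zip(*g.degree)
            w = np.asarray(degs, dtype=float) + 1.0
            w /= w.sum()
            for a, b in rng.choice(nodes, size=(deficit, 2), p=w):
                if a != b and not g.has_edge(a, b):
                    g.add_edge(int(a), int(b))

    order = sorted(g.nodes)
    return nx.relabel_nodes(g, {v: _node_name(i) for i, v in enumerate(order)})


def plant_disease_module(g: nx.Graph, size: int, seed: int = 0) -> frozenset[str]:
    """Connected gene set grown by snowball sampling from a random seed node."""
    if size >= g.number_of_nodes():
        raise ValueError("module size must be smaller than the graph")
    rng = np.random.default_rng(seed)
    nodes = sorted(g.nodes)
    start = nodes[int(rng.integers(len(nodes)))]
    module = {start}
    frontier = set(g[start])
    while len(module) < size:
        if not frontier:
            raise ValueError("component exhausted before reaching module size")
        pick = sorted(frontier)[int(rng.integers(len(frontier)))]
        module.add(pick)
        frontier.update(g[pick])
        frontier -= module
    return frozenset(module)


def plant_drug(
    g: nx.Graph,
    disease_genes: Iterable[str],
    profile: Sequence[int],
    seed: int = 0,
    drug_id: str = "planted",
) -> DrugRecord:
    """Drug whose targets realize exactly the requested closest distances.

    For each entry d of ``profile`` one distinct node is drawn uniformly from
    the BFS ring at distance d from the disease set (d = 0 picks a disease
    gene itself), so the drug's true d_c is the profile mean.  Realized
    distances are re-checked against the BFS map before returning.

    Raises
    ------
    ValueError
        If some requested ring has no unused node in this graph.
    """
    rng = np.random.default_rng(seed)
    dist = shortest_distances(g, disease_genes)
    rings: dict[int, list[str]] = {}
    for node, d in dist.items():
        rings.setdefault(d, []).append(node)
    chosen: list[str] = []
    for d in profile:
        candidates = sorted(set(rings.get(d, ())) - set(chosen))
        if not candidates:
            raise ValueError(
                f"no unused node at distance {d} from the disease set "
                f"(ring size {len(rings.get(d, ()))})"
            )
        chosen.append(candidates[int(rng.integers(len(candidates)))])
    realized = [dist[t] for t in chosen]
    assert list(realized) == list(profile), "planted distances failed verification"
    return DrugRecord(
        drug_id=drug_id,
        name=drug_id,
        annotations=tuple(TargetAnnotation(t, "target", "unknown") for t in chosen),
        licensed=False,
        medicinal=True,
        indication=f"synthetic drug, planted profile {tuple(profile)}",
    )


@dataclass(frozen=True)
class SyntheticStudy:
    """One generated study: graph, disease module, drug catalogue, truth."""

    config: SyntheticStudyConfig
    graph: nx.Graph = field(repr=False)
    disease_genes: frozenset[str]
    drugs: tuple[DrugRecord, ...]
    true_profiles: dict[str, tuple[int, ...]] = field(repr=False)


def generate_study(config: SyntheticStudyConfig = SyntheticStudyConfig()) -> SyntheticStudy:
    """Generate graph + module + catalogue from one root seed.

    Planted drugs are named ``planted_<i>_d<mean distance>``; background
    drugs (``random_<i>``) get three uniformly drawn target genes each.
    """
    rng = np.random.default_rng(config.seed)
    g = generate_interactome(
        config.n_nodes, config.mean_degree, config.degree_model,
        seed=int(rng.integers(2**31)),
    )
    disease = plant_disease_module(
        g, config.disease_module_size, seed=int(rng.integers(2**31))
    )
    drugs: list[DrugRecord] = []
    truth: dict[str, tuple[int, ...]] = {}
    for i, profile in enumerate(config.drug_profiles):
        mean_d = sum(profile) / len(profile)
        drug_id = f"planted_{i}_d{mean_d:g}"
        drugs.append(
            plant_drug(g, disease, profile, seed=int(rng.integers(2**31)),
                       drug_id=drug_id)
        )
        truth[drug_id] = tuple(profile)
    nodes = sorted(g.nodes)
    for i in range(config.n_random_drugs):
        targets = rng.choice(nodes, size=3, replace=False)
        drugs.append(
            DrugRecord(
                drug_id=f"random_{i}",
                name=f"random_{i}",
                annotations=tuple(
                    TargetAnnotation(str(t), "target", "unknown") for t in targets
                ),
                medicinal=True,
                indication="synthetic background drug",
            )
        )
    return SyntheticStudy(
        config=config,
        graph=g,
        disease_genes=disease,
        drugs=tuple(drugs),
        true_profiles=truth,
    )


# --------------------------------------------------------------------------
# packaged fixture tables

FIXTURE_FILES = (
    "table1_loci.tsv",
    "table2_psc_candidates.tsv",
    "table3_trialled.tsv",
    "table4_ibd_drugs.tsv",
    "table5_overlap.tsv",
    "errata.md",
)

# sha256 of the packaged transcriptions; guards accidental edits
FIXTURE_CHECKSUMS: dict[str, str] = {
    "errata.md": "d9dfa1ca727ae1965af5be4f4706efc8a75ab2745b02b434a399bcbe8c18c8ce",
    "table1_loci.tsv": "adb5bfb8dd238a47287ec9788d4142503885223af7a7de495ba8cf8f53b88fbc",
    "table2_psc_candidates.tsv": "08f64c7911c8380a988f08b3063d8f679539852b3fa0d96430226f99d97a83d3",
    "table3_trialled.tsv": "f4f0d9866f07e27ec6266fe57535f62b5e0a24f07e3d887d3e388d9cf944ded4",
    "table4_ibd_drugs.tsv": "762a5587e5991855c302f8040810ce9602ae41a5672fe189ba13956c0f26f0be",
    "table5_overlap.tsv": "4ba98946d216a3763864d5bd61c6a4436fff57cf8a65602e3917e5590c60ccc7",
}


def fixture_path(name: str) -> Path:
    """Filesystem path of a packaged fixture table."""
    if name not in FIXTURE_FILES:
        raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_FILES}")
    return Path(str(resources.files("netprox") / "data" / name))


def make_fixture_tables(dest_dir) -> dict[str, Path]:
    """Copy the packaged fixture tables into ``dest_dir``.

    Each file's sha256 is verified against the frozen checksum before
    copying, so a corrupted installation fails loudly.
    """
    dest_dir = Path(dest_dir)
    dest_dir.mkdir(parents=True, exist_ok=True)
    out = {}
    for name in FIXTURE_FILES:
        src = fixture_path(name)
        digest = hashlib.sha256(src.read_bytes()).hexdigest()
        expected = FIXTURE_CHECKSUMS.get(name)
        if expected is not None and digest != expected:
            raise ValueError(
                f"fixture {name} checksum mismatch (got {digest[:12]}...)"
            )
        out[name] = Path(shutil.copy(src, dest_dir / name))
    return out


def load_table1_records() -> list[LocusRecord]:
    """Candidate-locus evidence rows (38 records, 8 sources)."""
    return load_locus_table(fixture_path("table1_loci.tsv"))


def load_table2_catalog():
    """Strict-cutoff medicinal candidates as a drug catalogue (42 records)."""
    from netprox.drugs import load_drug_table

    return load_drug_table(fixture_path("table2_psc_candidates.tsv"))


def load_table2_screen() -> pd.DataFrame:
    """The same 42 candidates with their published z / mean / sd."""
    df = pd.read_csv(fixture_path("table2_psc_candidates.tsv"), sep="\t").fillna("")
    df["medicinal"] = df["medicinal"].astype(int).astype(bool)
    df["licensed"] = df["licensed"].astype(int).astype(bool)
    return df


def load_table3_trialled() -> pd.DataFrame:
    """Proximities of drugs trialled in the disease (20 rows)."""
    return pd.read_csv(fixture_path("table3_trialled.tsv"), sep="\t").fillna("")


def load_table4_ibd() -> pd.DataFrame:
    """Proximities of drugs used in inflammatory bowel disease (18 rows)."""
    return pd.read_csv(fixture_path("table4_ibd_drugs.tsv"), sep="\t")


def load_table5_overlap() -> pd.DataFrame:
    """Published two-disease overlap at the strict cutoff (20 rows)."""
    return pd.read_csv(fixture_path("table5_overlap.tsv"), sep="\t").fillna("")


def cross_disease_inputs() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic reconstruction of the two screening tables behind the
    published overlap.

    The two input screens were not published as separate tables; this
    rebuilds them from the overlap transcription (name, per-disease z,
    use/investigation status) and appends, as non-passing distractors, the
    four PBC z values quoted in the running text (ursodeoxycholic acid 0.171,
    obeticholic acid -0.737, bezafibrate -0.866, fenofibrate -0.986) and
    their counterparts from the trialled-drug table.  Row counts and z values
    of the overlapping compounds are verbatim; everything else is scaffolding.
    """
    t5 = load_table5_overlap()
    status = [
        (cu or ui).strip()
        for cu, ui in zip(t5["current_use"], t5["under_investigation"])
    ]
    psc = pd.DataFrame({"name": t5["name"], "z": t5["z_psc"], "status": status})
    pbc = pd.DataFrame({"name": t5["name"], "z": t5["z_pbc"], "status": status})
    pbc_text = pd.DataFrame(
        {
            "name": ["Ursodeoxycholic acid", "Obeticholic acid", "Bezafibrate",
                     "Fenofibrate"],
            "z": [0.171, -0.737, -0.866, -0.986],
            "status": ["", "", "", ""],
        }
    )
    t3 = load_table3_trialled()
    psc_text = pd.DataFrame(
        {
            "name": t3["name"],
            "z": t3["z"],
            "status": ["" for _ in range(len(t3))],
        }
    )
    psc_all = pd.concat([psc, psc_text], ignore_index=True)
    psc_all = psc_all.drop_duplicates(subset="name", keep="first").reset_index(drop=True)
    pbc_all = pd.concat([pbc, pbc_text], ignore_index=True).reset_index(drop=True)
    return psc_all, pbc_all
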