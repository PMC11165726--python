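"""The closest-measure drug–disease distance and its randomization z-score.

For a drug with target genes T and a disease gene set S on an interactome G,
the closest measure is

    d_c = mean over t in T of  min over s in S of  d(t, s)

with d(.,.) the unweighted shortest-path hop count.  A target that is itself
a disease gene contributes 0.  The statistic is standardized against a
degree-preserving null: surrogate target and disease sets are drawn so that
every surrogate node comes from the same degree bin as the real node it
replaces, d_c is recomputed for ``n_random`` surrogate pairs, and

    z = (d_c - mu) / sigma

with mu and sigma the empirical mean and (population) standard deviation of
the null sample.  z well below zero means the drug's targets are closer to
the disease module than degree-matched chance.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass
from typing import Iterable

import networkx as nx
import numpy as np

from netprox.interactome import DegreeBins, degree_bins, shortest_distances

__all__ = [
    "ProximityResult",
    "closest_distance",
    "sample_matched_set",
    "null_distribution",
    "proximity_z",
    "recover_dc",
    "derive_seed",
]


@dataclass(frozen=True)
class ProximityResult:
    """Proximity of one drug to one disease gene set.

    ``z`` is NaN and ``degenerate_null`` is set when the null sample has zero
    spread (sigma = 0), which happens on very small or complete graphs.
    Mapping counts record how many of the supplied genes were actually found
    in the interactome.
    """

    drug_id: str
    d_c: float
    mu: float
    sigma: float
    z: float
    n_random: int
    seed: int
    n_targets_mapped: int
    n_targets_total: int
    n_disease_mapped: int
    degenerate_null: bool = False
    n_unreachable_targets: int = 0


def _mapped(g: nx.Graph, genes: Iterable[str]) -> frozenset[str]:
    return frozenset(x for x in genes if x in g)


def _dc_from_distances(
    dist: dict[str, int], targets: Iterable[str]
) -> tuple[float, int]:
    """Mean closest distance over targets; unreachable targets are excluded.

    Returns (d_c, number of unreachable targets).  ``dist`` must be the
    multi-source BFS map from the disease set.
    """
    total = 0
    reached = 0
    missing = 0
    for t in targets:
        d = dist.get(t)
        if d is None:
            missing += 1
        else:
            total += d
            reached += 1
    if reached == 0:
        raise ValueError("no target gene can reach any disease gene")
    return total / reached, missing


def closest_distance(
    g: nx.Graph,
    targets: Iterable[str],
    disease_genes: Iterable[str],
) -> float:
    """Closest-measure distance d_c between a target set and a disease set.

    Targets and disease genes absent from the graph are dropped (with an
    error if nothing maps); targets with no finite path to any disease gene
    are excluded from the mean and reported via a warning.
    """
    t_mapped = _mapped(g, targets)
    s_mapped = _mapped(g, disease_genes)
    if not t_mapped:
        raise ValueError("drug unmappable: no target gene in the interactome")
    if not s_mapped:
        raise ValueError("no disease gene in the interactome")
    dist = shortest_distances(g, s_mapped)
    d_c, missing = _dc_from_distances(dist, t_mapped)
    if missing:
        warnings.warn(
            f"{missing} target gene(s) unreachable from the disease set; "
            "excluded from d_c",
            stacklevel=2,
        )
    return d_c


def sample_matched_set(
    g: nx.Graph,
    template: Iterable[str],
    bins: DegreeBins,
    rng: np.random.Generator,
) -> frozenset[str]:
    """Draw a degree-matched surrogate for ``template``.

    For each template node the surrogate is drawn uniformly, without
    replacement, from that node's degree bin; the result has exactly
    ``len(template)`` distinct nodes with the same per-bin composition.
    """
    demand: dict[int, int] = {}
    for node in template:
        try:
            b = bins.bin_of[node]
        except KeyError:
            raise ValueError(f"template node {node!r} not covered by bins") from None
        demand[b] = demand.get(b, 0) + 1
    out: list[str] = []
    for b, k in demand.items():
        pool = bins.nodes_in_bin(b)
        if k > len(pool):
            raise ValueError(
                f"degree bin {bins.bins[b][0]} holds {len(pool)} nodes but "
                f"{k} are required; rebuild bins with a larger min_bin_size"
            )
        idx = rng.choice(len(pool), size=k, replace=False)
        out.extend(pool[i] for i in idx)
    return frozenset(out)


def null_distribution(
    g: nx.Graph,
    targets: Iterable[str],
    disease_genes: Iterable[str],
    bins: DegreeBins,
    n_random: int,
    seed: int | np.random.Generator,
) -> tuple[float, float, np.ndarray]:
    """Empirical null of d_c over degree-matched surrogate set pairs.

    Draws ``n_random`` (surrogate target set, surrogate disease set) pairs,
    each degree-matched to the corresponding real set, and returns the mean,
    population standard deviation and the raw samples of d_c.  sigma = 0 is
    possible (degenerate null) and is left to the caller to flag.
    """
    if n_random < 2:
        raise ValueError("n_random must be >= 2")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    t_mapped = _mapped(g, targets)
    s_mapped = _mapped(g, disease_genes)
    if not t_mapped or not s_mapped:
        raise ValueError("targets and disease genes must map into the graph")
    samples = np.empty(n_random)
    for i in range(n_random):
        surr_t = sample_matched_set(g, t_mapped, bins, rng)
        surr_s = sample_matched_set(g, s_mapped, bins, rng)
        dist = shortest_distances(g, surr_s)
        samples[i], _ = _dc_from_distances(dist, surr_t)
    return float(samples.mean()), float(samples.std(ddof=0)), samples


def proximity_z(
    g: nx.Graph,
    targets: Iterable[str],
    disease_genes: Iterable[str],
    n_random: int = 1000,
    seed: int = 0,
    bins: DegreeBins | None = None,
    min_bin_size: int | None = None,
    drug_id: str = "drug",
) -> ProximityResult:
    """Full proximity analysis of one drug: d_c, the null, and z.

    ``bins`` may be passed in to share one binning across a batch; otherwise
    bins are built from ``g`` with ``min_bin_size`` (default
    min(100, ceil(n/20))).
    """
    targets = [t for t in targets]
    t_mapped = _mapped(g, targets)
    s_mapped = _mapped(g, disease_genes)
    if not t_mapped:
        raise ValueError("drug unmappable: no target gene in the interactome")
    if not s_mapped:
        raise ValueError("no disease gene in the interactome")
    if bins is None:
        bins = degree_bins(g, min_bin_size)

    dist = shortest_distances(g, s_mapped)
    d_c, n_unreachable = _dc_from_distances(dist, t_mapped)
    mu, sigma, _ = null_distribution(
        g, t_mapped, s_mapped, bins, n_random=n_random, seed=seed
    )
    degenerate = sigma == 0.0
    z = math.nan if degenerate else (d_c - mu) / sigma
    return ProximityResult(
        drug_id=drug_id,
        d_c=d_c,
        mu=mu,
        sigma=sigma,
        z=z,
        n_random=n_random,
        seed=seed,
        n_targets_mapped=len(t_mapped),
        n_targets_total=len(set(targets)),
        n_disease_mapped=len(s_mapped),
        degenerate_null=degenerate,
        n_unreachable_targets=n_unreachable,
    )


def recover_dc(z: float, mu: float, sigma: float) -> float:
    """Invert the z formula: d_c = mu + z * sigma (requires sigma > 0)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive to recover d_c")
    return mu + z * sigma


def derive_seed(root_seed: int, drug_id: str) -> int:
    """Stable per-drug seed below 2^31, independent of batch order."""
    digest = hashlib.sha256(f"{root_seed}:{drug_id}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
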