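"""A full proximity screen on a synthetic study with known ground truth.

Generates a 750-node scale-free-like interactome, plants a 10-gene connected
disease module and a catalogue of drugs at controlled distances, then scores
every drug: d_c against the module, a 500-draw degree-matched null, and
z = (d_c - mu) / sigma.  Planted near-module drugs should surface at the top.
"""

from netprox import screen_all
from netprox.synthetic import SyntheticStudyConfig, generate_study

study = generate_study(SyntheticStudyConfig(seed=1))
result = screen_all(
    study.graph, study.drugs, study.disease_genes, n_random=500, seed=1
)

print(f"graph: {study.graph.number_of_nodes()} genes, "
      f"{study.graph.number_of_edges()} interactions; "
      f"disease module: {len(study.disease_genes)} genes")
print(f"drugs scored: {len(result.table)}  "
      f"(z <= -0.15: {result.n_broad}, z <= -2.0: {result.n_strict})\n")
cols = ["drug_id", "n_targets_mapped", "d_c", "mu", "sd", "z"]
print(result.table[cols].to_string(index=False,
                                   float_format=lambda v: f"{v:.3f}"))
print("\nplanted_* drugs carry their true mean distance in the id; the "
      "ranking recovers it.\nrandom_* drugs are background; against a "
      "clustered disease module their z drifts\nsomewhat below zero (see "
      "docs/methods.md), so ranks are the robust readout.")
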