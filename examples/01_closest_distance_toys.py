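"""The closest-measure distance d_c on hand-built toy interactomes.

Four small graphs, each with a drug (a set of target genes) and a disease
gene set.  d_c is the mean over the drug's targets of the hop distance to
the nearest disease gene — the raw proximity before standardization.
"""

import networkx as nx

from netprox import closest_distance

worlds = {
    "drug 1 (four targets, near)": (
        nx.Graph([("T1", "PSC1"), ("T2", "PSC1"), ("T3", "X1"), ("X1", "PSC2"),
                  ("T4", "X2"), ("X2", "PSC3")]),
        {"T1", "T2", "T3", "T4"}, {"PSC1", "PSC2", "PSC3"},
    ),
    "drug 2 (two targets, near)": (
        nx.Graph([("U1", "PSC1"), ("U2", "Y1"), ("Y1", "PSC2")]),
        {"U1", "U2"}, {"PSC1", "PSC2"},
    ),
    "drug 3 (four targets, distal)": (
        nx.Graph([("O1", "A1"), ("A1", "A2"), ("A2", "PSC1"),
                  ("O2", "B1"), ("B1", "B2"), ("B2", "PSC1"),
                  ("O3", "C1"), ("C1", "C2"), ("C2", "PSC2"),
                  ("O4", "D1"), ("D1", "D2"), ("D2", "D3"), ("D3", "PSC3")]),
        {"O1", "O2", "O3", "O4"}, {"PSC1", "PSC2", "PSC3"},
    ),
    "drug 4 (three targets, adjacent)": (
        nx.Graph([("P1", "PSC3"), ("P2", "PSC3"), ("P3", "PSC2")]),
        {"P1", "P2", "P3"}, {"PSC2", "PSC3"},
    ),
}

for label, (g, targets, disease) in worlds.items():
    print(f"{label}: d_c = {closest_distance(g, targets, disease)}")
print("\nSmaller d_c = targets sit closer to the disease genes;"
      " a drug touching the disease genes themselves would score 0.")
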