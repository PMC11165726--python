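"""Parse a drug catalogue and inspect target sets and effect directions.

Loads the packaged 42-candidate table (drugs at the strict proximity cutoff)
and shows how GENE_relation_action annotations become target-gene sets and
down-regulation counts.
"""

from netprox import classify_direction, target_genes
from netprox.synthetic import load_table2_catalog

catalog = load_table2_catalog()
print(f"catalogue: {len(catalog)} medicinal products\n")

for name in ("Basiliximab", "Metronidazole", "Denileukin diftitox"):
    drug = next(d for d in catalog if d.name == name)
    all_genes = sorted(target_genes(drug))
    pharm = sorted(target_genes(drug, {"target"}))
    n_down = sum(classify_direction(a) == "down_regulating" for a in drug.annotations)
    print(f"{name} ({'licensed' if drug.licensed else 'investigational'})")
    print(f"  genes (all relations): {', '.join(all_genes)}")
    print(f"  pharmacological targets only: {', '.join(pharm) or '-'}")
    print(f"  down-regulating annotations: {n_down}")
print("All relation kinds (target/enzyme/transporter/carrier) feed the "
      "proximity target set by default;\ndown-regulating actions "
      "(inhibitor/antagonist/antibody) mark a likely therapeutic direction.")
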