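"""Compare candidate screens of two diseases and lookup trialled drugs.

Reconstructs the two cholestatic-liver-disease screening tables behind the
packaged overlap fixture, intersects them at the strict cutoff, and
separately checks which trialled compounds the proximity method would have
flagged.
"""

from netprox import apply_threshold, cross_disease_overlap, lookup_trialled
from netprox.synthetic import cross_disease_inputs, load_table3_trialled

psc, pbc = cross_disease_inputs()
overlap = cross_disease_overlap(psc, pbc, cutoff=-2.0, require_status=True)
print(f"compounds at z <= -2.0 in both diseases, in use or under "
      f"investigation: {len(overlap)}")
print(overlap.head(5).to_string(index=False))

trialled = load_table3_trialled()
broad = apply_threshold(trialled, -0.15)
strict = apply_threshold(trialled, -2.0)
print(f"\ntrialled compounds: {len(trialled)}; "
      f"proximal at -0.15: {len(broad)}; at -2.0: {strict['name'].tolist()}")

annotated, unmatched = lookup_trialled(psc, trialled["name"].tolist())
print(f"screen rows matching a trialled compound: "
      f"{int(annotated['trialled'].sum())} (unmatched trial names: {len(unmatched)})")
print("\nShared strict-cutoff candidates are repurposing leads supported by "
      "both diseases' genetics.")
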