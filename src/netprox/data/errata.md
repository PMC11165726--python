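# Fixture transcription notes

The five TSV fixtures transcribe the published summary tables as printed,
including apparent typographical slips, so that counts computed on them match
the published counts.  Nothing is silently corrected.  Known oddities:

- `table1_loci.tsv`
  - Row "IL2RA ... CR40" quotes SNP `rs56258221` (chr 10), duplicating the
    BACH2 SNP; `rs4147359` is the IL2RA SNP quoted elsewhere.  Transcribed as
    printed.
  - Row "CD226 ... CR40" quotes SNP `rs3184504` (chr 18), duplicating the
    SH2B3 SNP; `rs1788097` is the CD226 SNP quoted elsewhere.  Transcribed as
    printed.
  - Row "SIK2 ... CR40" prints p = 4.77E-07, which does not reach genome-wide
    significance; the strict min(p) < 5e-8 filter drops this record.  SIK2
    remains in the curated set through its other source row (p = 3.17E-09),
    so the curated unique-gene count is still 26.
  - Emphasis markup around "(2 SNPs)" annotations is dropped (rendering, not
    content).
- `table2_psc_candidates.tsv`
  - Bold markup on actions (the published likely-therapeutic highlighting) is
    dropped; the same classification is recomputed from the action strings.
  - "canceers" (Galiximab), "inhibito" (one Promethazine CYP2D6 token),
    repeated tokens (TUBA3C twice, CYP3A7 twice, CALM1 three times,
    CYP2D6 twice) transcribed as printed; repeated tokens deduplicate on
    load.
  - The Fostamatinib annotation field is empty: the published row defers its
    >300 associations to a supplement that is outside desk scope.
  - Asterisks marking licensed products were transcribed into the `licensed`
    column; counting them gives 22, while the published text says 23 of 42
    are licensed.  The ambiguity is recorded here and the licensed count is
    asserted nowhere.
- `table3_trialled.tsv` / `table5_overlap.tsv`
  - Multi-trial result narratives are abridged into the `status` column; drug
    names, z values and row counts are verbatim.  En-dashes in drug aliases
    are transcribed as spaced hyphens.
  - The published Table 5 caption reads "both PSC and PSC"; the second
    disease is PBC.
- `table4_ibd_drugs.tsv`
  - "Tofacitinib 0.851" is printed twice; both rows are kept.
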