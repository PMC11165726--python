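# Methods

## Model

The analysis treats drug repurposing as a graph-distance problem.  Nodes of
an undirected interactome are gene symbols; edges are physical/functional
interactions; distances are unweighted hop counts (the method family this
package implements was defined on unweighted interactomes, and edge
confidences are deliberately out of scope).  A disease is a gene set *S*
(curated GWAS hits); a drug is a gene set *T* (its annotated gene
associations).  The closest measure

    d_c(T, S) = mean over t in T of min over s in S of d(t, s)

is computed with one multi-source BFS from *S*, so a whole screen costs one
BFS per null draw rather than one per target.  A target inside *S*
contributes 0.

### The degree-matched null

Raw d_c confounds proximity with connectivity: hubs are close to everything.
The null therefore resamples both the target set and the disease set,
replacing every node with a uniform draw (without replacement) from its
degree bin, recomputes d_c for `n_random` surrogate pairs, and standardizes:
z = (d_c − µ)/σ with µ, σ the empirical mean and population (divide-by-n)
standard deviation.  Population σ was chosen so that z is a plain plug-in
standardization, bit-for-bit reproducible from a seed; with n_random ≥ 100
the distinction from the n−1 form is far below the Monte-Carlo noise.

Degree bins group nodes by ascending degree, merging adjacent degree groups
until each bin holds `min_bin_size` nodes (a short trailing group folds
backwards).  Default `min_bin_size = min(100, ceil(n/20))`: 100 matches the
convention of the full-scale method, the n/20 floor keeps toy graphs from
collapsing into a single bin-of-everything.

σ = 0 (possible on tiny, regular or saturated graphs) is flagged
(`degenerate_null`, z = NaN) rather than raised: a batch screen should not
die on one pathological drug.

### Known bias, and why ranks are the readout

When the real disease set is a *connected module* (as disease genes tend to
be), surrogate disease sets are scattered across the graph and cover it more
efficiently, so null distances run slightly short and even random drugs drift
to mildly negative z.  This is a property of the double-randomization design,
not of the implementation; the calibration test therefore draws *both* real
sets from the null (self-null), where mean(z) ≈ 0 and sd(z) ≈ 1 hold, and
the synthetic-study tests assert rank order between planted drugs rather
than absolute z levels.  Screening cutoffs applied to real data inherit this
conservatism toward proximity.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| `n_random` | 1000 | draws | full-scale convention; Monte-Carlo SE of z ≈ 1/√n_random |
| `min_bin_size` | min(100, ⌈n/20⌉) | nodes | degree-matching granularity vs within-bin sample size |
| broad cutoff | −0.15 | z | validated "proximal, plausibly pharmacologically active" threshold |
| strict cutoff | −2.0 | z | stringent shortlist (≈ 2 null SDs closer than chance); both cutoffs inclusive |
| significance `alpha` | 5×10⁻⁸ | p | genome-wide significance, strict inequality, per-record min(p) |
| relations | all four | — | enzymes/transporters/carriers count as targets by default, because published strict-cutoff candidates include drugs with only enzyme/transporter annotations; configurable |

Per-drug random streams are derived as `sha256(root_seed, drug_id) mod 2^31`,
so batch order and catalogue subsetting cannot change any drug's z.

## Curation rules

Records are retained when min(p) < α strictly — retention is per record, not
per SNP, because published locus tables print non-significant companion SNPs
inside retained loci.  HLA exclusion defaults to an explicit per-record flag:
a blanket 6p21 cytoband rule would wrongly drop non-HLA readthrough loci in
that band.  Labels split on `/` and `,` (configurable); parentheticals are
stripped; hyphens are preserved (readthrough symbols).  Unmapped and
duplicate genes are dropped with counts, not errors.

## Synthetic data: what it does and does not establish

`netprox.synthetic` generates (i) a connected scale-free-like graph —
Barabási–Albert growth (default) or a power-law configuration model, topped
up or reconnected to hit the requested size and mean degree; (ii) a
connected disease module grown by snowball sampling; (iii) drugs whose
targets are drawn from exact BFS rings around the module, so true d_c is
known by construction and re-verified by an independent BFS.  Defaults
(750 nodes, mean degree 4, module of 10, profiles from adjacent to 4 hops,
10 random background drugs) emulate the sparsity and degree heavy-tail of
curated interactomes at desk scale; 750 is the smallest round size whose BFS
rings reliably reach 4 hops at any seed, so every default profile is
plantable.  The generator does **not** emulate biological pathway structure,
annotation bias, edge confidence or literature ascertainment — a green
synthetic test establishes the statistical machinery (ranking, calibration,
determinism), not biological validity of any real screen.

The packaged fixture tables transcribe the published summary tables of the
motivating study verbatim (including typographical slips; see
`data/errata.md`).  Published per-drug z values are *inputs* from those
fixtures, never recomputed: reproducing them would need the full external
interactome and drug database, which are out of desk scope.  The two input
screens behind the cross-disease overlap were not published; they are
reconstructed from the overlap table plus text-quoted values, labelled
synthetic, and only their verbatim parts (names, z, counts) are asserted.

## Numerical choices and degenerate inputs

- Unreachable target→disease pairs are excluded from the d_c mean (with the
  drug flagged and a warning), not given a sentinel distance — sentinels
  would let an arbitrary magnitude dominate the mean.  Consequence: d_c
  monotonicity under edge addition is guaranteed only within a connected
  component.
- Largest-component ties break toward the component containing the
  lexicographically smallest gene symbol (deterministic preprocessing).
- Duplicate edges, reversed duplicates and (optionally) self-loops collapse
  on load; gene symbols are uppercased and stripped; no alias resolution.
- Screen tables sort by (z, drug_id) so ties cannot reorder between runs.
- Restricting the analysis to the largest connected component is an explicit
  switch (`RunConfig.restrict_to_lcc`, default on): whether the published
  analysis did so is not stated, and the package makes the choice visible
  rather than silent.

## Limitations

- z values depend on the binning and n_random; published values are matched
  through fixtures only (the published randomization settings are not
  stated).
- No directionality: a proximal drug may worsen rather than improve disease;
  the down-regulation classifier is a heuristic over action strings.
- Gene symbols must already be harmonized between interactome, disease set
  and catalogue; no identifier mapping is attempted.
- The empirical null gives a z, not a p-value; alternative proximity
  measures (shortest, centre, kernel, separation) are out of scope.
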