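# epletclust

Clustering of anti-HLA class II antibody responses from single-antigen-bead
(SAB/Luminex) assays, and nomination of the *driver eplets* — the shared
antibody targets that explain why responses against groups of HLA alleles
rise and fall together.

## The problem

Anti-HLA antibodies recognise *eplets*: small patches of polymorphic surface
residues that many HLA alleles share. Because of this sharing, a patient
sensitized against one allele typically reacts against a whole cluster of
alleles carrying the same eplet — cross-reactivity that matters for donor
selection in organ transplantation. Given a cohort's patients × beads matrix
of raw Mean Fluorescence Intensities (MFI), this package asks: which eplets
best explain the observed clusters of correlated responses?

The pipeline, per locus group (DRB, DQ, DP):

1. **Standardize** the raw MFI matrix X (patients × beads): center each bead
   column and scale to unit sample SD. No positivity threshold is applied.
2. **Ordinate** by PCA on the correlation matrix (via SVD of the
   standardized matrix; λₖ = sₖ²/(n−1)), exporting eigenvalues, scores,
   loading arrows (eigenvector columns scaled by √λₖ) and cos² qualities —
   the contents of a biplot.
3. **Cluster antigens**: each bead's standardized column is an
   antigen-specific feature vector; pairwise Minkowski distances
   dᵢⱼ = (Σₜ|xᵢₜ−xⱼₜ|ᵖ)^(1/p) (default p = 2) feed Ward's minimum-variance
   agglomeration (Lance–Williams on squared dissimilarities, unsquared
   heights), giving a dendrogram that can be cut into k response groups or
   replaced by an explicit group file.
4. **Nominate drivers**: each group's allele set is the union of its beads'
   alleles (both chains for DQ/DP heterodimer beads). An eplet is
   *group-exclusive* when every tested allele expressing it sits inside one
   group. Exclusive eplets carried by fewer than 2 tested alleles, or with a
   Low/Very Low ElliPro accessibility category, are flagged off; the rest
   are the nominated drivers.

A synthetic-cohort generator inverts the logic — patients are sensitized to
eplets, and every bead carrying a targeted eplet lights up together — so the
whole stack is testable against ground truth without patient sera.

## Worked example

```sh
python examples/nominate_dr_drivers.py
```

prints, from the packaged DR reference fixtures:

```
group-exclusive eplets: 32 of 123 DR eplets
excluded single-allele: 8
excluded low/very-low ElliPro: 5
retained drivers (19): 108T, 11STS, 142M, 30C, 30G, 31FH, 37L, 37S, 48Q, 57A, 57DE, 70QQ, 71A, 74R, 77N, 96EV, 96HK, 96Y, 98Q
chain attribution: {'alpha': 0, 'beta': 19}
```

Of the 123 DR eplets, 32 are confined to a single one of the three DR
response groups; 8 of those sit on only one tested allele (so cannot explain
a multi-bead cluster) and 5 more are poorly antibody-accessible, leaving 19
eplets nominated as the drivers of the clustered anti-DR response — all on
the β chain, as expected for DR. `examples/simulate_and_recover.py` runs the
full pipeline on a synthetic block-design cohort (ARI, recall and precision
all 1.000 at the default parameters), and `examples/ordination_and_tree.py`
shows the ordination/dendrogram stack on a simulated cohort.

There is also a thin CLI for shell use:

```sh
hla2 simulate --locus DR --registry <registry.csv> --panel <panel.csv> \
     --n-patients 200 --seed 1 --out sim/
hla2 run --locus DR --registry <registry.csv> --panel <panel.csv> \
     --mfi sim/mfi.csv --k 3 --out results/
```

`hla2 run` writes `pca_summary.csv`, biplot tables, the distance matrix, the
dendrogram as Newick, the group assignment, the driver report
(CSV + JSON) and a machine-readable run summary.

## Layout

- `src/epletclust/` — `registry`, `panel`, `ordination`, `clustering`,
  `nomination`, `simulate`, `pipeline`/`cli`, and packaged fixtures under
  `data/`
- `examples/` — one short narrative script per capability
- `tests/` — unit, property and acceptance suites
- `docs/methods.md` — the model, its assumptions, parameters and limitations
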