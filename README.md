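# structmap

Structural characterisation of serine/threonine post-translational
modification sites — built around O-GlcNAcylation, the attachment of a
single β-N-acetylglucosamine to intracellular S/T residues by the
transferase OGT.  Unlike phosphorylation, most O-GlcNAc sites show no
clear sequence motif, so the natural question is whether recognition is
encoded in local three-dimensional structure instead.  `structmap` gives
structural biologists and PTM bioinformaticians a tested pipeline to ask
that question of any S/T site catalog:

* build modified / unmodified / background site sets from site tables and
  FASTA sequences, keeping unique 7-residue motifs;
* map sites onto X-ray structure chains (residue-level SIFTS-style tables
  first, Smith–Waterman alignment with Karlin–Altschul E-values for the
  rest) and annotate missing-residue (REM465) status, DSSP secondary
  structure, relative solvent accessibility and Cα B-factor z-scores;
* superimpose the 7-residue windows around each site (Kabsch, 7 Cα + the
  central Cβ), cluster the pairwise RMSD matrix by complete linkage, and
  compare the cluster count with a bootstrap null of windows centred on
  unmodified S/T from the same chains;
* compute per-offset sequence relative entropy and predicted-disorder
  log-odds profiles against background sets.

## Core quantities

For corresponded window atoms x, y the superposition RMSD is
min over rotations R and translations t of √(Σᵢ‖R xᵢ + t − yᵢ‖²/n),
solved in closed form by SVD with the proper-rotation (det +1) sign
correction.  Complete-linkage clustering cut at 3 Å guarantees every
cluster has diameter ≤ 3 Å.  Enrichment of modified sites in a binary
structural state is the sample odds ratio of the 2×2 table with Fisher's
exact p; proportions are compared with pooled two-proportion z-tests and
Wald intervals.  The per-offset sequence information is the
Kullback–Leibler divergence Rᵢ = Σₐ p̂ₐᵢ log₂(p̂ₐᵢ/qₐ) in bits
(pseudocount 0.5), and disorder enrichment at offset d is
log₁₀ of the odds ratio of predictor-thresholded disorder calls between
target and background sites.

## Worked example

Enrichment of modified sites in crystallographically missing (REM465)
regions, from a 2×2 table of site counts:

```python
>>> from structmap.stats import ContingencyTable2x2, fisher_exact_or
>>> odds, p = fisher_exact_or(ContingencyTable2x2(26, 117, 553, 4258))
>>> print(f"REM465 enrichment: OR = {odds:.2f}, Fisher p = {p:.3f}")
REM465 enrichment: OR = 1.71, Fisher p = 0.024
```

Modified S/T here are 1.7× more likely than background S/T to fall in
regions missing from the crystal model — a proxy for structural disorder.

An end-to-end structural run on a synthetic bundle with planted ground
truth (12 chains, 24 sites drawn from 3 backbone motif templates, one
missing region per chain):

```python
>>> from structmap.synthetic import SyntheticSpec, generate_structure_set
>>> from structmap.pipeline import RunConfig, run_structural_analysis
>>> generate_structure_set(SyntheticSpec(n_proteins=12,
...                        n_modified_per_protein=2, seed=7), "bundle/")
>>> rep = run_structural_analysis("bundle/", "out/",
...                               RunConfig(bootstrap_reps=200, seed=1))
```

prints per-stage counts and reports

```
mapped: 24 backbone-complete: 24
clusters: 3 clustered: 24 singlets: 0
bootstrap 95% interval: [3, 6] (pool 126)
```

— all 24 planted sites map onto their chains, every window has a complete
backbone, and complete-linkage clustering at 3 Å recovers exactly the 3
planted templates.  The bootstrap interval is the range of cluster counts
expected from unmodified S/T windows of the same chains.  Output CSVs
(`cluster_assignments.csv` with columns `PDB,Chain,Position,Cluster,RSA,SS`,
`rem465.csv`, `ss3_proportions.csv`, `rsa_bins.csv`, `bootstrap_null.csv`)
carry the full configuration fingerprint in their header line.

The same pipeline is scriptable from the shell:

```sh
structmap synth --out bundle --n-proteins 12 --seed 7
structmap all bundle --out reports --seed 1
```

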