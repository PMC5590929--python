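# Methods

## Site catalogs

A site is a (protein accession, 1-based position, S/T) triple with its
7-residue flank (offsets −3…+3).  Flank positions beyond the termini are
padded with `-` rather than the site being excluded; exclusion is
available (`filter_unique_motifs(drop_padded=True)`) but padding is the
default so that terminus-proximal sites stay in the sequence-space
analyses.  Motif uniqueness keeps the first occurrence of each distinct
7-mer in stable input order.  The unmodified background of a catalog is
every S/T position of the same proteins that carries no modification.
For length-capped predictors, `trim_for_predictor` centres a window
(default 800 residues) on the site and shifts it to fit the sequence,
which keeps the site at least the margin (default 100 residues) away from
both termini whenever the sequence allows.

## Structure model

Chains are parsed with gemmi from PDB or mmCIF.  The construct sequence
comes from the sequence records (SEQRES / entity_poly); coordinate-less
positions are flagged as missing (REM465), the standard proxy for
structural disorder in crystal models.  Window indexing is in construct-
sequence space, so missing residues occupy their window slots and windows
spanning them are incomplete; author numbering is carried for reporting.
Eligibility follows the usual quality gate: X-ray structures at ≤ 2.50 Å
with chains longer than 30 residues.  Only the first model of multi-model
files is used; alternate locations resolve to the highest-occupancy
conformer; modified residues map through the standard chemical-component
table, with unmappable residues becoming `X` (never matching S/T).

Cα B-factors are z-scored per chain with the population standard
deviation (for chains of > 30 residues the sample/population distinction
is negligible; the choice is recorded here and in the output headers).
Zero-variance chains get all-zero scores with a warning.

## Secondary structure and accessibility

DSSP output files are parsed when supplied — the package never executes
DSSP.  The 8-state to 3-state reduction is G,H → H; I,B,E → E; all other
states including unassigned → C.  Mapping π-helix (I) to strand is
unusual relative to common practice but is applied as stated; it affects
almost no residues.  Relative solvent accessibility divides the DSSP
accessible area by the residue-type maximum; the default scale is the
Tien et al. (2013) theoretical maxima with the Miller et al. (1987)
empirical scale selectable, and the scale name is part of the
configuration fingerprint because the buried-site count is sensitive to
it.  Burial bins are buried (RSA ≤ 0.05), partially buried
(0.05 < RSA ≤ 0.25) and exposed (RSA > 0.25), both cut-offs inclusive on
the buried side.

Without DSSP, two geometric fallbacks annotate chains and are labelled as
non-DSSP in outputs.  Accessible surface area is computed by
Shrake–Rupley sphere sampling with a deterministic golden-spiral point
set (default 960 points, probe 1.4 Å) over the available heavy atoms; its
quadrature error is first-order in the point count (~1.2% per residue at
960 points on helical test fixtures, halving per doubling).  Because
synthetic chains carry backbone atoms only, fallback RSA values can
exceed 1 against full-residue maxima; they are kept and logged.  The
3-state dihedral assigner calls a residue H (E) when its own φ/ψ and both
neighbours' fall in the helical (φ ∈ [−100°, −30°], ψ ∈ [−80°, −5°]) or
extended (φ ∈ [−180°, −40°], ψ ∈ [90°, 180°]) region, and C otherwise,
including termini and residues flanking chain breaks.

## Mapping sites to chains

Residue-level mapping tables are used first; alignment covers the
remainder.  The aligner is Smith–Waterman with BLOSUM62 and affine gaps
(open 11, extend 1), matching common BLAST defaults, and scores convert
to E-values via the Karlin–Altschul formula (λ = 0.267, K = 0.041, the
gapped BLOSUM62-11-1 parameters).  The default E-value gate is 1e-25; it
is a configurable conservative default.  User-supplied BLAST tabular
output (outfmt 6) is accepted and takes precedence over the built-in
aligner.  A candidate survives only if the aligned column covers the site
without a gap and the chain residue equals the site residue.  Selection
is deterministic: table candidates outrank alignment candidates, highest
coverage wins among table hits, lowest E-value among alignment hits
("highest E-value" in the selection rule is read as best, i.e. lowest
numeric, since preferring worse hits would contradict a conservative
gate), and exact ties resolve to the lexicographically smallest
(pdb, chain).

## Window superposition and clustering

A site window holds 8 superposition atoms: the 7 Cα and the central
residue's Cβ (the Cα of the central residue is counted once).  Windows
are backbone-complete when all 7 residues are observed with N, CA, C and
the central Cβ is present — glycine-centred background windows are
incomplete by definition when the Cβ is required.  Pairwise RMSD is the
Kabsch/SVD solution with the determinant sign correction so reflections
are never allowed; the implementation applies the optimal rotation
explicitly rather than using the trace formula, which avoids ~1e-8 Å
cancellation error.  Degenerate (collinear) point sets remain defined.

Complete-linkage clustering of the RMSD matrix is cut at 3 Å with merges
at height ≤ the threshold kept (boundary ties on float RMSDs are
vanishingly rare); the linkage choice guarantees every reported cluster
has maximum pairwise RMSD ≤ 3 Å, which the tests assert directly on the
matrix.  Size-1 clusters are reported as singlets.  Cluster labels A, B,
… are assigned by descending size, then lexicographically smallest first
member.  Per-cluster consensus secondary structure is a per-offset
plurality vote with ties (and all-abstain offsets) going to C.

The bootstrap null resamples n windows (n = number of backbone-complete
modified windows) with replacement from the pool of windows centred on
unmodified S/T of the same chains, clusters each replicate identically
and records the multi-member cluster count; 1,000 replicates by default
with a 2.5/97.5 percentile interval.  Replicate RMSDs are gathered from
the precomputed pool matrix, and one seed drives independent
per-replicate substreams, so runs are reproducible and replicates
independent.

## Enrichment statistics and profiles

* 2×2 enrichment: sample odds ratio (a·d)/(b·c) with the Haldane +0.5
  correction only when a cell is zero (flagged), two-sided Fisher exact
  p-value.
* Proportions: pooled-variance two-proportion z-test (the pooled variant
  reproduces the published predicted-SS p-values; the published
  DSSP-table p-values are reproduced by neither pooled nor unpooled
  variants, so both are recomputed and reported rather than tuned to
  match) and Wald 95% intervals clipped to [0, 1].
* Scores: Welch t-test or Kruskal–Wallis, with means ± standard errors.
* Relative entropy per offset: KL divergence in bits with pseudocount 0.5
  per amino acid; gap-padded positions are excluded from counts.  The
  confidence band is a percentile bootstrap over sites (200 resamples by
  default), widened minimally where the point estimate falls outside the
  percentile band at degenerate offsets.
* Disorder profiles: a residue is disordered when its predictor score is
  at or above the method threshold (inclusive; the published cut-offs are
  stated without an inequality direction).  Defaults per method:
  DisEMBL-REM465 0.6, DisEMBL-COILS 0.516, DisEMBL-HOTLOOPS 0.1204,
  IUPred-Long 0.5, IUPred-Short 0.5, JRonn 0.5.  Per offset the log₁₀
  odds ratio between target and background sites gets a Haldane
  correction for zero cells and a Wald 95% band on the log-odds scale.
  The profile half-width defaults to 50 residues.
* No multiple-testing correction is applied; raw p-values are reported.

Re-implementing the disorder and secondary-structure predictors
themselves is out of scope: their scores are consumed as input tracks.

## Synthetic data

The generator emulates the study conditions end to end with planted
truth.  Backbones are built by sequential internal-coordinate placement
with Engh–Huber ideal bond lengths and angles and trans peptide bonds;
per-residue (φ, ψ) come from a six-state alphabet (helix, strand,
left-handed helix, extended-glycine, polyproline II, bridge-like).  Six
7-residue motif templates were chosen for mutual separation — minimum
pairwise window RMSD 3.2 Å, safely above the intra-template spread at the
default coordinate noise of 0.3 Å per coordinate — so complete linkage at
3 Å separates them cleanly.  Chains carry SEQRES records, planted missing
regions (the REM465 truth), lognormal B-factors (median 20 Å², σ = 0.3 in
log-space, a typical crystallographic spread) and a nominal 2.0 Å X-ray
annotation.  Synthetic ids use the letter-first namespace `s001…`, which
cannot collide with real PDB codes.

Disorder tracks draw per-residue scores so that P(score ≥ threshold)
equals p_in = 0.6 within ±15 residues of a site and p_out = 0.3
elsewhere, giving a planted offset-0 log₁₀ odds ratio of
log₁₀[(0.6/0.4)/(0.3/0.7)] ≈ 0.544.  Sequence-arm bundles additionally
plant coil enrichment at site positions in the 3-state prediction track.

What the synthetic data does not emulate: side chains and packing (only
backbone + Cβ atoms exist, so fallback RSA is relative to full-residue
maxima), crystal contacts and altloc/insertion-code pathologies, real
coil conformational statistics, sequence-composition biases and
homology between proteins.  Passing tests therefore demonstrate the
correctness of the machinery — parsing, mapping, superposition,
clustering, statistics — under controlled truth, not biological claims
about real catalogs.

## Problem sizes and numerical choices

The default test and acceptance runs use scaled-down problem sizes chosen
to exercise every code path with comfortable statistical margins: 12-24
synthetic chains of 120 residues, 120-window clustering sets, 100-500
replicate checks, bootstrap nulls of 25–200 replicates in tests (1,000 by
default in production runs), and disorder studies of 300 target / 600
background proteins of 301 residues.  Tolerances: superposition is
checked against an independent rotation-search minimiser to 1e-3 Å;
B-factor z-scores to 1e-9; the entropy identity to 1e-9; percentile
bands at the conventional 95%.  All randomness flows from a single seed
per run through spawned substreams.

## Known limitations

* The built-in aligner computes one best local alignment per
  (protein, chain) pair; multiple HSPs per pair come only through
  user-supplied BLAST tabular input.
* Karlin–Altschul parameters are fixed at the gapped BLOSUM62-11-1
  values rather than estimated per scoring system.
* The fallback accessibility path scores only the atoms present in the
  model; for backbone-only models RSA is meaningful comparatively, not
  absolutely.
* Biological assemblies, symmetry mates and ligands are out of scope;
  burial is assessed on the single chain.
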