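# Methods

## Problem and data model

A conditionally folding segment (Protean Segment) is a region of an
intrinsically disordered protein with experimental evidence of disorder
in isolation and of order in complex. The package compares the
experimental (in-complex) conformation of each segment with the
corresponding region of a predicted *monomeric* model and asks which
structural and sequential properties distinguish well-predicted from
poorly predicted segments.

Inputs are (a) experimental structures in PDB/mmCIF, (b) predicted
models in PDB format with per-residue confidence (pLDDT, 0–100) in the
B-factor column, and (c) a segment table giving, per segment, the
UniProt accession, the region in 1-based inclusive UniProt numbering,
the experimental chain and partner chains, and file references.

Model residue numbering is taken as UniProt numbering (the AlphaFold DB
convention). Experimental author numbering is never trusted: the
model-to-experiment correspondence is always established by global
pairwise sequence alignment (identity scoring, affine gaps), restricted
to region residues with a Cα on both sides; an alignment identity below
0.9 over the region is treated as a wrong-chain error. Nonstandard
residues are mapped to their parent amino acid by a fixed lookup
(MSE→M etc.); unmapped residues become `X`, which is retained for
geometry but excluded from composition. Multi-model (NMR) files
contribute their first model only. Altloc copies are resolved to the
highest occupancy, ties to the first identifier.

## Features

* **RMSD** — Cα RMSD over mapped region residues after least-squares
  optimal superposition (Kabsch via SVD, proper rotation enforced). All
  mapped residues enter the fit; no fragment or iterative trimming.
* **pLDDT** — arithmetic mean of per-residue confidence over the region,
  one value per residue read from the Cα B-factor of the model.
* **nRG** — radius of gyration of the experimental region's Cα trace
  (unweighted) divided by N^(1/3). A compact globule has R_g ∝ N^(1/3),
  so nRG measures compactness independent of length. The convention was
  validated by reproducing the published long-helix example: an ideal
  33-residue α-helix trace gives nRG ≈ 4.5–4.7, within 10% of the
  printed 4.40, while N^(1/2) normalisation does not come close.
* **mrASA / crASA** — per-residue solvent accessible surface area from
  an in-package Shrake–Rupley implementation (probe 1.4 Å, 960-point
  deterministic golden-spiral lattice per atom, standard van der Waals
  radii, hydrogens/waters/ligands excluded), divided by the residue's
  theoretical maximum (Tien et al. 2013) and averaged over the region.
  Monomeric context isolates the segment chain; complex context adds the
  declared partner chains. ΔASA (region area lost on adding partners)
  below 1 Å² is treated as "no contact" — that tolerance absorbs
  quadrature noise. Doubling the lattice changes totals by < 0.5%, and
  an isolated atom reproduces its analytic sphere area to < 1%.
* **%Helix / %Strand / %Coil** — an in-package DSSP-style assigner:
  amide hydrogens rebuilt anti-parallel to the preceding carbonyl,
  Kabsch–Sander hydrogen-bond energy
  E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) with a −0.5 kcal/mol
  cutoff, n→n+4/3/5 turn patterns for H/G/I, bridge patterns for E/B,
  remaining turn residues T. Three-state collapse: helix = {H} (the
  analysis concerns α-helix; 3₁₀ and π count as coil), strand = {E, B},
  coil = the rest, so the three fractions always sum to 1. On an ideal
  helix the assignment matches an independent DSSP implementation
  residue for residue.
* **Composition** — fractions of the 20 standard residues over the
  model-sequence region (composition is a sequence property, so the
  complete sequence is used rather than the possibly gapped experimental
  chain), plus polar {G,N,P,Q,S,T} and hydrophobic {A,C,I,L,M,V} group
  sums. The implemented battery (31 features: 20 residues, 2 group sums,
  3 secondary-structure fractions, mrASA, crASA, nRG, pLDDT, length)
  covers every feature the downstream analysis selects; homology counts
  are out of scope because they require a sequence-database search.

## Statistics

* **Classification** — excellent iff RMSD ≤ b₁, poor iff RMSD ≥ b₂
  (both inclusive, as printed), else average; defaults b₁ = 1.76 Å,
  b₂ = 4.13 Å. Boundary re-optimization does a grid search over
  midpoints of adjacent observed RMSDs (quantile-thinned to ≤ 40
  candidates to keep the search tractable), requires every class to hold
  ≥ 20% of segments, maximizes the number of features with
  p(excellent vs poor) < 0.01, and breaks ties by the smallest summed
  log₁₀ p. This objective is the package's own reconstruction of
  "boundaries making the classes most distinctive under the U-test";
  fixed published boundaries are available whenever comparability
  matters.
* **Mann–Whitney U** — two-sided, midrank ties; exact enumeration when
  both samples are ≤ 8 without ties, otherwise normal approximation with
  tie and continuity corrections (SciPy). Verified against a full
  enumeration oracle for every size pair up to (8,8).
* **Selection** — raw p < 0.01 excellent vs poor, no multiple-testing
  correction (the screen is reported as raw p-values by design).
* **Regression** — OLS with intercept; rows whose *true* RMSD exceeds
  7 Å are excluded as outliers before fitting (an outcome-based rule,
  not residual-based, matching how the outliers were identified);
  classical t-values; R² and Pearson r of fitted vs true reported on the
  rows used. Rank-deficient designs raise an error naming the collinear
  columns; the pipeline pre-prunes exactly collinear features (this
  matters for degenerate cohorts, e.g. all-helix/all-coil data where
  %Strand ≡ 0 makes %Coil = 1 − %Helix).
* **Feature grouping** — features negated when negatively correlated
  with RMSD, distance d = 1 − r (range 0–2; signed, not |r|), Ward
  linkage, tree cut at the root into two groups. Group 1 is defined as
  the cluster containing the feature with the largest |r| against RMSD —
  a deterministic labeling that reproduces the confidence-led group
  being "group 1" in the reference analysis.
* **Segment groups** — with the fitted model, RMSD_1 zeroes the group-2
  coefficients (intercept kept) and RMSD_2 zeroes group 1; a segment is
  group 1 iff |RMSD_all − RMSD_2| > |RMSD_all − RMSD_1|, ties to
  group 2 (strict inequality for group 1).

## Synthetic data

The generator emulates the archetypes observed among conditionally
folding segments. Backbones (N, Cα, C, O) are built from internal
coordinates (NeRF; ideal bond lengths/angles, trans peptide) with
per-archetype φ/ψ schedules: long helix (−57°, −47°), extended coil
(φ ∈ U(−150°, −90°), ψ ∈ U(100°, 160°) — stiff, extended statistics),
short helix with ~30% coil termini, and a helix-turn-helix "domain-like"
hairpin; self-clashing chains are resampled with bounded retries.
Sequences are uniform over the standard residues except proline (no
amide hydrogen, which would fray generated helices).

The "experimental" copy adds an independent Gaussian displacement per
residue (σ = `noise_sigma`, same offset for all atoms of a residue, so
local geometry survives small σ), giving a superposed RMSD of
≈ σ√3·√(1 − 3/N). A 20-residue partner helix is placed alongside the
segment, iteratively translated to a minimum interchain heavy-atom
distance of ~4 Å (contact mode; guarantees ΔASA > 0) or parked 60 Å
away. The model copy stays ideal and carries pLDDT = clip(mean + N(0, 3))
per residue.

The two-condition cohort (`gen_study`, 20 + 20 segments) fixes the study
conditions: well-predicted segments as 33-residue long helices with
σ = 0.5 Å and planted pLDDT 85 (expected RMSD ≈ 0.8 Å, clearly
excellent), poorly predicted segments as 20-residue extended coils with
σ = 4 Å and pLDDT 55 (expected RMSD ≈ 6.5 Å, clearly poor, with a tail
beyond the 7 Å outlier threshold so the outlier rule is exercised).
σ = 4 Å was chosen so the poor condition sits well above the 4.13 Å
boundary rather than on it; the pLDDT means mirror the observation that
well-predicted segments carry high confidence. Problem sizes throughout
(40-segment cohort; n = 150 rows for planted regression tables; 100
seeds for recovery suites) were chosen as the smallest sizes at which
the estimators' standard errors are far below the effects being
recovered.

Feature tables plant a linear RMSD model on multivariate-normal features
with block-diagonal correlation (Cholesky; non-positive-definite
requests are rejected). The grouped variant gives each item one active
feature block (unit variance) and one near-constant block
(σ = 0.02 ≪ 1), so "RMSD depends only on one block" is unambiguous: the
analytic misassignment rate 2/π·atan(0.02√6/√5) ≈ 1% makes per-seed
recovery ≥ 90% robust rather than borderline.

What the synthetic data does *not* emulate: side chains beyond the
backbone (so absolute rASA values are backbone-referenced), strand
pairing and β-sheet partners, sequence–structure coupling (composition
is independent of archetype), and the messy partner geometry of real
complexes. Passing tests therefore demonstrate the correctness of the
measurement and statistical machinery under known ground truth, not
predictor performance on real proteins; the per-segment checks against
the four published example segments (long helix, domain, short helix
with loops, extended segment) cover the real-data path and require the
original structure files, fetched by `scripts/fetch_worked_examples.py`.

## Numerical choices and degenerate inputs

Superposition requires ≥ 3 points; collinear inputs still return a valid
proper rotation via the SVD sign convention. RMSD/oracle agreement is
held to 1e-9. The SASA lattice is deterministic, so feature extraction
is bitwise reproducible. Chains shorter than 4 residues are all-coil; a
chain break (C–N > 2.5 Å) suppresses hydrogen reconstruction across the
break. Mann–Whitney on identical samples returns p ≈ 1; empty samples,
empty regions, empty atom selections, all-`X` sequences, constant
features and rank-deficient designs raise typed errors naming the
offender. Filtering is order-independent; redundancy clustering is
greedy single linkage with deterministic representatives (longest
segment, then lexicographic accession).

## Known limitations

* The boundary-optimization objective and the exact nRG/rASA
  conventions are reconstructions of procedures whose full definitions
  live in the study's appendices; the printed per-segment values are the
  validation anchor for the choices made here.
* The SASA reference differs from DSSP's algorithm; relative values are
  treated as reproducible to ±0.05.
* BlastClust is replaced by alignment-based single-linkage clustering
  with the same thresholds; cluster compositions can differ from BLAST's
  local-alignment semantics in edge cases.
* The aggregate published statistics (class counts, R², Table-1
  coefficients) depend on the full IDEAL + AlphaFold DB snapshot and its
  supplementary feature table, which are not redistributable here; the
  corresponding checks run only when those inputs are provided.
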