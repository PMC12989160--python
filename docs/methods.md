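# Methods

This note records the modelling choices behind `missdriver`: what each stage
computes, the defaults and why, what the synthetic generator does and does
not emulate, and the numerical details a maintainer would otherwise have to
reverse-engineer.

## Problem setting

A missense mutation is described by (protein, position, wild-type residue,
mutant residue, cancer type, sample count). Drivers are the positive class.
When labels are not given explicitly, a mutation recurring in ≥ 3 samples is
labelled a driver; existing passenger labels are never overwritten by the
recurrence rule. Positions are 1-based throughout the public API, matching
mutation nomenclature (R175H).

## Feature families

**Physicochemical deltas.** For each AAindex1 property table P, the feature
is ΔP = P(mut) − P(wt). The reference configuration uses a large
physical/chemical/energetic/conformational property set; the list is
configuration, not a constant — any AAindex-format file can be loaded. One
property (Kyte–Doolittle hydropathy) ships with the package so examples and
tests run self-contained. ΔP is antisymmetric in (wt, mut) by construction.

**Substitution matrices and contact potentials.** Each configured AAindex2
matrix contributes its (wt, mut) cell directly; matrices may be asymmetric.
Each AAindex3 contact potential contributes three values: CP(left, mut) −
CP(left, wt), CP(right, mut) − CP(right, wt), and CP(left, right) — the
pairing of the two flanking residues themselves. A terminal position yields
a missing value for the absent side, never zero, because zero is a valid
potential.

**Window composition.** The 20 residues partition into six side-chain
classes — aliphatic {G,A,V,L,I,P}, sulfur {C,M}, aromatic {F,W,Y}, polar
{S,T,N,Q}, positive {K,R,H}, negative {D,E} — and the feature vector counts
each class among the 12 window neighbors (flank 6 on each side, site
excluded, truncated at termini). The partition covers all 20 residues so
the counts always sum to the in-bounds window size.

**Gapped motif odds.** Seven pattern families pair the mutation site with
one or two neighbors at fixed offsets: (0,+1), (−1,0), (0,+4), (−4,0),
(0,+5), (−1,0,+1), (−1,0,+5). For each concrete motif string realized at
training driver vs passenger sites, the stored odds is
((n_D + c)/(N_D + c)) / ((n_P + c)/(N_P + c)) with Haldane–Anscombe
pseudocount c = 0.5, so zero counts never divide by zero. At prediction
time an unseen or unrealizable motif (e.g. a terminal site for a
left-anchored family) scores 1.0, the odds-neutral value. The family
offsets and pseudocount are configurable. Motif tables must be fitted on
training data only; fitting them on a full corpus and then cross-validating
is leakage, and the grouped-split evaluation in `scripts/acceptance.py`
refits them on the training side of the split.

**PSSM features.** Three values per site from the PSI-BLAST ascii profile:
the mean over the in-bounds 13-residue window of each position's log-odds
score for its own native residue; score(pos, mut) − score(pos, wt); and
score(pos, wt).

**Tracks.** Every per-residue track (18 conservation methods, one disorder
track) contributes its site value and the nan-aware window mean. Missing
values stay nan until the imputation step.

**Structure.** Per residue: pLDDT (mean B-factor over the residue's atoms —
exact for AlphaFold files, which repeat the value per atom); Shrake–Rupley
accessible surface area; relative ASA normalized by the Tien et al. (2013)
theoretical maxima and clipped to [0, 1]; 3-state secondary structure
(DSSP 8-state collapsed as {H,G,I}→H, {E,B}→E, rest→C, one-hot encoded);
residue depth; and the number of residues with ≥ 1 atom pair within 7 Å,
excluding |Δresidue| ≤ 1 to suppress trivial backbone contacts. With
multiple structural models per protein, features are averaged per residue
across models; residues present in only some models are averaged over those
and flagged.

**Network.** The contact network has residues as nodes and an edge wherever
any atom pair lies within 7 Å, weighted by the number of such pairs. Four
per-residue centralities are exported: closeness (Wasserman–Faust form, so
nodes in different components remain comparable; an isolated node scores
0), betweenness normalized by (n−1)(n−2)/2, eigenvector centrality, and
weighted degree. Shortest paths use unit edge lengths; weights enter only
the eigenvector and degree measures.

## Numerical choices

- **Shrake–Rupley quadrature**: each atom's probe-expanded sphere (van der
  Waals radius by element + 1.4 Å probe) is sampled with a deterministic
  golden-spiral lattice of 960 points; a point survives if outside every
  neighbor's expanded sphere. Points exactly on a coincident neighbor's
  sphere are kept by the lower-index atom only, so shared surface is counted
  once. The retained points are the accessible surface.
- **Residue depth** is the minimum distance from the residue's heavy-atom
  centroid to any retained surface point (surface-point-distance
  definition); an isolated residue therefore has depth ≤ r_atom + r_probe.
- **Eigenvector centrality** is computed by power iteration (tolerance
  1e-9, 10⁴ iteration cap, all-ones start, max-norm 1) on the weighted
  adjacency shifted by (max weighted degree)·I. The shift leaves the
  eigenvectors unchanged and makes the spectrum positive, preventing the
  oscillation that unshifted iteration exhibits on bipartite-like graphs.
- **Min-max normalization** is fitted on training rows only; test values
  outside the training range are clipped to [0, 1] with a warning; constant
  columns map to 0; one-hot columns pass through.
- **Missing features** are median-imputed with medians computed on training
  rows only.
- **Feature selection** ranks univariate scores (ANOVA F by default; mutual
  information and χ² available) in descending order with ties broken by
  column name, so selection is deterministic. A nan score never ranks; an
  infinite score (perfect separation) ranks first. The K sweep picks the K
  maximizing mean CV balanced accuracy, smallest K on ties.
- **Splits**: the 80:20 split stratifies by label with largest-remainder
  rounding of per-class test counts; the protein-grouped split assigns whole
  proteins to one side, shuffling proteins by seed and filling the test side
  to the 20% mutation target best-effort.
- **Classifier**: ReLU hidden layers with He-normal initialization, a single
  sigmoid output unit (mathematically equivalent to a two-way softmax
  head), binary cross-entropy with an L2 penalty λ·Σ‖W‖², mini-batch SGD
  with momentum. Defaults: layers (64, 32), lr 0.01, momentum 0.9,
  λ = 1e-4, batch 32, ≤ 500 epochs, early stopping (patience 10) on the
  loss of an internal stratified 10% validation split with restoration of
  the best checkpointed weights. All randomness (initialization, batch
  order, validation split) flows from one integer seed; identical seeds
  give bit-identical weights. A non-finite loss aborts with a diagnostic
  rather than returning a silently broken model.
- **Metrics**: sensitivity, specificity, accuracy, balanced accuracy and
  MCC are computed exactly from the confusion counts (MCC = 0 when any
  denominator factor vanishes); ROC-AUC is the trapezoidal rank statistic
  and PR-AUC the step integration of the precision–recall curve;
  single-class truth leaves the AUCs flagged as undefined rather than 0.
  Cross-validation reports per-fold metrics and their mean (counts summed,
  rates averaged), so both per-fold-averaged and pooled views are
  available.
- **Prediction threshold** 0.5, boundary mapped to the driver class;
  configurable.
- **Class imbalance** is left as-is (no over/undersampling); balanced
  accuracy and MCC are reported precisely because of this.

## Mutation-preference statistics

Substitution preference is n_ij/N per class. The driver/passenger odds
ratio (n_D/N_D)/(n_P/N_P) carries an explicit flag instead of a number when
a substitution is class-unique (driver-unique → infinite odds flagged,
passenger-unique → 0 flagged); no continuity correction is applied here —
pseudocounts are used only where odds become model features. Motif
preference uses inclusive cutoffs: odds ≥ 1.2 → driver-preferred, ≤ 0.8 →
passenger-preferred. Composition differences use Fisher's exact two-sided
test on (residue vs rest) × (class vs class) tables; frequency intervals
use the Wilson score formula.

## Synthetic generator

The generator emulates the *statistical shape* of a recurrence-labelled
cancer mutation corpus, not biology:

- sequences are i.i.d. draws from a configurable residue frequency table
  (uniform by default);
- structures are idealized α-helices (rise 1.5 Å, 100°/residue, Cα radius
  2.3 Å, approximate backbone companions) with optional Gaussian jitter and
  synthetic pLDDT in the B-factor column;
- each protein carries a latent per-site score; driver sites are drawn
  where that score is high (shifted by the configured effect size, default
  d = 2), and the score feeds the conservation tracks (through a sigmoid),
  the disorder track (negated), the PSSM native-column scores and the
  pLDDT, so one planted contrast propagates into several feature families;
- a `motif_bias` fraction (default 0.5) of driver sites is constrained to
  carry a favored right-neighbor residue ({R,K,E}), and passengers a
  disfavored one. This plants a transferable motif signal; without it,
  motif odds on random sequences are pure training-set memorization, which
  is not how real corpora behave (real corpora show reproducible motif
  enrichment);
- sample counts are drawn so recurrence labelling at threshold 3
  reproduces the intended classes exactly; the default driver:passenger
  ratio is 2:1;
- all artifacts are written in the real external formats so every format
  reader is exercised end to end, and seeded runs are bit-reproducible.

What passing tests on this generator show: the pipeline recovers planted
multivariate signal, does not hallucinate signal from shuffled labels
(including under protein-grouped splits), and every reader/feature/metric
stage composes correctly. What they do not show: performance on real
COSMIC/ClinVar-derived corpora, whose feature correlations, redundancy
structure and label noise the generator does not model.

## Study sizes used in the shipped evaluations

The planted-signal evaluation uses n = 2000 mutations, 40 features with 5
planted at d = 2, K = 10 selected features, 10-fold CV, three seeds. The
file-backed corpus evaluation uses 40 proteins of 60–120 residues with 600
drivers and 300 passengers, a protein-grouped 80:20 split, motif tables
fitted on the training side, and K = 25. The corpus size is the smallest at
which sparse motif-odds estimates stop being dominated by counting noise;
structural quadrature there uses 240 sphere points per atom (the 960-point
default is kept wherever single structures are analyzed).

## Known limitations

- Single-chain models are assumed (true for AlphaFold monomers); multi-chain
  files contribute their first chain only.
- Secondary structure is taken from DSSP output when supplied; otherwise
  residues default to coil — the package does not re-derive hydrogen-bond
  assignments from coordinates.
- Microenvironment descriptor sets and interaction typing (H-bond/salt
  bridge classes) are out of scope; pLDDT, ASA, SS, depth and contacts are
  the structural families exported.
- The per-cancer-type hidden-layer sizes of a production deployment are a
  tuning matter; the defaults here are a sensible middle of the 1–5 layer
  range, and the config exposes every hyperparameter.
- Redundancy clustering of input proteins (40% identity) is documented as a
  data-preparation step but not re-implemented; the protein-grouped split
  addresses within-corpus leakage, not cross-protein homology.
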