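# Methods

This note records the models, numerical choices and known limitations behind
`rna-assess`, at the level of detail a maintainer needs to change them
safely.

## Scope and data model

Structures are ordered lists of residues (chain, author seq id, insertion
code) carrying heavy atoms only; hydrogens and waters are discarded on read.
Author numbering is authoritative throughout, matching how blind-prediction
submissions are keyed. Modified nucleotides are mapped to their parent base
(pseudouridine → U, 2′-O-methyl-G → G, …) via a built-in table; polymer
residues that map to neither an RNA parent nor an amino acid become
`kind="other"` and are excluded from RNA metrics. Alternate locations keep
the highest-occupancy atom, ties broken by altloc label order, so reads are
deterministic. Multi-model files (PDB `MODEL` blocks, multi-model mmCIF)
become ensembles; every metric can be evaluated against each reference
conformation, and the ranking layer takes the best value per group across
models and conformations.

Residue correspondence is fixed, never alignment-per-superposition:
`by_numbering` pairs identical (chain, seq id, icode) keys; `by_sequence`
falls back to a global alignment of one-letter sequences (match +1,
mismatch −1, gap −2, via Biopython's PairwiseAligner) for renumbered
models. Sequence-independent structural alignment is deliberately out of
scope.

## Metrics

**Superposition** is least-squares (Kabsch via SVD) with the proper-rotation
correction; fewer than three points or collinear inputs raise a degenerate-
input error rather than returning an arbitrary frame.

**GDT_TS** uses C4′ atoms and cutoffs 1/2/4/8 Å. The exact maximization of
in-cutoff fractions over all rigid motions is combinatorial, so the score is
defined by a documented search: seeds from the global superposition and
every contiguous window of 3, 5 and 7 pairs (plus, for chains of ≤10
residues, every 3-point subset), each seed refined for three rounds by
re-superposing on its cutoff inlier sets and on k-nearest-pair prefixes of
its distance ordering, keeping the five most promising refinements per
round. On small instances the search is tested to stay within one
percentage point of an exhaustive all-subset oracle; on ≤10-point inputs
the exhaustive 3-subset seeding makes it effectively optimal.

**TM-score** uses C3′ atoms, the fixed correspondence, and
`d0(L) = 0.6·√(L−0.5) − 2.5` with L the reference RNA length. The formula
goes negative below L ≈ 25, so d0 is floored at 0.3 Å; short-chain scores
are therefore conservative, and the worked example in the README shows the
consequence. The score is normalized by the reference length, so missing
residues in a model are penalized. The superposition search reuses the GDT
seed family, iterating inliers at d0 and d0/2 and keeping the maximal TM
sum; it is guaranteed by construction (and asserted in tests) to be at
least the single-global-superposition score.

**lDDT** is superposition-free: all heavy-atom pairs in distinct residues
within 15 Å in the reference, both atoms present in the model, scored as
the mean over {0.5, 1, 2, 4} Å of the fraction of pairs whose distance is
preserved within the threshold. No stereochemical penalty is applied, and
only corresponded residues are scored. The 15 Å radius is the protocol
value; the four thresholds follow the metric's standard definition.

**INF/DI/DP.** INF is √(PPV · TPR) over category-restricted edge sets of
annotated networks (WC, NWC, BPS = WC∪NWC, STACK, ALL); an empty reference
category yields an undefined (None) score, and DI = RMSD/INF is undefined
when INF is 0 or undefined — undefinedness is propagated, never silently
zeroed. The Deformation Profile superposes the model on the reference one
anchor nucleotide at a time (all heavy atoms of the anchor) and records the
base-atom RMSD of every other nucleotide without re-superposition; base
atoms are everything outside the sugar-phosphate name set. Anchors with
fewer than three matched atoms leave a NaN row, and summaries (sum, mean,
median) are taken over defined entries.

**Clashscore** counts heavy-atom pairs whose van-der-Waals spheres
(C 1.70, N 1.55, O 1.52, P/S 1.80 Å) overlap by more than 0.4 Å, excluding
pairs within three covalent bonds. Bonds are inferred from distance
(<1.8 Å intra-residue, plus O3′–P and peptide C–N linkages up to 2.1 Å).
Excluding up to 1–4 neighbors rather than only 1–3 is deliberate: aromatic
rings place 1–4 atoms at ~2.7 Å, which would otherwise count as clashes in
every correct nucleotide. The default denominator is 1000 atoms (MolProbity
convention); a per-1000-residues variant is available because both
conventions circulate in the RNA assessment literature.

**MCQ** is the arithmetic mean of circular distances
`min(|Δ|, 360−|Δ|)` over the seven standard torsions (α…ζ, χ) wherever
both structures define them; χ is O4′-C1′-N9-C4 for purines and
O4′-C1′-N1-C2 for pyrimidines. Missing atoms or chain termini yield
undefined angles, never exceptions.

## Base-pair and stacking annotation

The metrics only need the WC/NWC dichotomy plus stacking, so no
twelve-family edge classification is attempted. A pair requires: C1′–C1′
distance in [5, 14] Å ([8, 12] Å for the WC window), at least two
donor–acceptor contacts ≤ 3.4 Å between polar base atoms (donor/acceptor
roles from a per-base table), inter-plane angle ≤ 35°, and vertical plane
separation ≤ 2.5 Å. WC is assigned when the parent combination is AU, GC
or GU *and* at least two qualifying contacts use canonical WC-edge atoms
(N1/N3-centred sets); G·U wobbles therefore count as WC. Stacking requires
plane separation in [2.8, 5.5] Å, plane angle ≤ 30°, lateral centroid
offset ≤ 4.0 Å, and not already being a pair — so the three categories are
mutually exclusive by construction. All thresholds live in one
`AnnotationThresholds` object. These windows are this package's own
calibrated definition (external annotators differ among themselves at the
margins); they are validated by requiring exact recovery, with zero false
positives, of the designed pairing of generated duplexes, including
wobbles.

## Two-pass Z ranking

Per target and metric, group values (best model, best reference
conformation) are standardized with the population standard deviation;
groups below the tolerance (−2) are discarded; mean/sd are recomputed on
the kept set and *all* groups are re-scored against the pass-2 statistics;
scores below the clip (−2), and missing values, become the clip. Discarded
groups are excluded from the pass-2 statistics but still scored against
them. If discarding leaves fewer than two groups, pass-1 statistics are
retained; zero variance yields all-zero Z. Weighted combinations treat a
missing component as the clip so an absent prediction can never help, and
the final ranking sums only positive combined Z over targets, so a group
missing a target contributes zero rather than being dragged negative.
Podium ranking uses competition ("1224") placement: tied groups share the
better placement and consume the following ones. An RMSD row filter is
provided for map-based metric tables whose scores can reward degenerately
collapsed models; its per-target threshold is user-set.

Orientation (higher-vs-lower-better) is a registry keyed by metric name,
extensible for externally computed tables (map correlations, LLG/TFZ);
computing those external metrics themselves is out of scope.

## RNA–protein interfaces

A contact is any nucleotide/amino-acid pair with heavy atoms within 5 Å
(KD-tree accelerated, identical to the all-pairs definition). Contact MCC
is computed over the union of residue keys of the two maps, absent
residues contributing zero rows, so hallucinated and missing chains are
punished symmetrically; a constant map scores 0. Folding patterns segment
contacted RNA sequence positions into regions wherever the gap exceeds 10
nucleotides (configurable — the operational definition of "region" is this
module's choice), order regions 5′→3′, letter entities B, R, G, … by their
most-5′ contacted region, and, when an expected region count exceeds the
observed bound regions, place '−' markers at the largest uncontacted gaps.
Protein entity composition (which chains form a dimer) is user input, not
inferred.

## Synthetic fixtures

The duplex generator is first-class code, not a test convenience: it is
the ground-truth oracle for annotation and the clash model. Bases use
standard reference-frame planar coordinates; each pair level is placed by a
twist of 32.7° and rise of 2.81 Å per base pair, with the pair frame
displaced −4.4 Å from the helix axis and inclined 20°. The inclination +
displacement combination matters: with coplanar, axis-centred pairs the
2.81 Å rise is sterically impossible (stacked atoms would overlap by up to
0.6 Å), whereas the chosen frame gives ~3.5 Å separation along the base
normals and a worst non-bonded overlap of −0.05 Å — clash-free with
margin, verified by the clashscore operation on randomized duplexes. The
sugar-phosphate template was solved once by least squares over bond-length,
1-3-distance and repulsion constraints plus the requirement that the helix
symmetry operation carries O3′ onto the next residue's P on *both* strands
(1.599 Å); the solved coordinates are hard-coded. G·U wobbles are realized
as in-plane rotations of the two bases about their glycosidic attachment
points (G −15.39°, U +10.93°, solved once), because a rigid helical
backbone cannot absorb the canonical ~2 Å wobble shear; the resulting
hydrogen bonds are 2.89/2.96 Å through the correct donor–acceptor atoms.
5′-terminal residues carry no phosphate.

What the generator does *not* emulate: loops, junctions, non-canonical
pairs, sugar-pucker diversity, realistic torsion distributions, or
experimental noise. Passing the identity/recovery suites therefore shows
the metrics and annotator are self-consistent and correctly implemented,
not that annotation thresholds are tuned for distorted experimental
structures.

Decoys are deterministic per seed. Gaussian decoys scale a fixed unit-noise
draw by σ, so a single seed yields a nested family across noise levels —
this common-random-numbers design is what makes per-replicate monotone
degradation a meaningful test. Hinge decoys rotate all residues after a
pivot about the O3′–P bond axis; rigid decoys probe superposition
invariance; register decoys shift numbering to exercise correspondence
modes. Simulated score tables draw `baseline ± (group effect + noise)` per
metric with orientation-correct signs; because the two-pass Z is invariant
under positive affine maps, per-metric scales are irrelevant to ranking
recovery and are not simulated.

## Problem sizes and test design

The property suites run at sizes chosen to keep the whole test run in a few
minutes while still exercising every code path: identity and annotation
suites use 5–13 bp duplexes; GDT oracle checks use ≤8-point fixtures
(where the all-subset oracle is exact and cheap); monotone degradation
uses a 20-bp (40-nt) duplex so the TM-score d0 sits above its short-chain
floor — at 16 nt the σ = 2 and σ = 4 scores are both at the noise floor
and their order is chance; ranking recovery uses 20 groups × 12 targets ×
200 seeds with effects spaced by 2 and noise sd 2.

## Known limitations

- GDT/TM superposition searches are defined approximations; their quality
  bound is established on small instances only.
- TM-score short-chain behaviour (floored d0) makes scores for RNAs under
  ~25 nt conservative and hard to compare across lengths.
- The annotator is calibrated on idealized geometry; distorted
  low-resolution models may gain or lose marginal pairs relative to other
  annotation tools, which themselves disagree at the margins.
- `by_sequence` correspondence aligns chains independently and does not
  attempt inter-chain rescue when chain ids differ and counts mismatch.
- Clash detection has no hydrogen model and no hydrogen-bond exemption;
  donor–acceptor pairs at ~2.6–3.0 Å are still below the 0.4 Å overlap
  threshold, so this does not inflate scores for plausible geometry.
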