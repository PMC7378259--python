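# Methods

## Block descriptor

Each 100×100 block is converted to grayscale (rounded ITU-R 601
luminance; the choice of colour-to-gray transform is a package decision
— the classifier operates on gray-level texture only) and every interior
pixel receives an 8-bit LBP code: neighbour p = 0 is the east pixel, the
ring proceeds counter-clockwise, and the comparison `s(g_p − g_c)` is 1
when the neighbour is **greater than or equal to** the centre, so ties
set the bit. Border pixels lack a full ring and are skipped rather than
padded — padding would fabricate intensities at block edges — so a
100×100 block contributes 98² = 9604 codes.

The rotation-invariant variant canonicalises each code to the minimum
over its 8 cyclic bit rotations. The 256 codes fall into exactly 36
orbits; class indices are assigned contiguously by ascending canonical
code. A 90° image rotation cyclically shifts the neighbour ring by two
positions, which the canonicalisation absorbs, so the LBPri histogram is
exactly invariant under quarter-turn rotations of a block.

The descriptor is the 256-bin LBP histogram concatenated with the
36-bin LBPri histogram (292 values). Each sub-histogram is
L1-normalised before concatenation so descriptors are comparable across
block sizes and the SVM is not dominated by the raw pixel count; a
raw-count mode is available (`describe_block(..., normalize=False)`).
Whether the original pipeline normalised its histograms is not
recoverable; normalisation is this package's choice.

## Cascade classifier

Stage 1 is a linear-kernel SVC over five classes — HE, MA, LC, LR, and
a merged EA∪LV class, merged because elastic-artery and large-vein
smooth muscle are near-identical in texture. Stage 2, a polynomial
SVC (degree 3, variance-scaled gamma), splits the merged class and is
consulted only when stage 1 emits it; if the training data lack EA or
LV the stage is skipped with a warning and the present label is used as
a fallback. Multi-class handling is scikit-learn's one-vs-one voting,
which is deterministic for fixed data and seed.

Hyperparameter defaults are C = 10 for both stages. L1-normalised
histogram descriptors have Euclidean norms around 0.1–0.3, so linear
kernel values are small and C = 1 visibly under-fits even cleanly
separable classes (the margin penalty dominates); C = 10 fits separable
fixture data exactly while remaining far from the hard-margin regime.
All hyperparameters are overridable through `CascadeConfig` / the
`train --config` YAML.

## Knowledge base

The refinement stage needs only two question forms — organ/organ
presence and organ/epithelium lining — and only ever branches on
whether the answer is empty. A closed-world triple store (set
membership over a controlled vocabulary, Turtle serialisation via
rdflib) therefore reproduces the query semantics of a full OWL ontology
plus DL reasoner for this workload; no subsumption inference is
required. The default fact set asserts **no** cross-organ
`hasPresenceOf` facts — arteries and veins travel together anatomically
but are sampled separately in histology, so all 12 ordered cross-organ
queries answer empty and trigger correction — and links each organ to
`FlatSimpleEpithelium` (endothelium/endocardium). Users can assert
presence facts in a Turtle file (e.g. vasa vasorum scenarios) to
suppress correction; `histoblocks export-kb` writes the default set as
an editable template.

## Refinement

**Organ correction.** Occurrences of EA/LV/MA/HE are counted; organs
with non-zero counts are ranked descending (ties broken by the fixed
priority heart > muscular artery > elastic artery > large vein, with a
warning). Every higher-rank→lower-rank pair yields one presence query —
k ranked organs give k(k−1)/2 — and each empty answer rewrites the
object organ's cells to LC with provenance `corrected`. Correction is a
single pass in rule order; occurrence counts are not recomputed
mid-pass. The corrected label is LC because that is what foreign-organ
false positives overwhelmingly are: connective tissue misread as
muscle.

**Epithelium detection.** "Large enough" light regions are 4-connected
LR components of at least t = 10 blocks; 4-connectivity (rather than
straight runs) is robust to lumen shape. A component qualifies only if
some 4-adjacent cell carries a muscle label — the qualifying set
defaults to {EA, LV, MA, HE}: cardiac muscle is included because
endocardium lines heart chambers exactly as endothelium lines vessels,
even though only the smooth-muscle classes are usually named. If the
knowledge base links the dominant organ to an epithelium type, the
component's muscle-touching cells (the lumen-side boundary — epithelium
lines the lumen, so the LR side, not the muscle side, is relabelled)
become EP with provenance `epithelium`. Refinement is idempotent: after
one pass only the dominant organ's label survives among discriminant
classes and the remaining lumen interior no longer touches muscle.

**Threshold calibration.** The minimum component size t is recovered by
exhaustive search: the error of a candidate is the summed count of
disagreeing cells (Hamming distance — the natural reading of an
absolute difference between categorical matrices) between ground-truth
matrices and refined outputs at that t; the smallest t wins ties.

## Synthetic fixtures

The generator's purpose is statistical separability under LBP features,
not visual realism. Each class is an oriented sinusoidal grating plus
Gaussian noise with a stain-like base colour; (orientation, frequency)
pairs are pairwise distinct, and the light-region class has the lowest
pixel variance of all classes, as a near-white lumen should. Organ
images place an LR lumen disk inside a muscle annulus inside an LC
surround on the 20×15 grid, render the full 2048×1536 px geometry
(partial edge blocks filled with the surround and discarded by tiling),
and mark lumen cells 4-adjacent to muscle as EP in the ground truth.
Datasets assign organs round-robin and split at the image level —
floor(0.7·K) leading images train, the rest validate — so no block
leaks across splits and every organ appears in both splits at K = 20.

Corruption exists at two levels, with different roles. Image-level
corruption swaps the rendered *texture* of randomly chosen muscle cells
to a foreign organ class while the truth keeps the organ's own label —
producing genuine classifier errors. Matrix-level corruption
(`corrupt_matrix`) injects foreign-organ *labels* into cells whose
truth is LC; this is the configuration under which refinement provably
improves every class's F-score, and it mirrors how such false
positives arise in practice (connective blocks misread as foreign
muscle). A foreign label written onto a muscle-truth cell is corrected
to LC — still wrong, merely differently wrong — so the strict
every-class monotonicity property is stated over matrix-level
corruption.

What passing tests on these fixtures shows: the descriptor, cascade,
rule engine and geometry operate correctly and the refinement
behaviours hold wherever their preconditions (truth-consistent
knowledge base, dominant organ actually dominant) are met. What they do
not show: performance on real stained tissue, where class textures
overlap, blocks mix tissues, and staining varies — the fixture
separability gate is an artifact property, not an expected clinical
accuracy.

## Problem sizes and numerical choices

The study-scale round trip uses 20 images at 2048×1536 (6000 blocks,
14/6 image split); threshold recovery sweeps t ∈ {2..20} over 100
seeded problems whose component sizes bracket the generating value
(always including sizes t−1 and t, which make the generating threshold
uniquely error-free); monotone-improvement checks run corruption rates
1–20% across organs and seeds. All randomness flows through
`numpy.random.default_rng` seeded per fixture; SVC training is
deterministic given data and seed. Degenerate inputs are rejected with
explicit errors: blocks under 3×3, images under one block, empty
candidate sets, layouts whose lumen+annulus overflow the grid or whose
lumen falls under the configured minimum block count.

## Known limitations

* Real-data performance is out of reach of the fixtures by design; no
  claim is made about F-scores on stained tissue.
* The vocabulary covers the four modelled organs and one epithelium
  type; multi-organ slides and other epithelium shapes (cubic,
  cylindrical — distinguishable only at 40×) are out of scope.
* Correction reassigns impossible organ labels to LC unconditionally;
  a probabilistic or confidence-weighted correction is not modelled.
* `load_kb` reports unknown vocabulary by term and file, without line
  numbers (the parsed graph does not retain source positions).
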