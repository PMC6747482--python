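# Methods

`ssefold` predicts RNA tertiary structure from a sequence and a
secondary structure by assembling all-atom fragments of the *smallest
secondary elements* (SSEs) — stems, hairpin loops, bulge loops, internal
loops and multi-branch junctions — and then refining the assembled model
by restraint-guided simulated-annealing Monte Carlo (SAMC).  This note
records the model, its assumptions, the tunable parameters, and the
design choices made where the method leaves them open.

## Secondary-structure model

A secondary structure is a one-to-one pairing of sequence positions.
The crossing-free ("nested") part drives template assembly; pairs that
cross the nesting (pseudoknots) are never modelled with templates but
are converted to distance restraints for the refinement stage.  The
split keeps a *maximum-cardinality* crossing-free subset, computed by an
interval dynamic program; ties are broken by retaining the pair whose
opening index is most 5'.  All bracket alphabets `()[]{}<>` and
`Aa..Zz` are parsed.

The nested structure is decomposed into a rooted tree whose nodes are
SSEs and whose edges are shared closing base pairs.  Loop nodes carry up
to two closing pairs per adjoining helix end (one for length-1 helices);
these closing pairs are the overlap regions used to superpose adjacent
templates.  Isolated length-1 helices are treated as stems.  Regions
outside every helix (dangling ends, linkers between top-level helices)
form an `exterior` pseudo-node, which also covers the degenerate
no-pairs case.  The root of the tree is the SSE containing the
5'-terminal residue.

*Movable elements* are the contiguous spans whose rigid motion cannot
break a helix: a span qualifies exactly when every helix lies entirely
inside or entirely outside it.  They are the move set of the Monte Carlo
refinement, which therefore preserves the secondary structure by
construction.

## Idealized nucleotide geometry

All synthetic coordinates derive from one frozen table
(`ssefold._nucdata`): heavy-atom positions of the four nucleotides in a
standard Watson-Crick pair frame, in which the paired partner of any
base is the proper 180° flip about the x axis.  The sugar-phosphate
backbone shared by the four bases was refined once by least squares so
that propagating residues with the helical step — twist 32.7° (11
residues/turn), rise 2.81 Å, base-pair inclination 18.8°, axis
displacement −3.14 Å — closes the O3'–P bond at 1.60 Å on both strands
with preserved sugar chirality and no heavy-atom contacts below 2.9 Å.
Within a pair this geometry gives N1–N3 ≈ 2.83 Å and C1'–C1' ≈ 10.78 Å.
G·U wobbles are placed with the same flip geometry, a deliberate
idealization.  Base-pair parameters beyond these (propeller, roll,
sequence-dependent steps) are not modelled.

## Template library

Templates are SSE-shaped all-atom fragments indexed by an exact shape
key: helix length for stems, per-strand unpaired counts for loops.
Near-shape matches are not admitted; a miss triggers de novo generation.
Harvesting decomposes an annotated structure (given pairs, or pairs
detected geometrically) and cuts one template per node, tagged with its
source id so whole sources can be excluded from queries (leave-one-out
validation).  Query results are ranked by sequence identity over all
template positions; ties break on lexicographic source id and insertion
index, making the ranking insertion-order invariant.  Library
persistence is one PDB file plus one JSON sidecar per template.

When a template residue's base differs from the target sequence, the
residue is remodelled: the backbone is kept and the target base's
standard atoms are placed through a frame fitted to four anchor atoms
(C1', the glycosidic nitrogen and its two ring neighbours, whose
standard positions nearly coincide for purines and pyrimidines).

## Synthetic structures

The fixture generator builds complete molecules without any external
data: stems are ideal helices; loop templates place ideal 2-bp closing
stubs (coaxial for internal/bulge loops, splayed at fixed tilt/azimuth
for junctions, side by side for the exterior) and interpolate the loop
nucleotide frames along the screw motion (matrix log/exp) between their
anchors, followed by a rigid-body relaxation that closes every O3'–P
junction.  When the two anchor frames point against each other (a
hairpin-type turn) the screw geodesic would cut through the preceding
helix, so the path is arched outward along the anchor's helix axis
(sinusoidal lift, at most 5 Å).  Assembled fixture molecules get a
final whole-molecule relaxation, leaving them free of covalent,
pairing and steric violations.  A dedicated constructor builds hairpin-type (H-type)
pseudoknots with the two stems coaxially stacked, used as ground truth
in the restraint experiments.

These synthetic molecules are idealized: loops are smooth arcs rather
than experimentally observed conformers, non-canonical pairs and
tertiary contacts are absent, and every helix is geometrically perfect.
Tests passing on them demonstrate the machinery (decomposition,
assembly, refinement, clustering) is correct and self-consistent — not
that predictions on natural RNAs reach any particular accuracy, which
depends on a template library harvested from experimental structures.

## De novo loop generation

Two generators fill library misses:

*Bi-residue method.*  Fragments of two covalently continuous
nucleotides are cut from a source structure (any structure is accepted;
a bundled synthetic mixed hairpin/internal-loop source stands in for a
ribosomal RNA).  An initial chain is grown across each loop strand by
superposing each fragment's first residue onto the chain end; then a
Metropolis loop replaces the fragment at a random position, accepting on
an energy of squared closure gaps (chain ends vs. the closing stubs)
plus a clash count, under geometric cooling from T=1.0 to T=0.05.  The
best chain seen is kept and finally relaxed for exact closure.

*Distance geometry.*  Distance bounds are collected per interaction
class — atom pairs within a nucleotide, in adjacent nucleotides, in
paired nucleotides and in stacked nucleotides — keyed by base and atom
names, as observed min/max (optionally inner percentiles).  For a loop,
stub atoms get zero-width bounds (their geometry is known), classed
pairs get their bounds, covalent junction distances are pinned, and
everything else gets clash-to-diameter defaults.  After Floyd–Warshall
triangle smoothing, a distance matrix is sampled uniformly between the
bounds, embedded by the classical metric-matrix eigendecomposition (top
three eigenvectors), mirror-corrected by majority vote over sugar
improper volumes (C1'–N–O4'–C2'), refined by damped Gauss–Seidel
corrections of bound violations, and re-anchored on the ideal stubs.

## Assembly

Pre-order traversal of the SSE tree: the root template is placed as is;
every child template is superposed onto the already-placed structure by
the Kabsch algorithm over all atoms of the shared closing-pair residues,
and duplicated residues keep the parent's copy.  Superposition uses the
SVD solution with the smallest-singular-vector sign correction, so
rotations are always proper; degenerate (collinear, < 3 atoms) inputs
are flagged as ambiguous.  Assembly is deterministic given the template
choices, and structure size is unbounded.

Fast mode produces N models (default N = 5): the first from the
top-homology template of every node, the rest from seeded random
choices.  Sampling mode starts from the top assembly and, for a set
number of steps (default 500), swaps one random node's template for a
random candidate and re-assembles; the whole ensemble is clustered and
cluster representatives are ranked.

## Geometric relaxation

In place of force-field minimization, models are relaxed geometrically:
whole helices and individual loop residues move as rigid bodies under
bounded least squares against flat-bottom windows — O3'–P junctions at 1.2–1.8 Å,
canonical-pair windows (C1'–C1' 9.8–11.6 Å, N1–N3 2.3–3.5 Å) for the
nested pairs, user/pseudoknot restraint windows — plus a soft-sphere
hinge below 2.5 Å between bodies and a weak anchor to the starting
pose.  An update that would increase the clash count is discarded, so
relaxation never worsens packing.  Internal geometry of each body is
preserved exactly.  An external minimizer can be applied afterwards by
users who have one; nothing in the pipeline depends on it.

## Refinement (SAMC) and pseudoknots

The refinement energy is a weighted sum

E = w_conn·Σ junction violations² + w_clash·Σ soft-sphere overlaps²
  + w_ss·Σ nested-pair window violations² + w_res·Σ restraint violations²
  + w_stat·(statistical potential),

with defaults w_conn = 1, w_clash = 0.3, w_ss = 1, w_res = 1 (raised to
3 in the pseudoknot experiments), w_stat = 0 (the potential is used for
final ranking rather than inside the Monte Carlo, trading a small
amount of guidance for a large speedup).  All violations are flat-bottom:
zero inside the window, linear distance outside, squared in the sum.

Each step picks one movable element and one move type uniformly:
translation (σ = 2 Å), rotation about the element centroid, or rotation
about the axis through its backbone anchors (σ = 15°), magnitudes scaled
by √(T/T_high).  Acceptance is Metropolis.  The schedule heats from
T_low = 0.05 to T_high = 5.0 over 10 geometric rungs and cools back over
10 more (default 25 sweeps per rung); heating first helps escape the
assembled model's local minimum.  One sample per rung sweep is recorded
(capped at 1000) and the best-energy conformation is tracked separately.
A fixed seed reproduces the trajectory bit for bit.

Pseudoknot pairs are converted one-to-one to base-pair restraints:
flat-bottom windows C1'–C1' ∈ [9.3, 12.3] Å (10.8 ± 1.5, centred on the
ideal-helix value) and, for purine–pyrimidine pairs, N1–N3 ∈ [2.0, 3.6] Å
(2.8 ± 0.8).  Distance restraints from files (`PAIR i j [w]` /
`DIST i j lo hi [w]`, 1-based) use the same machinery; the top-N rule
for coevolution-derived contacts keeps floor(0.2 × length) restraints
(flooring chosen where the rule's rounding is unspecified).

## Clustering and ranking

Conformations are clustered by k-means on the pairwise all-atom
superposed-RMSD matrix, with the medoid update rule: the representative
of a cluster is its member with the smallest sum of distances to all
other members (ties: smallest index).  Initialization is farthest-point
seeding from a seeded random start; iteration stops at a stable
assignment, and the within-cluster distance sum is non-increasing.  The
number of clusters equals the requested number of predictions.

Representatives are ranked by a knowledge-based score: distance-binned
(0.5 Å bins to 20 Å) pseudo-energies over P/C1'/glycosidic-N atom pairs
plus a backbone pseudo-torsion term (P–C1'–P–C1', 24 bins), trained as
the negative log ratio of observed frequencies to a uniform-density
(r²) reference; bins never observed in training (clash range and
beyond-envelope distances) are set to a repulsive plateau above every
observed bin.  The shipped default tables are trained on the synthetic
fixture set and are explicitly a stand-in for potentials trained on
experimental structures; they are rigid-motion invariant and rank the
synthetic natives above loop-randomized decoys, which is all the package
claims for them.

## Interaction annotation and evaluation

Canonical pairs are detected geometrically: complementary bases
(Watson-Crick or G·U), purine-N1 to pyrimidine-N3 distance in
[2.3, 3.5] Å, C1'–C1' in [9.0, 11.5] Å, base-plane angle < 30°.
Stacking is annotated at the helical-step level: two canonical pairs
stack when their pair centroids are within 5.5 Å and their planes within
30°; the step is recorded under the two 5'-most residues.  Loop-region
base stacking is therefore not annotated — a deliberate simplification
consistent across model and reference.  Interaction network fidelity is
INF = √(PPV × STY) with PPV = |pred∩ref|/|pred| and
STY = |pred∩ref|/|ref|; both sets empty gives 1, exactly one empty
gives 0.

## Problem sizes used in the shipped analyses

The bundled experiments run on a synthetic 28-nt H-type pseudoknot
(stems of 5 and 4 pairs, loops of 2 and 8 nt), with five independent
refinement runs per condition in the acceptance script and ten in the
test suite; the large-structure assembly check uses a 322-nt
fourteen-junction molecule.  These sizes were chosen as the smallest
that exercise every code path convincingly.

## Known limitations

- Helix geometry is a single idealized A-form; sequence-dependent
  structure, non-canonical pairs and base triples are absent.
- The shipped scoring tables are trained on synthetic fixtures; for
  real predictions users should harvest a library and retrain on
  experimental structures.
- G·U wobble pairs use Watson-Crick placement geometry.
- Stacking annotation covers helical steps only.
- The refinement moves rigid spans; it cannot repack individual
  backbone torsions (the de novo generators and the per-residue
  relaxation provide the finer granularity where needed).
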