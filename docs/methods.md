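# Methods

## The model

`perihull` implements a purely structural model of how peripheral membrane
proteins present hydrophobic residues to a flat membrane. The protein is
reduced to the point cloud of its C&alpha; and C&beta; atoms (glycine and
residues with a disordered C&beta; contribute only the C&alpha;). On this
cloud:

* A **vertex residue** is a residue whose C&beta; is a vertex of the convex
  hull of the full cloud. Hull vertices are the positions that can touch a
  plane (an idealised flat membrane) without any other residue touching it
  first, assuming a rigid backbone.
* The **local protein density** *d* of a residue is the number of
  C&alpha;/C&beta; points within *c* = 1 nm of its C&beta;, boundary
  inclusive and counting the residue's own two atoms. *d* is undefined for
  residues without a C&beta;.
* A **protrusion** is a vertex residue with *d* < *n* = 22: it is not only
  geometrically extreme but also sits in a sparse region, so inserting it
  disrupts little protein and little lipid packing.
* Two protrusions are **co-insertable** when the segment between their
  C&beta; points is an edge of the hull polygon: both can contact the plane
  simultaneously. Qhull returns triangulated facets, so facets whose
  normals agree within 10⁻⁶ rad are merged first and only boundary edges
  of the merged polygons count; otherwise flat faces would contribute
  arbitrary triangulation-dependent diagonals.
* A **hydrophobe** is a residue that partitions favourably into a membrane
  interface on the Wimley–White scale: Leu, Ile, Phe, Tyr, Trp, Cys, Met.
* The **Likely Inserted Hydrophobe (LIH)** — the single-residue binding-site
  prediction — is the protruding hydrophobe with the largest number of
  co-insertable hydrophobic partners; ties fall to the smallest *d*, then
  to a uniform random choice from a stream keyed by (seed, model id), so
  cohort evaluation order cannot change the result. A protein with no
  protruding hydrophobe has no LIH.

Assumptions inherited from the model: the protein binds without
conformational change (single rigid conformer; NMR ensembles reduced to
model 1) and the membrane is locally flat. No energetics — electrostatics,
desolvation, curvature — enter anywhere.

## Surface accessibility

Exposure is decided by side-chain solvent-accessible surface area: a
residue is **exposed** when the summed accessible area of its side-chain
heavy atoms (all heavy atoms except backbone N, C&alpha;, C, O, OXT;
C&beta; counts as side chain) is strictly greater than 0.2 nm², computed
with a 0.14 nm probe and Bondi van der Waals radii (C 0.170, N 0.155,
O 0.152, S 0.180 nm; unknown elements fall back to 0.170 nm with a
warning). Whether C&beta; belongs to the side chain in the area sum is not
fixed by the model's description; we include it (the standard convention),
which mainly affects small residues near the threshold.

Integration is numerical: each atom's sphere of radius r+probe is sampled
with a golden-section spiral (960 points by default) and a point counts as
accessible when outside every other atom's probe-expanded sphere.
Accuracy: an isolated atom reproduces the closed form 4π(r+p)² to well
under 2%, and doubling the point count changes a backbone-occluded atom's
area by ~0.3%. For strongly occluded atoms the *relative* error diverges
as the area approaches zero, so convergence there is asserted in absolute
terms (< 0.02 nm² at doubling) together with stability of the exposure
flags, which are the only quantity consumed downstream.

## Membrane frame and insertion coordinate

A membrane is a hydrocarbon slab: center, unit normal, half-thickness *h*
(OPM's hydrocarbon boundary, where the hydrocarbon volume fraction crosses
0.5). The **insertion coordinate** of an atom at signed normal distance
*z* from the slab center is *h* − |z|: positive inside the hydrocarbon
core, zero on either boundary plane, negative on the solvated side. Both
leaflets fold onto one axis, matching the two boundary *planes* of the
planar model. Frames come either from explicit parameters or from the two
layers of DUM pseudo-atoms in OPM-flavoured PDB files.

**Non-binding surface fragments** of transmembrane complexes are the
residues whose C&alpha; insertion coordinate is ≤ −1.5 nm (inclusive),
i.e. at least 1.5 nm outside the slab on either side. Distance is measured
along the normal, consistent with the infinite-plane membrane model.
Annotations (hull, density, pairs) are always computed on the entire
complex first; the fragment only restricts the statistical selection.

Per-family **median LIH insertion coordinates** summarise agreement with an
external orientation model; the headline number is the fraction of
families whose median is within a 0.5 nm margin of the boundary,
compensating for the rigid-protein and flat-membrane idealisations and the
C&alpha;-to-side-chain offset.

## Family-weighted statistics

Proteins are grouped into families; every family contributes equally
regardless of size, preventing large families from dominating. With G a
protein, C a family, D a data set (cohort) and G_s the residues of G
meeting selection s:

* mean fraction within a family:  f̂_{s|r} = mean over G of |G_s∩G_r|/|G_r|
  (members with |G_r| = 0 are skipped and the mean renormalised; a family
  whose members all have |G_r| = 0 is an error, not a silent zero)
* weighted residue count:  N̂_s = Σ_C (1/|C|) Σ_G |G_s|
* weighted protein count:  M̂_s = Σ_C (1/|C|) Σ_G 1[|G_s| > 0]
* weighted fraction:  F̂_{s|r} = N̂_{s∩r}/N̂_r
* protein fraction:  Ê_s = M̂_s/|D|

95% intervals are Wald (normal approximation to the binomial) with the
real-valued weighted counts standing in for trial counts — N̂_r for
F̂_{s|r}, |D| for Ê_s — with no continuity correction. Cohorts are
compared by the log odds ratio

    ln R(A,B) = ln[F̂_A(1−F̂_B)] − ln[F̂_B(1−F̂_A)]

with Wald interval SE² = 1/s_A + 1/f_A + 1/s_B + 1/f_B where s and f are
the weighted success/failure counts of each side. Fractions of exactly 0
or 1 yield a flagged infinite estimate; nothing is clipped. **No multiple
testing correction is applied anywhere** — intervals on families of
comparisons (per amino acid, per density range, per secondary structure)
are per-comparison intervals.

Pair measures repeat the construction over co-insertable pairs: 'one'
pairs contain at least one protruding hydrophobe, 'both' pairs two;
F̂^pair_{both|one} = N̂^pair_both/N̂^pair_one estimates the conditional
probability that a pair is fully hydrophobic given it is partly so. Its
Wald failures are N̂^pair_one − N̂^pair_both, the only non-negative
reading of the pair failure count.

### Co-insertion null model

The null for co-insertion reassigns each protein's hydrophobic labels
uniformly over its protrusion positions, preserving the count of
hydrophobic protrusions, and recounts both/one pairs. Sampling defaults to
1000 permutations per protein, each protein on an independent RNG
substream keyed by (seed, model id). Cohort-level null counts are the
per-sample family-weighted counts averaged across samples; the null
fraction and the observed one are compared with the same ln R machinery.

A calibration caveat, measured on planted cohorts: the Wald interval on
ln R(observed, null) is conservative by a factor of about 2. The null side
enters the SE as if it were an independent binomial sample although the
permutation average is nearly noiseless, and the permutation is
conditioned on the observed labels, which cancels the count-driven part of
the observed variance. Under a truly random placement of hydrophobes the
interval therefore covers 0 essentially always (measured 100% over 500
replicate cohorts) rather than at the nominal 95%. Conclusions of
*enrichment* drawn from this interval are safe (it errs toward caution);
it is not a calibrated test. A calibrated alternative would take quantiles
of the permutation distribution directly, which this package deliberately
does not substitute.

## Secondary structure

DSSP summary codes map to five classes: H/G/I → helix, B/E → beta,
T → bend, S → turn, everything else (including blank) → loop. Note this
labelling swaps the conventional DSSP names of T (turn) and S (bend); it
is kept as the model defines it, and the table is configurable. DSSP
output files are parsed; the dssp program is never invoked.

## Binding-site angle evaluation

For a residue set I, the site vector is t_I = mean C&alpha; of I − mean
C&alpha; of all residues. The "protein center" is the unweighted C&alpha;
mean (the defining equation's plain mean), not a mass-weighted center.
The evaluation angle is the angle between t for the experimentally
identified residues and t for {LIH}; angles below 90° mean prediction and
experiment are on the same side of the protein. Control angles are
computed for every protrusion taken singly; on a spherically symmetric
fixture their median is 90°. A protein without an LIH is reported with the
sentinel 180° and an explicit flag. Angles are undefined (an error) for
zero-length vectors, e.g. an experimental set centered exactly on the
protein center.

## Synthetic fixtures

The generator builds point-cloud proteins with *planted, certified* ground
truth rather than realistic geometry:

* a core of residues uniform in a ball (default 120 residues, radius
  1.2 nm ≈ 33 points/nm³, comparable to packed protein interiors), C&beta;
  0.15 nm from C&alpha; in a random direction;
* k radial spikes (min. pairwise angle 20°) whose tip C&beta; sits
  spike_length = 1.2 nm above the core surface — roughly an exposed loop.

Certification at generation time is independent of the Qhull pipeline:
each tip is *strictly extreme* along its own spike direction (an exact
supporting-plane certificate of vertexhood), densities are recounted by
brute force, and any low-density core residue is checked against an LP
vertex test. A draw violating the plant is rejected and resampled from the
same deterministic stream (bounded at 20 attempts, then a hard error);
rejection never looks at hydrophobe labels, so their Bernoulli placement
is unbiased. The same seed always yields the same fixture. Tip adjacency
(which spike pairs share a hull edge) can additionally be computed with a
brute-force projection oracle, giving an expected LIH where the tie-break
is deterministic.

What a green test on these fixtures establishes: the geometry, counting
and statistics machinery is correct on inputs with known answers. What it
does not establish: behaviour on real side-chain packing, flexible loops,
crystal contacts, or quaternary-structure errors — fixtures have no
chemistry beyond the hydrophobe labels, and their density contrast between
core and spikes is sharper than in real structures.

## Numerical choices and degenerate inputs

* Lengths in nm throughout; PDB Å divided by 10 on input.
* Density boundary inclusive (≤ c); the residue's own C&alpha;/C&beta;
  count toward *d* (a plain reading of the definition — excluding them
  would shift every *d* by exactly 2 and is not what we do).
* Hull tolerances: facet-merge angle 10⁻⁶ rad; no coordinate joggling —
  clouds with affine rank < 3 or fewer than 4 points raise an error naming
  the rank.
* Altlocs: highest occupancy, ties to file order. Selenomethionine and a
  small editable table of modified residues remap to parent amino acids;
  unmappable residues and residues without C&alpha; are dropped with
  warnings.
* All randomness (LIH tie-break, null permutations) flows from explicit
  seeds through per-protein substreams, so results are independent of
  iteration order and reproducible.

## Known limitations

* SASA is a point-sampling approximation rather than an exact analytic
  surface decomposition; only the 0.2 nm² threshold crossing matters
  downstream, and that is stable under refinement.
* The Wald intervals inherit the real-valued "trial count" convention;
  they are not exact small-sample intervals, and the null-model interval
  is conservative as described above.
* Curved membranes, conformational ensembles and any energetic scoring are
  out of scope by design.
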