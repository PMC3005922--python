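# Methods

## The model

A docked pose is reduced to an interaction profile: for each heavy atom
*j* of the binding site, the summed pairwise energy contributed by every
heavy atom *i* of the ligand,

E_j = Σ_i [ f(r_ij; B_ij) + 332.0 · q_i q_j / r_ij ],

with r_ij the Euclidean distance in Å, q the formal charges in units of
e, and B_ij ∈ {hbond, steric} the interaction class of the pair. The
class is hbond when one atom can donate a hydrogen bond and the other
accept one (donor/acceptor/both assignments below), steric otherwise.

f is a trapezoidal piecewise linear potential per class: a contact
penalty falling linearly from V5 at r = 0 to zero at V1, a linear
descent to the well depth V6 at V2, a flat well on [V2, V3], a linear
return to zero at V4, and zero beyond V4. It is continuous everywhere
and its minimum over r ≥ 0 is exactly V6, attained on [V2, V3].

### Parameters

| parameter | hbond | steric | units | role |
|---|---|---|---|---|
| V1 | 2.3 | 3.3 | Å | end of contact penalty |
| V2 | 2.6 | 3.6 | Å | well start |
| V3 | 3.1 | 4.5 | Å | well end |
| V4 | 3.6 | 5.5 | Å | interaction cutoff |
| V5 | 20 | 20 | kcal/mol | penalty at r = 0 |
| V6 | −2.5 | −0.4 | kcal/mol | well depth |

These defaults follow the established piecewise-linear-potential
convention for docking scoring functions — a deep narrow well for
hydrogen-bond-capable pairs, a shallow wide well for steric contact —
and are deliberately shipped as configuration (YAML/JSON `plp:`
section), not constants in code, so any six-parameter variant can be
substituted per class.

The Coulomb term applies only between pairs where both formal charges
are nonzero, with a hard cutoff of 12 Å (configurable); whether it is
summed into E_j at all is a flag (`include_electrostatics`, default on).
Coincident atoms (r = 0) raise a degenerate-geometry error naming the
pair rather than propagating infinities.

Other defaults: binding-site radius 10 Å around the reference ligand
(residue-level membership: a residue joins the site if any of its atoms
is within the radius of any reference atom); zero-column tolerance
ε = 1e−6 kcal/mol for the "involved atoms" reduction; stage-1 cut 0.39
on correlation distance; stage-2 cut 0.55 on Tanimoto distance. The two
cut values are reference thresholds calibrated on docked verification
sets by maximum discrimination; they are configuration, and the
calibration machinery (`reference_threshold`) is included so users can
re-derive thresholds for their own targets from labelled pair
distances.

## Donor/acceptor typing

Structures arrive with hydrogens stripped (they are removed on load in
any case), so hydrogen-bond capability is inferred, not observed:

- ligand atoms (bond graph available): N with ≥1 implicit/explicit H →
  donor, N without H → acceptor; O with H → both, O without → acceptor;
  S → acceptor; everything else nonpolar;
- receptor atoms (no bond graph): every N → donor (amino-acid nitrogens
  are protonated at neutral pH), O named OG*/OH/OW → both (hydroxyls),
  other O → acceptor, S → acceptor, rest nonpolar;
- unknown elements → nonpolar, with a logged warning.

This fixed rule table trades chemical nuance (His tautomers,
deprotonated Tyr, thiol donors) for determinism: identical inputs give
identical classes on every platform. Receptor formal charges are read
from the PDB charge column; pose charges from the SDF/MOL2 record.

## Descriptors and metrics

Atom-pair descriptors use a 10-letter typing alphabet {C, N, O, S, P,
F, Cl, Br, I, other} — element identity is the minimal typing consistent
with a 55-pair space — and 15 topological bins; bit (t_a, t_b, k) is set
when some pair of atoms with those types lies k bonds apart (shortest
path, BFS). Distances beyond 15 bonds fold into bin 15 rather than
being discarded; pairs in different connected components set no bit.
Encoding is presence/absence, not counts. Columns zero across a whole
molecule set are dropped before clustering, which provably changes no
Tanimoto distance.

Correlation distance is 1 − Pearson r, range [0, 2]. Zero-variance
vectors: two identical constant vectors are at distance 0, any other
constant pairing at distance 1 (r taken as 0) — the formula is undefined
there and a fixed convention keeps clustering total. Tanimoto distance
is 1 − |X∩Y|/|X∪Y| with the both-empty case defined as 0.

## Clustering

UPGMA (unweighted average linkage) is implemented in the package rather
than delegated: the distance between two clusters is the plain mean of
all cross-pair leaf distances, recomputed from the original matrix in a
canonical orientation so results are bit-identical to a from-scratch
recomputation, and ties between equally close pairs are broken by the
lexicographically smallest pair of cluster representatives (each cluster
represented by its smallest leaf label). This makes trees reproducible
across platforms and input orderings; the test suite cross-checks
heights against SciPy's average linkage. Flat clusters come from
removing merges above the cut height; cluster labels are the smallest
member id, again for permutation invariance. Newick export halves merge
heights so leaves sit at depth (root height)/2 — an ultrametric tree —
and emits children smallest-label-first as a canonical form.

## Threshold calibration and validation

The discrimination objective is unbalanced pooled accuracy:
(#intra < t + #inter ≥ t)/(n_intra + n_inter). Candidates are the
midpoints between consecutive sorted unique pooled distances plus the
two extremes, which avoids boundary ambiguity of the strict "<"; the
smallest maximising candidate is returned. Whether the two count terms
should instead be normalised separately (balanced accuracy) is a
genuinely open reading; unbalanced accuracy is implemented and the CLI
report names the objective explicitly.

Validation is a pooled-variance (not Welch) two-sample two-sided
t-test between intra- and inter-cluster distance populations, α = 0.01
by default; zero pooled variance with equal means is reported as t = 0,
p = 1.

## Pipeline conventions

- One pose per compound is assumed; duplicate pose ids are collapsed to
  the minimum-energy pose before stage 1.
- The binding site is cut around the supplied reference ligand when one
  is given; otherwise around the union of all docked pose atoms, which
  approximates the occupied pocket without requiring a crystal ligand.
- Stage 2 runs on every stage-1 cluster by default; a `--clusters` flag
  restricts it (e.g. to the actives-containing cluster).
- Representatives: minimum docked energy per stage-2 sub-cluster, ties
  broken by lexicographically smallest pose id.
- Stage 2 uses 2D atom-pair descriptors as its structural features; the
  procedure is sometimes described in terms of physicochemical feature
  sets, but the atom-pair/Tanimoto route is what is implemented here and
  is self-contained (no external QSAR software).
- MOL2 pose files carry per-pose energies as a `# <field> = <value>`
  comment line preceding each `@<TRIPOS>MOLECULE` record, since MOL2 has
  no property block; SDF uses a named data field.

## Synthetic data: what it emulates, what it does not

The generator builds a point-atom pocket whose atoms form shells
(3.2–4.5 Å) around n_modes anchors placed on a 6 Å circle, cycling
through elements/names so that all four donor classes and both charge
signs occur. Poses place compact chain molecules at one anchor with
isotropic N(0, σ²) jitter per atom (default σ = 0.1 Å) and energies
~ N(−8, 1) kcal/mol. Scaffold families differ in backbone heteroatom
sequence (families stay mostly carbon, halogens terminal) plus 1–2
random family-typical decorations per molecule; every family's first
backbone nitrogen is protonated (+1) so the electrostatic signature is a
mode-level feature shared across families, not a family discriminator.
All randomness flows through one seeded generator: identical spec +
seed gives identical output.

Defaults (2 modes × 10 poses, 2 families, σ = 0.1 Å, 32 site atoms)
describe the canonical recovery scenario used in the tests and the
acceptance script; the problem size keeps every suite run in seconds
while the separation margins (intra-mode correlation distance ≲ 0.27 vs
inter-mode ≳ 0.49 around the 0.39 cut; within-family Tanimoto ≲ 0.38 vs
across-family ≳ 0.62 around 0.55) are comfortable but not degenerate.

What passing on this data shows: the full pipeline — file round-trips
included — recovers planted binding modes and scaffold families and
selects the correct minimum-energy representatives. What it does not
show: performance on real docking output, where binding modes overlap
spatially, scoring noise correlates with pose geometry, molecules share
scaffolds only approximately, and protonation/charge assignment is
genuinely ambiguous. The geometries are not force-field valid and make
no claim of chemical realism.

## Known limitations

- Donor/acceptor typing is element/name-based; no aromaticity,
  tautomer or pH model.
- Receptor charge information relies on the PDB charge column, which
  most deposited files leave empty (profiles then simply lack Coulomb
  terms).
- UPGMA is O(n³); fine for post-screening set sizes (10²–10³ poses),
  not for full-library clustering.
- The stage-1/stage-2 default thresholds were calibrated on docked
  verification sets of five protein targets; for other targets a
  recalibration with `tscc threshold` on labelled pairs is advisable.
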