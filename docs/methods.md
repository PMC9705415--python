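# Methods

`formindock` implements the geometric toolkit used to build and measure
structural models of the actin-filament barbed end capped by a formin FH2
dimer: crystallographic symmetry expansion, rigid-body docking of helical
filaments, a direction-cosine coplanarity statistic, a small/large-domain
shear decomposition, profilin–actin grafting, and clash/contact/interface
analysis. This note records the models, conventions, numerical choices, and
what the synthetic fixtures do and do not establish.

## Structural model and coordinate conventions

All coordinates are orthogonal Cartesian Ångström in the frame of the input
file; fractional↔orthogonal conversion uses the standard PDB
orthogonalization convention (cell axis *a* along *x*, *b* in the *x–y*
plane). Residues are addressed by **author numbering** throughout, because
that is the numbering in which the literature names residues (actin Y169,
formin K1410–D1414, profilin R88). Only model 1 of multi-model files is
read. Hydrogens are retained on read but excluded from every default
selection and all distance computations. Alternate locations default to the
highest-occupancy conformer, ties broken by altloc character order; this is
a package choice (deposition software differs) and is reported wherever it
matters.

Two built-in residue-interval cores address the two lobes of the actin
monomer on either side of the nucleotide cleft:

- small domain (subdomains 1+2): 1–38, 68–135, 335–350, 352–375
- large domain (subdomains 3+4): 150–195, 209–232, 245–320

Missing residues (e.g. the disordered D-loop, ≈40–51) are skipped and
counted, never modelled; grafting a complete isoform is the supported way of
completing a chain.

## Superposition

`kabsch_fit` is the SVD form of the Kabsch algorithm with determinant
correction: reflections are never returned, because a protein and its mirror
image are different molecules; if the unconstrained optimum is a reflection
the (proper-rotation) result is flagged. Fits are single-pass — no outlier
trimming — and unweighted. Backbone atoms {N, CA, C, O} are the default fit
set; all-atom fits are selected explicitly where a measurement calls for
them. Degenerate (near-collinear) point sets are rejected by the ratio of
the second singular value to the first (1e-10).

Under per-coordinate Gaussian noise σ applied to one copy, the fitted RMSD
converges to σ·√(3·(1 − 2/n)) — the √3 from three coordinates per atom, the
(1 − 2/n) from the six rigid-body degrees of freedom absorbed by the fit.
The test suite verifies this law by simulation at n = 500 within 10%.

## Screw decomposition and helices

Any proper rigid motion with a non-trivial rotation is a screw (Chasles):
rotation by an angle about an axis plus a translation along it.
`screw_decompose` takes the axis from the rotation's rotation-vector, the
translation as the axis component of the translation vector, and the axis
point by least squares on (I − R)p = t⊥, reduced to the axis point closest
to the origin. Conventions: angles in degrees in (−180°, 180°]; the axis is
oriented so the translation is ≥ 0, and for pure rotations so the angle is
positive. Rotations below 0.1° are treated as degenerate: a pure translation
is returned flagged (axis along the translation), and the exact identity is
an error. Round-trip fidelity (decompose ∘ recompose) is property-tested to
1e-6 Å over a ±20 Å probe cube.

A helix is the iterated screw: rise (Å/subunit, > 0) and twist
(deg/subunit, negative = left-handed one-start; actin ≈ 27.5 Å, −166.7°).
`fit_helix` fits consecutive-subunit transforms, screw-decomposes each,
sign-aligns the axes, and averages; a twist s.d. above 5° across steps means
the stack is not a regular helix and is rejected. Subunits must have equal
atom counts (synthetic stacks and single-entity filaments do).

Crystallographic expansion converts a fractional operator through the cell
(R꜀ = M R_f M⁻¹, orthonormalized by SVD against cell round-off) and appends
the transformed copy with deterministically renamed chains; the chain map
and transform are recorded in the output metadata. For FH2–actin co-crystals
the relevant operator is a two-fold screw (2₁: 180° + half-cell translation)
relating the two bound actins by one filament rise.

## Coplanarity statistic

For matched atoms x→y between two subunits, each connecting line's unit
vector has direction cosines (cos α, cos β, cos γ) against three orthonormal
reference axes, with Σcos² = 1 per line. Two subunits related by pure
translation give identical lines — zero dispersion of the cosines — which is
the operational meaning of "coplanar" here. Conventions and choices:

- Reference frame: for crystal-derived models, the orthogonalized unit-cell
  axes; for synthetic data, the lab axes (user-overridable). The frame used
  is recorded in every report.
- Line direction: from the polymerase-bound subunit toward the docked
  filament subunit; a `--flip` flag reverses it (negating the means).
- Dispersion: sample s.d. (ddof = 1) by default; the population value is
  computed and reported alongside.
- "Variance" for the small-vs-combined comparison is the pooled mean of the
  three per-component variances.
- Coincident pairs (|y − x| ≤ 1e-6 Å) are dropped and counted; at least 10
  pairs are required.

Exact coplanarity, given the two-fold screw symmetry of the polymerase and
a filament-axis tilt β, fixes the triple to (90°, β, arccos(−sin β)) — the
solution with cos α = 0 and non-positive third cosine; at β = 13° this is
(90°, 13°, 103°) to the nearest degree.

The shear decomposition fits the small and large cores independently and
reports the rotation angle of R_small·R_largeᵀ — the relative rotation about
the shear plane between the two halves of the actin subunit. Synthetic
hinge rotations over 1°–30° are recovered within 0.1°.

## Assembly recipes

- **Filament docking**: fit a chosen filament subunit's core onto the anchor
  actin (small-domain backbone by default; the D-loop lies outside it), move
  the whole filament rigidly, re-fit its helix axis, and measure the tilt to
  a reference axis (directly supplied, or the screw axis decomposed from two
  model chains). A core fit worse than 3 Å RMSD aborts (wrong
  anchor/subunit). The tilt is frame-equivariant to 0.01°.
- **Profilin–actin grafting**: the complex's actin is fitted to each target
  by backbone pairing — global sequence alignment (match/mismatch/gap =
  +1/−1/−5) for cross-isoform grafts — then actin + profilin are moved as
  one rigid body, the target chain is removed, and per-site fit RMSDs are
  recorded (their unweighted mean is the headline graft RMSD). Internal
  complex geometry is preserved exactly (pairwise distances to 1e-9 Å).
  Pairings covering < 50% of the target's residues are rejected.
- **Ribbon oligomer**: among the space-group operators (± one lattice
  translation), the generator of the flat crystal-packing ribbon is chosen
  as the symmetry copy burying the largest actin–actin interface; unit i is
  generatorⁱ(unit 0). On synthetic crystals with a known packing operator
  the recovered unit-to-unit transforms equal that operator to 1e-6.

## Contacts and interfaces

Van-der-Waals radii are a single published heavy-atom set (C 1.70, N 1.55,
O 1.52, S 1.80 Å; further elements included), printed in reports because
clash magnitudes depend on the radii. A clash is max pairwise overlap
r_i + r_j − d > threshold. Residue contacts use a 4.0 Å heavy-atom cutoff;
a salt bridge is a basic side-chain nitrogen (Arg/Lys/His, or N-terminal
amine) within 4.0 Å of an acidic side-chain oxygen (Asp/Glu, or OXT);
polar contacts are N/O–N/O pairs within 3.5 Å.

SASA is Shrake–Rupley sphere sampling with a deterministic golden-spiral
point set: probe 1.4 Å, 960 points/atom by default; buried interface area is
SASA(A) + SASA(B) − SASA(AB), symmetric by construction. Accuracy checks:
the two-sphere closed form is matched within 2% (observed ≈0.5%), doubling
the point density moves the result by < 1%, and the implementation agrees
with an independent Shrake–Rupley implementation (biotite) to < 1% under
identical radii. No interface free energy is estimated — that requires an
empirical solvation model outside this package's scope.

## Synthetic generators

The generators produce the geometry each measurement assumes, with attached
ground truth and full determinism (every output is a pure function of
parameters + seed; one named RNG per call, no global state):

- `make_subunit`: Gaussian cloud (sd 12 Å) grouped into 4-atom
  pseudo-residues with backbone atom names, redrawn until the inertia tensor
  eigenvalues are well separated (unique fits guaranteed). Chiral almost
  surely; not chemically realistic (no bond geometry) — deliberately so.
- `make_screw_pair` / `make_filament`: exact screw/helical arrangements;
  the defaults used throughout the tests and acceptance script are the
  filament's own values, 27.5 Å rise with 180° (crystal two-fold limit) or
  −166.7° (helical) twist, 6 subunits, and 0.2 Å coordinate noise for the
  noisy-recovery studies.
- `make_hinged_pair`: two-domain subunit (domain centroids 28 Å apart) with
  the large domain rotated by a known hinge angle about an axis through the
  inter-domain midpoint; the default hinge in the pipeline is 5.3°.
- `perturb`: i.i.d. per-coordinate Gaussian noise (so displacement RMSD is
  σ√3).

Because the fixtures are geometric, passing tests establish the correctness
of the *measurements* (fits, decompositions, statistics) — not
crystallographic parsing quirks of any particular deposited entry, nor the
biological correctness of a model built from real structures. Running the
pipeline on deposited entries requires supplying local copies of the files;
the library never fetches from the network.

## Problem sizes and defaults

Default study conditions: 200-atom (50-pseudo-residue) subunits, 6-subunit
filaments, 100 random transforms/screws for the recovery sweeps, 100 seeds
for the noisy-helix bias estimate, 100-atom cores for the hinge fixtures,
960 sphere points/atom for SASA. The full suite runs in seconds on one CPU.

## Known limitations

- PDB text output carries 3 decimal places, so arbitrary coordinates
  round-trip through PDB at ≈5e-4 Å; mmCIF round-trips at ≈5e-8 Å. Use
  mmCIF where exact round-trips matter.
- Twist averaging in `fit_helix` is a plain mean of step angles; stacks with
  steps straddling the ±180° branch cut of the angle convention would need
  unwrapping (not an issue for actin-like twists).
- `by_alignment` pairing takes the aligner's first optimal alignment;
  degenerate optima are theoretically possible for low-complexity sequences.
- No structure validation/repair, hydrogen placement, rotamer substitution,
  point-group assemblies, weighted or fragment fits, or energy models.
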