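# Methods

This note records the models, conventions and design choices behind the
package, in the order the pipeline uses them.

## Molecular model

Disaccharide molecules are built from idealized internal coordinates rather
than a crystal-structure seed. Each glucopyranose ring is an exact
tetrahedral ⁴C₁ chair: six ring atoms with uniform 1.52 Å bonds, 109.47°
angles and alternating ±60° ring torsions, which closes the ring identically
(the alternating-sign pattern fixes the D-sugar chirality — with the wrong
sign the syn conformer cannot form the O5′···HO3 contact). Substituents
occupy the two open tetrahedral directions at each ring carbon, equatorial
for heavy atoms and axial for ring hydrogens in the β anomer; the α anomer
inverts only the C1 substituent geometry. Exocyclic bonds are C–O 1.43 Å,
C–H 1.09 Å and O–H 1.00 Å (all hydroxyl and water O–H bonds are exactly
1.0 Å). The β-(1→4) linkage is assembled by placing the non-reducing ring's
anomeric carbon at a 116° C1′–O4–C4 angle with the glycosidic torsions set
exactly: ψ_H = C1′–O4–C4–H4, then φ_H = H1′–C1′–O4–C4 by rotation about the
glycosidic bond. The idealization trades sub-0.1-Å bond-length fidelity for
exact, reproducible geometry; the refinement stage, not the seed geometry,
is responsible for structure.

Named torsions (φ_H, ψ_H, ω = O5–C5–C6–O6, ω′ on the primed ring) are
settable and measurable to numerical precision; torsion rotations move the
distal side of the central bond as a rigid unit, so bonded geometry is
conserved exactly. Torsions follow the IUPAC sign convention (cis = 0°,
right-hand rule along the central bond) on (−180°, +180°]; hydroxymethyl
rotamer references are gt = +65°, gg = −65°, tg = ±180°, with classification
by nearest circular distance and ties broken toward gt (so ω = 0° is gt).

Site labels carry two levels: a coarse `site_class` for scattering and
potentials (Cs, Hc, Oh, Ho, Oe, Ow, Hw — sugar carbon, carbon-bound H,
hydroxyl O/H, ether O, water O/H) and a fine `role` naming the chemical
position (C1…O5, HO3, O4a/O4b for the anomer-specific linkage oxygen, primed
roles for the non-reducing ring). Hydroxyl and water hydrogens are flagged
exchangeable; only they respond to isotopomer schemes.

## Synthetic ensembles

The generator *poses* structure geometrically instead of simulating dynamics:
the analysis stages consume only coordinates, so a posed ensemble with known
statistics is the appropriate validation fixture. Defaults are the study
conditions: 20 solutes (40% α), 63 waters per solute, 0.103018 atoms Å⁻³
(cubic box, edge ≈ 35.68 Å for the full composition).

Per configuration: solutes are built with torsions drawn from Gaussians
centered on the syn conformer (φ_H 22°, ψ_H −40°, σ 10° — a realistic spread
for a "fairly tight" solution distribution) and hydroxymethyl torsions from a
gt/gg/tg categorical (defaults ω (0.45, 0.33, 0.22), ω′ (0.39, 0.42, 0.19))
with 12° angular jitter, then placed with random rigid poses under a 2.0 Å
heavy-atom overlap threshold (bounded retries, explicit packing error). With
Bernoulli probability p (`hbond_occupancy`, default 0.5) the HO3 proton is
posed on its 1.0 Å sphere about O3 at an exact target distance from O5′ drawn
from N(2.28 Å, 0.3 Å) clipped to the 1.5–3.1 Å shell; otherwise the proton
points away and a water hydrogen is placed in that shell instead (the donor
role is shared with solvent). Remaining waters fill the box uniformly with
overlap rejection. The degenerate settings (p = 1, all σ = 0) produce exact
distances, which pins the posing arithmetic in tests. Identical seeds give
bit-identical ensembles; all randomness flows from one root seed through
named substreams.

What the generator does **not** emulate: water orientational correlations
(h-bond network geometry), solute–water energetic correlations, and
finite-temperature intramolecular strain. Passing recovery tests therefore
validates the *analysis machinery*, not any claim about real cellobiose
thermodynamics; accepted-coordination numbers from posed waters
(e.g. Oh–Hw ≈ 1.5) are higher than refined-model values because posed waters
are orientationally random.

Seven default isotopomer schemes span the (solute-hydroxyl × water)
deuteration axes including 50/50 water mixtures; the exact experimental
scheme table is configurable, as per-class deuterium fractions.

## Scattering conventions

F(Q) is the interference-only Faber–Ziman sum with explicit (2 − δ)
off-diagonal factors, b in fm, F in fm², decaying to zero at high Q. Sears
coherent scattering lengths (H −3.739, D +6.671, C 6.646, O 5.803 fm) ship in
a text constants file. Transforms use trapezoid quadrature on uniform grids
(Q default 0.1–30 Å⁻¹ step 0.05; r default step 0.02 Å) with an optional
Lorch taper (default off for the forward transform, recommended for inverse
transforms of truncated data; the g(r) region below 0.5 Å and any transform
with Q_max < 15 Å⁻¹ are flagged in result metadata rather than trusted).
Curve files are two-column text with `#` headers recording pair, scheme, ρ
and convention.

RDF histograms use exact shell volumes (4π/3)(r₊³ − r₋³) rather than the
4πr²Δr approximation, right-inclusive bins, and one sparse-distance pipeline
for the inter/intra/all molecular modes so binning conventions cannot drift
between the quadrature and direct-counting coordination routes (they are
required to agree within one bin's worth of pairs). Intramolecular analyses
(the O5′···HO3 contact) use the same-molecule mode; solvent analyses exclude
same-molecule pairs.

## Refinement

Reference potentials: SPC/E water (ε_Ow 0.650 kJ/mol, σ_Ow 3.166 Å, charges
−0.8476/+0.4238) and a simplified neutral CHARMM-like sugar set
(Cs +0.2667, Oh −0.65/Ho +0.40, Oe −0.40; Lorentz–Berthelot mixing).
Electrostatics are shifted-force Coulomb with a 10 Å cutoff instead of Ewald
— adequate at desk scale and documented as a deviation from production
refinement codes. Restraints are flat-bottom harmonics (k = 500 kJ/mol/Ų
outside the tolerance): H1′–H4 at 2.205 ± 0.3 Å plus per-ring 1–4
chair-holding distances measured from the ideal chair (tolerance 0.2 Å).
Moves are molecule translations (0.25 Å), rigid rotations (20°) and torsion
pivots (10°) on the named torsions; Metropolis acceptance at fixed 298 K.
Site overlaps below 0.1 Å clamp the energy and set a flag instead of
overflowing.

The empirical-potential update deconvolves the per-dataset F(Q) residuals
into per-pair corrections by ridge-regularized least squares over the
Faber–Ziman weight matrix (the ridge ties the under-determined directions
toward zero; pairs invisible in every dataset are skipped and reported),
transforms each to r-space with the same sine kernel as the g(r) recovery,
scales by feedback × kT (feedback default 0.1, config-exposed) and clamps to
the amplitude cap (default 5 kJ/mol, playing the role of a refinement energy
ceiling). Zero residual is exactly a fixed point. A divergence guard halves
the feedback after five consecutive rises of the mean chi-squared. Model
F(Q) is ensemble-averaged over Monte Carlo snapshots within each outer
iteration; the first iteration is treated as equilibration and not
accumulated into the output ensemble.

The recovery experiment used in validation displaces a 64-water box's first
O–O peak by ≈0.3 Å with an S-shaped perturbation added to the *reference*
potential (repulsive inside / attractive outside the true first shell,
±2.5 kJ/mol). This displacement mechanism is chosen deliberately: it is
counteractable within the amplitude cap, unlike a displaced Lennard-Jones
core, whose ~20 kJ/mol wall no capped empirical potential could cancel —
refinement corrects imperfect reference potentials, it does not rebuild
hard cores. Three water-deuteration datasets (H₂O, HDO, D₂O) provide the
contrast that makes the per-pair deconvolution well-posed. Sixty-four waters
and ~50 k total moves keep the experiment at desk scale while leaving the
first-shell statistics sharp enough to locate peaks to ±0.02 Å by parabolic
interpolation.

## Spatial density functions

The local frame sits on a C–O–C fragment (default C1′–O5′–C5): origin at the
ring oxygen, x along the bisector pointing away from the carbons, z along the
plane normal signed so the hydroxymethyl carbon lies at +z, y completing the
right-handed set. Target positions are accumulated per molecule-frame into
(a) a normalized 3D Cartesian histogram (default 24³ voxels over the shell)
used for enclosed-fraction iso-levels and plane projections, and (b) a
spherical-harmonic expansion of the angular density (default l_max = 8,
64×32 angular grid) with sample-mean coefficients f_lm = ⟨Y*_lm⟩ and
negative-lobe clipping at reconstruction.

Enclosed-fraction levels are defined on the superlevel sets of the voxel
density; for exactly tied densities (uniform fields) the enclosed *mass* is
computed from the minimal top-k voxel set, which is what an iso-surface
drawn at that level encloses. Levels are monotone non-increasing in the
fraction. Shell probability (not absolute water count) is the normalization
for fraction statements such as "the most probable 80%"; projections can
instead use a per-molecule-frame scale, which is the comparable intensity
convention for side-by-side maps of differently hydrated sites.

## NMR machinery

The glycosidic Karplus curves are the H–C–O–C cosine polynomial
³J = 7.49cos²θ − 0.96cosθ + 0.15 Hz for φ_H and the same curve with the
linear-cosine sign flipped (a 180° phase) for ψ_H, whose torsion is reported
with a negative sign for the syn conformer. Both reproduce the published
torsion/coupling pairs for cellobiose to the printed 0.1° precision, which
is how the parameterization was pinned. The hydroxymethyl relationships are
Stenutz-type Fourier forms in ω (see `data/karplus.yaml`); the `KarplusCurve`
container accepts the extra sin/cos(2ω) terms those need.

Inversion brackets roots on a fine grid and polishes with Brent's method;
the branch default is 0–90° (the syn region). The φ-type curve has an
interior extremum near 86°, so couplings just above the branch minimum are
genuinely two-valued there — inversion raises an explicit ambiguity error
rather than picking silently, and a coupling at the extremum returns the
extremal angle with a one-sided uncertainty. Uncertainties propagate as the
half-spread of inverting J ± ΔJ and therefore grow as |dJ/dθ|⁻¹.

The rotamer solver treats measured ³J_H5,H6R/³J_H5,H6S as population-weighted
averages over the three staggered conformers and solves the 3×3 linear
system with ΣP = 1; small negative populations (measurement noise) are
clamped to zero, renormalized and flagged. J-modulated intensity fitting
restricts J to the alias-free band of the mixing-time design and seeds the
nonlinear fit from a grid search; an all-zero series raises a degenerate-fit
error.

## Problem sizes used in validation

Parameter-recovery checks run the full 20-solute/1260-water composition over
200 configurations per occupancy setting; the refinement experiments use 64
waters (peak recovery) and 5 solutes/315 waters (restraint maintenance);
spherical-harmonic fidelity uses 5 solutes over 20 configurations. These
sizes give sampling errors comfortably inside each stated tolerance
(binomial error ~0.008 on occupancy at n = 4000, for instance) while keeping
the whole validation suite at desk scale.

## Known limitations

- The generator's waters are orientationally random; solvent-orientation
  observables (accepted hydrogen-bond counts, O–H angular distributions) are
  not faithful to refined models.
- Shifted-force electrostatics and the small cutoff bias long-range
  structure; the refinement loop absorbs part of this into the empirical
  potential, as it does for any imperfect reference.
- The per-pair deconvolution is under-determined when few isotopomer
  datasets are supplied; the ridge then damps the update rather than
  inventing structure, so convergence slows gracefully.
- The idealized chair geometry is not a substitute for a crystallographic
  seed when absolute intramolecular distances below ~0.1 Å matter.
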