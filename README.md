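# solvshell

Solution-structure analysis of carbohydrate hydration, built around the
cellobiose–water system: neutron-weighted total structure factors with H/D
isotopomer contrast, a simplified empirical-potential Monte Carlo refinement,
radial-distribution / coordination-number / spatial-density analysis, and
Karplus-equation NMR machinery for glycosidic torsions and hydroxymethyl
rotamer populations.

## Who this is for

Neutron-scattering and NMR practitioners who study the solution structure of
small saccharides — in particular the question of whether the intramolecular
O5′···HO3 hydrogen bond across the β-(1→4) linkage persists in water, and how
its occupancy, the glycosidic torsions (φ_H, ψ_H) and the hydroxymethyl
rotamer populations (gt/gg/tg) can be extracted from diffraction-refined
structural models and from scalar couplings.

Because measured neutron datasets for such systems are rarely deposited, the
package ships a synthetic-ensemble generator that emulates the refined
structural model of a 20-disaccharide (8 α, 12 β) / 1260-water periodic box at
0.103018 atoms Å⁻³, with *known, tunable* structural parameters — hydrogen-bond
occupancy, torsion distributions, rotamer populations — so every analysis
stage can be validated by parameter recovery.

## The model

**Scattering.** For atom classes α, β with number fractions c and coherent
scattering lengths b (fm), the interference-only total structure factor is the
Faber–Ziman sum

    F(Q) = Σ_{α≤β} (2 − δ_αβ) c_α c_β b_α b_β (S_αβ(Q) − 1)

and each partial structure factor is the sine-transform pair of its radial
distribution function g_αβ(r) at atomic number density ρ:

    S(Q) = 1 + (4πρ/Q) ∫ r (g(r) − 1) sin(Qr) dr
    g(r) = 1 + 1/(2π²ρr) ∫ Q (S(Q) − 1) sin(Qr) dQ

Isotopic H/D substitution enters through effective scattering lengths,
b = (1−f)·b_H + f·b_D for an exchangeable hydrogen class with deuterium
fraction f; the sign contrast (b_H < 0 < b_D) is what separates atom-pair
correlations between chemically identical samples.

**Coordination numbers.** The average count of β atoms around an α atom over
a radial shell [r₁, r₂] is n̄ = 4πρc_β ∫ g(r) r² dr, computed both by
quadrature and by direct neighbor counting (the two must agree).

**Refinement.** A Metropolis Monte Carlo engine samples the box under
reference potentials (SPC/E-type water, simplified CHARMM-like sugar sites,
harmonic distance restraints including H1′–H4 at 2.205 Å and ⁴C₁
chair-holding 1–4 distances). An empirical pair potential is iterated in
proportion to the F(Q) residual between model and target datasets, with the
per-pair correction deconvolved from multiple isotopomer datasets through
their Faber–Ziman weights.

**NMR.** Karplus curves ³J(θ) = A cos²θ + B cosθ + C (+ Fourier terms for the
hydroxymethyl relationships) are inverted for torsion angles on a stated
branch, three-state gt/gg/tg rotamer populations are solved from averaged
³J_H5,H6R / ³J_H5,H6S couplings, and J-modulated HMBC intensity series
I(τ) = A sin(πJτ) are fit for J. All numeric Karplus coefficients live in a
config-resident constants file (`src/solvshell/data/karplus.yaml`).

## Worked example

Invert the measured interglycosidic couplings of the concentrated (0.88 M)
sample for the glycosidic torsions:

```
$ solvshell nmr invert --j 4.58 --dj 0.16 --curve phi_H
phi_H: 33.3 +/- 1.4 deg (branch (0.0, 90.0))
$ solvshell nmr invert --j 5.32 --dj 1.15 --curve psi_H
psi_H: -39.7 +/- 8.4 deg (branch (0.0, 90.0))
```

i.e. a syn-φ_H/ψ_H conformation near (33°, −40°). Solve rotamer populations
from averaged hydroxymethyl couplings:

```
$ solvshell nmr rotamers --jr 5.81 --js 1.91
P_gt=0.53 P_gg=0.42 P_tg=0.05
```

Generate a synthetic 20-solute/1260-water ensemble (20 configurations,
hydrogen-bond occupancy posed at 0.5) and analyze it:

```
$ solvshell simulate --config run.yaml --out demo
$ solvshell coord    --config run.yaml --out demo
$ solvshell torsions --config run.yaml --out demo
$ cat demo/coordination.tsv
# pair	n_bar
Ho-Ow	0.877935959542051
Oh-Hw	1.4655130250649653
O5p-HO3(intra)	0.5505921519869863
$ cat demo/torsions.tsv
# torsion	peak_mean	gaussian_mean	gaussian_sigma	n
phi_H	21.0	22.06687253578079	10.428195979922592	400
psi_H	-40.0	-40.166655651901294	10.091217303324603	400
omega_rotamers	gt=0.485	gg=0.315	tg=0.2	-
omega_p_rotamers	gt=0.3575	gg=0.4575	tg=0.185	-
```

Reading these: each solute hydroxyl donates ≈0.9 hydrogen bonds to water
(Ho–Ow coordination over 0–2.46 Å); the intramolecular O5′···HO3 coordination
over 1.5–3.1 Å recovers the posed 0.5 occupancy within sampling error; and
the glycosidic torsion distributions recover the posed (22°, −40°) centers by
both the peak-average and Gaussian-fit reductions.

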