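# Karplus parameterizations, Hz.  3J(theta) = A cos^2(x) + B cos(x) + C
#   + sin1 sin(x) + cos2 cos(2x) + sin2 sin(2x),  x = theta + phase (degrees).
#
# phi_H / psi_H: three-bond H-C-O-C coupling across the glycosidic linkage
# (Cloran-type cosine polynomial).  The psi_H curve differs from phi_H only by
# the sign of the linear cosine term (a 180-degree phase); psi_H torsions are
# reported with a negative sign for the syn conformer.
phi_H:
  A: 7.49
  B: -0.96
  C: 0.15
psi_H:
  A: 7.49
  B: 0.96
  C: 0.15
  report_sign: -1
# Hydroxymethyl 3J_H5,H6R / 3J_H5,H6S curves as functions of the omega torsion
# (O5-C5-C6-O6), Stenutz-type Fourier forms used by the three-rotamer
# population solver at the staggered references +65 / -65 / 180 degrees.
H5H6R:
  A: 0.0
  B: 0.47
  C: 5.08
  sin1: 0.90
  cos2: -0.12
  sin2: 4.86
H5H6S:
  A: 0.0
  B: -1.29
  C: 4.92
  sin1: 0.05
  cos2: 4.58
  sin2: 0.07
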