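# Coherent neutron scattering lengths, femtometres (bound-atom values,
# Sears compilation). H is negative, D positive: this sign contrast is the
# basis of H/D isotopic-substitution experiments.
H: -3.7390
D: 6.671
C: 6.6460
N: 9.36
O: 5.803
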