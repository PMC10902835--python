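# Stillinger-Weber parameters for the mW coarse-grained water model
# (Molinero & Moore monatomic water). Energies in kJ/mol, lengths in Å,
# shape constants dimensionless. Interaction range is a_cut * sigma.
epsilon = 25.89488          # 6.189 kcal/mol
sigma = 2.3925
a_cut = 1.8
A = 7.049556277
B = 0.6022245584
p = 4.0
q = 0.0
lambda3 = 23.15
gamma3 = 1.2
cos_theta0 = -0.3333333333333333
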