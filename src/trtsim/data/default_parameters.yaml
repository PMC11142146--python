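# Reference ("basic") model parameters.
#
# Unit system: time in days, volumes in ml, amounts in pmol,
# concentrations in nM, cell counts in units of 1e7 cells.
#
# lambda_decay  radionuclide decay rate, 1/day (^225Ac, half-life ~9.9 d)
# k_on          antibody-receptor binding rate, 1/(nM day)
# kappa_c       intact-antibody clearance rate, 1/day
# kappa_p       antibody-fragment clearance rate, 1/day
# gamma         receptors per 1e7 cancer cells, pmol
# V             volume of drug distribution, ml
# nu            lesion volume per 1e7 cancer cells, ml
# k_s           relative significance of self-damage, dimensionless [0, 1]
# rho           viable-cell proliferation rate, 1/day
# omega         damaged-cell death rate, 1/day
# alpha         cancer-cell radiosensitivity, per (nuclide decay concentration)
# k_f           significance of unanchored-nuclide decays, dimensionless
# eta           drug impurity: inert antibodies per radioconjugate
# N0            initial viable cells, 1e7 cells
# N_cur         cure threshold, 1e7 cells (1e-9 = 0.01 cell)
# C_d           lethal burden, 1e7 cells (1e4 = 1e11 cells)
# A_bl_cr       lethal cumulative decays in blood, pmol (~230 nCi equivalent)

lambda_decay: 0.07
k_on: 11.15
kappa_c: 0.1
kappa_p: 1.0
gamma: 2.1
V: 1.0
nu: 0.015
k_s: 0.3
rho: 0.34
omega: 0.05
alpha: 500.0
k_f: 0.05
eta: 1780.0
N0: 3.0
N_cur: 1.0e-9
C_d: 1.0e4
A_bl_cr: 0.0175
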