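"""Simulate one treatment course and inspect its endpoints.

A disseminated-cancer mouse (3e7 cells) receives a single 63.2 nCi pure
radioconjugate bolus at t=0. The printed numbers are the minimum of viable
cells (cure means < 0.01 cell = 1e-9 units), the time of that minimum, and
where the injected nuclides ended up decaying.
"""

from trtsim import DoseSchedule, ModelParameters, simulate
from trtsim.analytics import activity_nCi_from_pmol

params = ModelParameters.basic()
dose = 0.0048  # pmol of radioconjugates
res = simulate(params, DoseSchedule.single(dose, eta=0.0), horizon=365.0)

final = res.final_state
print(f"dose: {dose} pmol = "
      f"{activity_nCi_from_pmol(dose, params.lambda_decay):.1f} nCi")
print(f"minimal viable cells: {res.n_min:.3e} x1e7 at day {res.t_nmin:.1f}")
print(f"cured (N_min < 0.01 cell): {res.cured}")
print(f"decays in blood: {final.cum_blood_decays:.2e} pmol "
      f"(lethal level {params.A_bl_cr} pmol)")
print(f"decays on viable cells: {100 * final.cum_viable_decays / dose:.2f}% "
      "of injected activity")
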