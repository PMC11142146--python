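"""Closed-form quantities: conversions, blood-decay split, safe doses.

Everything here is algebra on the reference parameters - the receptor count
behind gamma, the activity equivalent of the lethal blood-decay amount, the
fraction of a curative dose wasted in blood (and how much of that rides on
antibody fragments), and the worst-case safe dose bounds that no parameter
set within the physiologic ranges can breach.
"""

from trtsim import ModelParameters, analytics as an

p = ModelParameters.basic()
lam = p.lambda_decay

print(f"receptors per cell at gamma={p.gamma}: "
      f"{an.receptors_per_cell(p.gamma):,.0f}")
print(f"lethal blood decays {p.A_bl_cr} pmol = "
      f"{an.activity_nCi_from_pmol(p.A_bl_cr, lam):.0f} nCi of 225Ac")
print(f"impurity at 1.85 kBq/ug labeling: eta = "
      f"{an.eta_from_labeling_ratio(1.85):.0f}")

bd = an.blood_decay_fraction(p)
print(f"curative-dose blood decays: {100 * bd.total:.2f}% of activity, "
      f"{100 * bd.fragment / bd.total:.1f}% of that via fragments")
print(f"viable-decay share bound: "
      f"{100 * an.viable_fraction_bound(p.N0 * 1e7, 0.01):.2f}%")

for cap, label in ((0.0, "zero capacity"), (1e12, "saturating capacity")):
    nci = an.activity_nCi_from_pmol(an.max_safe_dose(cap, p), lam)
    print(f"maximal safe dose, {label}: {nci:.0f} nCi")
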