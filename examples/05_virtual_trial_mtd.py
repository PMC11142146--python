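"""In-silico trial: maximum tolerated dose and strategy comparison.

Samples 100 virtual mice from the physiologic parameter ranges, finds the
largest one-size-fits-all dose causing no toxicity deaths, and compares its
one-year survival with capacity-personalized dosing on the same population.
(The study-scale version of this experiment uses 1000 mice; see
scripts/acceptance.py.)
"""

from trtsim import trials
from trtsim.analytics import activity_nCi_from_pmol

pop = trials.sample_population(100, seed=5)
mtd = trials.find_max_tolerated_dose(pop, tol_nCi=1.0, top_k=15)
print(f"MTD on 100 mice: {mtd:.4f} pmol "
      f"= {activity_nCi_from_pmol(mtd, 0.07):.0f} nCi")

fixed = trials.run_trial(pop, trials.fixed_dose_strategy(mtd))
pers = trials.run_trial(pop, trials.personalized_strategy(
    use_true_capacity=True))
print(f"one-year survival, fixed MTD:     {fixed.one_year_survival:.2f}")
print(f"one-year survival, personalized:  {pers.one_year_survival:.2f} "
      f"(toxicity deaths: {pers.toxicity_death_rate:.2f})")
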