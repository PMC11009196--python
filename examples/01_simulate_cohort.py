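"""Generate a synthetic cohort and check its marginals.

The generator draws ages from a truncated normal whose realized mean/SD
match the configured targets, assigns sex and a latent vulnerability
factor, inverts each biomarker's coding rule to produce raw values whose
deficit prevalence rises with age and vulnerability, and draws death from
a logistic model. The intercept is calibrated so the death prevalence hits
its target.
"""

import numpy as np

import frailtykit as fk

dictionary = fk.default_data_dictionary()
config = fk.SimulationConfig(seed=11, n_participants=10_000)
config = fk.calibrate_mortality_intercept(config, dictionary)
cohort = fk.inject_missingness(fk.generate_cohort(config, dictionary),
                               config, dictionary)

w = cohort["weight"].to_numpy()
print(f"participants:        {len(cohort)}")
print(f"mean age (years):    {np.average(cohort['age'], weights=w):.1f}")
print(f"% female:            {100 * np.average(cohort['sex'] == 'female', weights=w):.1f}")
print(f"% died:              {100 * np.average(cohort['died'], weights=w):.2f}")
blood = dictionary.panel("blood").item_names
print(f"% missing blood panel: "
      f"{100 * cohort[blood].isna().all(axis=1).mean():.1f}")
# Expect ~59.4 years, ~50.3% female, ~3.1% deaths and ~10% missing blood
# panels: the marginal structure the downstream analysis assumes.
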