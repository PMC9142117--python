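"""Generate a small synthetic study region and look at what was planted.

The generator draws each area's covariates conditional on a latent
long-term-uninsured (LTU) quintile and then draws uninsured ED visit counts
from a Poisson law whose mean follows a linear model in that quintile, so
every downstream stage has an exact recovery target.
"""

from ltued import GeneratorConfig, generate_visits, generate_zcta_table

cfg = GeneratorConfig(n_zcta=50, seed=1, population_range=(1000, 5000), noise_fraction=0.5)
zcta, truth = generate_zcta_table(cfg)
records = generate_visits(zcta, truth, cfg)

print(f"{len(zcta)} areas, {len(records)} encounter records "
      f"({truth.n_qualifying} qualifying + {truth.n_noise} planted filter failures)")
print("\nPoverty share rises across the latent quintiles (mean % below poverty):")
print(zcta.groupby(truth.latent_quintile.to_numpy())["pct_below_200fpl"].mean().round(1))
print("\nEach row is one ED visit; qualifying rows carry an uninsured payer,")
print("an adult age and a valid area label:")
print(records.head(3).to_string(index=False))
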