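"""Score areas for long-term-uninsured concentration and rank into quintiles.

A fractional-response logistic model predicts each area's uninsured share
from the deprivation covariates; the inverse-logit predictions in (0, 1) are
ranked into five near-equal groups, Q1 lowest to Q5 highest concentration.
"""

from ltued import (
    GeneratorConfig, assign_quintiles, fit_propensity, generate_zcta_table,
    score_propensity,
)

zcta, truth = generate_zcta_table(GeneratorConfig(n_zcta=100, seed=2))
model = fit_propensity(zcta)
print("propensity coefficients (logit scale):")
print(model.params.round(4))

assignments = assign_quintiles(score_propensity(model, zcta))
print("\nquintile sizes (remainder goes to the lowest quintiles):")
print(assignments.groupby("quintile").size().tolist())

agree = (
    assignments.set_index("zcta_id")["quintile"].loc[truth.latent_quintile.index]
    == truth.latent_quintile
).mean()
print(f"\n{agree:.0%} of areas land in exactly their latent quintile; "
      "misclassification is what attenuates downstream effect estimates.")
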