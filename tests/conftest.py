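"""Shared fixtures: a small synthetic run and its full analysis chain."""

import pandas as pd
import pytest

from ltued import (
    DesignSpec,
    GeneratorConfig,
    assign_quintiles,
    build_design,
    compute_rates,
    filter_encounters,
    fit_ols_robust,
    fit_propensity,
    generate_visits,
    generate_zcta_table,
    score_propensity,
    tabulate_conditions,
)


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    return GeneratorConfig(
        n_zcta=40, population_range=(500, 3000), noise_fraction=0.25, seed=7
    )


@pytest.fixture(scope="session")
def small_run(small_config):
    """(zcta_table, truth, records) for a 40-area synthetic world."""
    zcta, truth = generate_zcta_table(small_config)
    records = generate_visits(zcta, truth, small_config)
    return zcta, truth, records


@pytest.fixture(scope="session")
def small_analysis(small_config, small_run):
    """Full downstream chain on the small run: assignments, panel, fits, designs."""
    zcta, truth, records = small_run
    model = fit_propensity(zcta)
    assignments = assign_quintiles(score_propensity(model, zcta))
    kept, tally = filter_encounters(records, zcta["zcta_id"])
    top = tabulate_conditions(kept, 15)
    panel = compute_rates(kept, zcta, [c for c, _ in top])
    fits, designs = {}, {}
    for cond in panel.conditions:
        y, X, terms = build_design(panel, zcta, assignments, DesignSpec.for_condition(cond))
        fits[cond] = fit_ols_robust(y, X, terms, condition=cond)
        designs[cond] = X
    return {
        "zcta": zcta,
        "truth": truth,
        "records": records,
        "assignments": assignments,
        "tally": tally,
        "panel": panel,
        "fits": fits,
        "designs": designs,
    }


@pytest.fixture()
def toy_zctas() -> pd.DataFrame:
    """Three areas with round populations for exact-arithmetic checks."""
    return pd.DataFrame(
        {
            "zcta_id": ["A", "B", "C"],
            "pop_year1": [1000, 500, 2000],
            "pop_year2": [1000, 500, 2000],
        }
    )
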