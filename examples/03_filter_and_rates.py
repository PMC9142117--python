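"""Apply the inclusion filters and compute two-year visit rates per 1000.

Kept encounters are uninsured (self-pay or indigent/charitable), adult
(18-64) and carry a valid area label; each exclusion is attributed to the
first failed criterion in the fixed order payer -> age -> area.  The rate is
1000 * visits / (pop_year1 + pop_year2) for every area x condition cell.
"""

from ltued import (
    GeneratorConfig, compute_rates, filter_encounters, generate_visits,
    generate_zcta_table, tabulate_conditions,
)

cfg = GeneratorConfig(n_zcta=60, seed=3, population_range=(1000, 5000), noise_fraction=0.5)
zcta, truth = generate_zcta_table(cfg)
records = generate_visits(zcta, truth, cfg)

kept, tally = filter_encounters(records, zcta["zcta_id"])
print(f"kept {tally.n_kept} of {tally.n_input} encounters "
      f"(payer {tally.excluded_payer}, age {tally.excluded_age}, "
      f"area {tally.excluded_area} excluded); conserved={tally.conserved}")

top = tabulate_conditions(kept, 5)
print("\ntop 5 conditions by visit count:")
for cond, n in top:
    print(f"  {cond:30s} {n:6d}")

panel = compute_rates(kept, zcta, [c for c, _ in top])
print("\nper-area rates per 1000 over the two study years (first rows):")
print(panel.rates.head(3).round(2).to_string())
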