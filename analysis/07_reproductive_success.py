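"""Demographic growth rates and the migrant-vs-resident fitness comparison:
negative-binomial regression of offspring number on dispersal status."""

import pedconnect as pc
from pedconnect import connectivity as conn
from pedconnect import demofit
from common import load_pedigree, load_qc, save


def main():
    g, records = load_qc()
    census = demofit.census_counts(records)
    save(census, "census_counts.tsv")
    growth = demofit.growth_rates(census)
    save(growth.to_frame().round(2), "growth_rates.tsv")
    print(f"median annual growth rate per patch: {growth.medians.round(2).to_dict()}")

    ped = load_pedigree()
    events = conn.events_to_frame(conn.events_from_pedigree(ped).events)
    fr = demofit.fitness_records(ped, events, last_years_excluded=2)
    save(fr, "fitness_records.tsv", index=False)
    model = demofit.fitness_model(fr)
    save(model.summary_frame().round(4), "fitness_model.tsv")
    means = model.group_means
    print(
        f"migrant-derived plants averaged {means.get('migrant', float('nan')):.2f} "
        f"offspring vs {means.get('resident', float('nan')):.2f} for residents; "
        f"rate ratio {model.rate_ratio:.2f} "
        f"[{model.ci_low:.2f}, {model.ci_high:.2f}], p = {model.p_value:.3f}"
    )


if __name__ == "__main__":
    main()
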