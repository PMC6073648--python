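"""End-to-end synthetic study: simulate -> age-adjust -> summary table.

Generates four archetype sites (150 men each), projects wives and wealth
to their completed (age-60) values, and prints the per-population summary
with 90% intervals plus subsistence means — the shape of a comparative
wealth/polygyny table.
"""

from polythresh import age_adjust_dataset, generate_multisite
from polythresh.report import table_report
from polythresh.simulate import SimConfig, archetype_config

config = SimConfig(
    populations=tuple(
        archetype_config(sub, f"{sub}_1", n_males=150)
        for sub in ("foraging", "horticulture", "agropastoral", "agriculture")
    )
)
dataset = generate_multisite(config, seed=7)
completed = age_adjust_dataset(dataset, seed=8, n_draws=400)
table = table_report(dataset, completed)

cols = ["population_id", "subsistence", "gini_median", "proportion_rich_median",
        "polygyny_median", "polygyny_over60"]
print(table.populations[cols].round(2).to_string(index=False))
print("\nsubsistence means:")
print(table.subsistence_means.round(2).to_string(index=False))
print("\nThe agricultural archetype shows the highest wealth Gini but the\n"
      "smallest proportion rich; completed polygyny tracks the proportion\n"
      "rich, not the Gini.")
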