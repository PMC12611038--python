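"""Stage-wise nutrient demand from a destructive-harvest series.

Generates a synthetic harvest (7 phenological stages × 7 tissues), sums
concentration × dry mass into whole-plant nutrient content (AWP, g per
tree), differences consecutive stages into demand (DTS) and expresses each
interval as a share of the season's total (RTS, %); finally converts the
season demand into nutrient uptake per 1000 kg of fruit.
"""

from vinefert import ExperimentScenario, generate_harvest_series, stage_demand_table, uptake_per_yield
from vinefert.synthetic import mean_tree

scenario = ExperimentScenario(seed=1, n_years=1, n_trees=1)
tree = mean_tree(generate_harvest_series(scenario))

demand = stage_demand_table(tree)
print("nitrogen demand by interval (g per tree, % of season):")
print(demand.loc["N"][["dts", "rts"]].round(2).to_string())

season = demand.groupby(level="element")["dts"].sum()
ms_fruit = tree[(tree["stage"] == "MS") & (tree["tissue"] == "fruit")]
fruit = (ms_fruit["concentration"] * ms_fruit["dry_mass"] / 1000.0).groupby(
    ms_fruit["element"]
).sum()
uptake = uptake_per_yield(season, scenario.yield_kg, fruit)
print("\nuptake per 1000 kg fruit (kg) and the fruit's share of it:")
print(uptake.round(4).to_string())
print("\nHigh Ca and K uptake with a modest P requirement is typical for grape.")
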