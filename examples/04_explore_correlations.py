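"""Correlation and principal-component view of the predicted means.

Uses the (genotype, environment) BLUP matrix — 36 observations when 18
genotypes meet 2 environments — so drought responses separate from control
along the leading components.
"""

from mgidi import (
    fit_all_traits,
    genotype_environment_blup_matrix,
    pca,
    pearson_matrix,
    percent_change,
    preset_wheat_drought,
    simulate_met,
)

config = preset_wheat_drought(seed=7)
data, _ = simulate_met(config)
cell = genotype_environment_blup_matrix(fit_all_traits(data))

corr = pearson_matrix(cell)
print("Pearson correlations (significant at 5% flagged *, 1% **):")
print(corr.flagged().loc[["GY", "pc", "Na", "TPC"], ["GY", "pc", "Na", "TPC"]])

res = pca(cell)
print(f"\nfirst two components explain {res.pc12_pct:.1f}% of total variation")
print("\nper-variable contribution to the leading plane (%):")
print(res.leading_contribution.sort_values(ascending=False).round(1).to_string())

ctrl = cell.xs("E1", level="environment")["pc"].mean()
drought = cell.xs("E2", level="environment")["pc"].mean()
print(f"\nmean proline: control {ctrl:.0f} -> drought {drought:.0f} ug/g "
      f"({percent_change(ctrl, drought):+.1f}%)")
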