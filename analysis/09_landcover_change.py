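"""Land-cover change accounting: net rates, transitions, met coupling.

Finding: sparse-vegetation <-> bare-ground flips dominate the transition
ranking and their annual net rates correlate with water availability
(positive for sparse vegetation, negative for bare ground), mirroring
drought-driven degradation; scripted bare->crops conversions appear as
cropland expansion.
"""

from _common import reference_run, outdir
from vegwater.landcover import top_transitions

out = outdir("09_landcover")
res = reference_run()

res.landcover_stats.net_rate_km2.to_csv(out / "net_rates_km2.csv")
res.landcover_stats.cumulative_pct.to_csv(out / "cumulative_change_pct.csv")
res.transition.to_csv(out / "transition_matrix_km2.csv")
top = top_transitions(res.transition, k=5)
top.to_csv(out / "top_transitions.csv", index=False)
res.landcover_met_correlation.to_csv(out / "netrate_met_correlation.csv",
                                     index=False)

print("top land-cover transitions (first vs last year):")
print(top.to_string(index=False))
key = res.landcover_met_correlation.set_index(["class", "parameter"])
for cls in ("shrubs/sparse vegetation/grassland", "bare"):
    r12 = key.loc[(cls, "ai_12")].r
    print("net rate of %-36s vs ai_12: R = %+.2f" % (cls, r12))
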