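"""Grade terra firme degradation with the structure index and account for loss.

Computes FDI = TCH + LCA + PC over terra firme cells, cuts it into
severe / moderate-to-high / light / intact at area-share quantiles
mirroring the published class areas, cross-tabulates the result against the
land-cover intact/degraded split, and derives per-class emission factors and
the regional biomass loss.
"""

from common import RESULTS, result

res = result()
fdi = res.fdi

fdi.fdi.to_ascii(RESULTS / "fdi.asc", fmt="%.1f")
fdi.class_raster.to_ascii(RESULTS / "fdi_classes.asc", fmt="%d")
fdi.summary.to_csv(RESULTS / "class_summary_fdi.csv", index=False)
res.summaries["confusion"].to_csv(RESULTS / "confusion_lulc_vs_fdi.csv")
loss = res.summaries["loss_fdi"]
loss.to_csv(RESULTS / "biomass_loss.csv", index=False)

print(f"FDI thresholds: {tuple(round(t, 1) for t in fdi.thresholds)}")
print(fdi.summary.round(2).to_string(index=False))
print("\nland-cover vs index classification (row %):")
print(res.summaries["confusion"].to_string())
print("\nemission factors and loss:")
print(loss.round(2).to_string(index=False))
total = loss.set_index("class").loc["all_degraded"]
print(f"\nregional biomass loss on the synthetic region: "
      f"{total['loss_mg']:,.0f} Mg over {total['area_ha']:,.0f} ha "
      f"({total['percent_reduction']:.1f}% below intact)")
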