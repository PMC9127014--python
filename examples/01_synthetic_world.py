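"""Generate a synthetic pension-register world and draw the two samples.

Builds the baseline two-region scenario (East DP prevalence 5%, West 3%,
ninefold DP/non-DP hazard ratio), materializes the ground-truth counts, and
draws the 1% stock (Bestand) and 10% death (Wegfall) record samples.
"""

from dpgap import build_true_counts, default_scenario, draw_sample

cfg = default_scenario(mode="stochastic", seed=1)
counts = build_true_counts(cfg)

dp_stock = counts.stock.subset("DP")
print(f"true DP stock, all cells/years:   {dp_stock.total():,.0f} person-records")
print(f"true DP deaths, all cells/years:  {counts.deaths.subset('DP').total():,.0f}")

bestand = draw_sample(counts, "stock", cfg.bestand_fraction, seed=2)
wegfall = draw_sample(counts, "death", cfg.wegfall_fraction, seed=3)
print(f"Bestand sample (1%):  {len(bestand):,} records "
      f"({(bestand.pension_type == 'disability').sum():,} disability)")
print(f"Wegfall sample (10%): {len(wegfall):,} records")

# Each Bestand record stands for ~100 pensioners, each Wegfall record for
# ~10 deaths; the samples mix disability pensions with other pension types,
# which the reconstruction stage must filter out.
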