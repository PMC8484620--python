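"""Simulate nine decades of deforestation and classify fragmentation.

Generates a clumped neutral landscape, clears it at a compound
-0.27 %/yr with edge-biased removal, then classifies every forest
pixel into patch / edge / perforated / core1-3 (100 m edge width,
250/500-acre core thresholds) and prints per-class areas per epoch.
"""

import fragtrack as ft

cfg = ft.SimulationConfig(rows=300, cols=300, pixel_size=30.0,
                          forest_fraction=0.57, clumpiness=3.0,
                          annual_rate=-0.27, epoch_years=(1930, 1975, 2000, 2020),
                          edge_bias=2.0, seed=7)
series = ft.simulate_series(cfg)

params = ft.FragParams()  # 100 m edge width, exact acre thresholds
for epoch in series:
    table = ft.class_area_summary(ft.classify_fragmentation(epoch, params))
    row = {k: round(v, 2) for k, v in table.areas_km2.items() if k != "nonforest"}
    print(epoch.epoch_year, row, f"total {table.total_forest_km2:.2f} km²")

print("\nClass areas always sum to the epoch's forest area exactly.")
print("Clearing perforates the tract: the large contiguous core (core3)")
print("collapses and most remaining forest ends up within 100 m of an opening.")
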