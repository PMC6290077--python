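"""Per-transcript report and map-ready output for a candidate transcript.

Picks one planted up-regulated transcript, tabulates its fold change and
significance in every dataset, and emits the geographic points (GeoJSON)
for the datasets where it is significant, coloured by the fold-change
category: down (<1), up_low (1-5), up_high (>5).
"""

import json
from pathlib import Path

from resistex import (
    SimulationConfig,
    map_points,
    map_points_to_geojson,
    simulate_integrated,
    transcript_report,
)

table, meta, truth = simulate_integrated(SimulationConfig(seed=42))
transcript = sorted(truth.planted_up)[0]

rep = transcript_report(table, meta, transcript, alpha=0.05)
print(f"{transcript}: significant in {rep.n_significant} of {len(rep.table)} datasets")
print(rep.table[["dataset_id", "fold_change", "log2_fc", "q_value", "country"]]
      .head(5).to_string(index=False))

points = map_points(table, meta, transcript, alpha=0.05)
categories = {}
for p in points:
    categories[p.category] = categories.get(p.category, 0) + 1
print(f"\nmap points: {len(points)} ({categories})")

out = Path("scratch/example_map.geojson")
out.parent.mkdir(parents=True, exist_ok=True)
out.write_text(json.dumps(map_points_to_geojson(points), indent=2), encoding="utf-8")
print(f"GeoJSON written to {out} — one point per significant dataset, with the")
print("category encoding the strength and direction of differential expression.")
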