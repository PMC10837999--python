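"""Immune-microbe association network with the five-criterion cascade.

Plants five naive-cohort-only microbe->immune effects in a synthetic
cohort, then runs the full screen: prevalence filter, correlation-module
binning, one interaction regression per marker x feature pair, and the
filter cascade (FDR < 0.2 on the overall F, adjusted R^2 > 0.25,
significant naive slope that differs from another cohort's slope, and
max |DFFITS| < 2 so no single participant drives an edge).
"""

from pathlib import Path

import microimmune as mi
from microimmune.pipeline import association_network, match_planted_edges

MARKERS = ["cd4_pd1_pct", "cd8_cd38_hladr_pct", "cd4_cd38_hladr_pct",
           "cd8_pd1_pct", "il6"]

cfg = mi.SynthConfig(seed=8, n_per_cell=40, gradient_strength=0.0,
                     cohort_effect_scale=0.0)
features = mi.synth.suggest_planted_features(cfg, 5)
cfg.planted_edges = [mi.PlantedEdge(f, m) for f, m in zip(features, MARKERS)]

table, tree, meta, panel, truth = mi.generate_dataset(cfg)
edges, fits, binning = association_network(table, meta, panel, week=0)

print(f"fitted {len(fits)} marker x feature models "
      f"({len(binning.modules)} correlation modules binned)")
print(f"edges surviving the cascade: {len(edges)}")
for e in edges:
    print(f"  {e.immune} {e.sign} {e.feature}   "
          f"(naive-slope p = {e.p_slope:.2g})")

recovered, false = match_planted_edges(edges, truth, binning)
print(f"\nplanted effects recovered: {recovered}/5, false edges: {false}")
print("each surviving edge is an association present in the untreated "
      "cohort and absent (or different) under therapy or in controls.")

g = mi.build_network(edges, immune_nodes=list(mi.MARKERS))
out = Path("scratch")
out.mkdir(exist_ok=True)
mi.export_network(g, out / "network.json", out / "edges.tsv")
print(f"\nnetwork written to {out / 'network.json'}; degree table:")
deg = mi.degree_table(g)
print(deg[deg["degree"] > 0].to_string(index=False))
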