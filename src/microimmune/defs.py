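"""Shared vocabulary: cohort labels, locations, and the immune marker panel.

The immune panel is the eight blood readouts used throughout the analyses:
six T-cell surface phenotypes (percent of parent CD4+/CD8+ T cells) covering
chronic activation (CD38+HLA-DR+), exhaustion (PD-1+) and mucosal trafficking
(CD103+), plus two plasma inflammation markers (IL-6 in pg/mL, CRP in mg/L).
"""

COHORTS = ("Naive", "Exp", "HC")
LOCATIONS = ("rural", "urban")
WEEKS = (0, 24)

#: T-cell percentage markers (values live in [0, 100]).
PCT_MARKERS = (
    "cd4_cd38_hladr_pct",
    "cd8_cd38_hladr_pct",
    "cd4_pd1_pct",
    "cd8_pd1_pct",
    "cd4_cd103_pct",
    "cd8_cd103_pct",
)

#: Plasma inflammation markers (non-negative concentrations).
PLASMA_MARKERS = ("il6", "crp")

MARKERS = PCT_MARKERS + PLASMA_MARKERS

#: CD4-lineage markers subject to missingness/imputation (the CD4 easy-count
#: assay can fail as a unit, so all three go missing together).
CD4_MARKERS = ("cd4_cd38_hladr_pct", "cd4_pd1_pct", "cd4_cd103_pct")
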