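"""End-to-end convenience wrappers over the module-level building blocks."""

from __future__ import annotations

import pandas as pd

from .defs import MARKERS
from .network import (
    AssociationEdge,
    CascadeThresholds,
    ModuleBinning,
    PairModelFit,
    bin_modules,
    filter_cascade,
    fit_all_pairs,
)
from .prep import filter_baseline, label_viremia, prevalence_filter

__all__ = ["association_network", "match_planted_edges"]


def association_network(table: pd.DataFrame, meta: pd.DataFrame,
                        panel: pd.DataFrame, week: int = 0,
                        thresholds: CascadeThresholds | None = None,
                        prevalence: float = 0.2, min_r: float = 0.35,
                        mode: str = "naive_specific",
                        reference: str = "Naive",
                        ) -> tuple[list[AssociationEdge], list[PairModelFit], ModuleBinning]:
    """One timepoint's immune-microbe association analysis, end to end.

    Applies viremia labeling and the baseline exclusion rules, restricts to
    the requested week, prevalence-filters the (non-rarefied) count table,
    bins co-correlated features into modules, fits every marker x feature
    interaction model, and runs the filter cascade. In ``exp_vs_hc`` mode
    the naive cohort is excluded and the reference is the experienced
    cohort.
    """
    flagged = label_viremia(meta)
    retained, _ = filter_baseline(flagged)
    keep = flagged["pid"].isin(retained) & (flagged["week"] == week)
    if mode == "exp_vs_hc":
        keep &= flagged["cohort"] != "Naive"
        reference = "Exp"
    ids = flagged.index[keep].intersection(table.index).intersection(panel.index)
    sub_table = prevalence_filter(table.loc[ids], prevalence)
    binning, combined = bin_modules(sub_table, min_r=min_r)
    fits = fit_all_pairs(panel.loc[ids], combined, flagged.loc[ids],
                         markers=list(MARKERS), reference=reference,
                         timepoint=week)
    edges = filter_cascade(fits, thresholds, mode=mode)
    return edges, fits, binning


def match_planted_edges(edges: list[AssociationEdge], truth: dict,
                        binning: ModuleBinning) -> tuple[int, int]:
    """Count recovered planted edges and false edges.

    A planted (marker, feature) effect counts as recovered if an emitted
    edge names the same marker and either the feature itself or a module
    containing it. Every other emitted edge is false.
    """
    feature_of = {}
    for mod, members in binning.modules.items():
        for f in members:
            feature_of[f] = mod
    planted = {
        (e["marker"], feature_of.get(e["feature"], e["feature"]))
        for e in truth.get("planted_edges", [])
    }
    emitted = {(e.immune, e.feature) for e in edges}
    recovered = len(planted & emitted)
    false = len(emitted - planted)
    return recovered, false
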