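"""Immune-microbe association networks.

Pipeline: correlation-module binning of co-varying features, per-pair
interaction regressions of each immune marker on each microbial feature,
influence diagnostics, a five-criterion filter cascade, and bipartite
network assembly/export.

The per-pair model regresses an immune marker on the sample's total read
count (the analysis runs on non-rarefied counts, so depth is a nuisance
covariate), the feature's relative abundance, cohort, and the
feature-by-cohort interaction. Per-cohort slopes are the reference-cohort
slope plus the interaction coefficients; slope-difference tests are Wald
tests on those interaction coefficients. An association survives the
cascade iff (1) Benjamini-Hochberg FDR-adjusted p of the overall F is
below 0.2, (2) adjusted R-squared exceeds 0.25, (3) the reference-cohort
slope is significant at 0.05, (4) it differs from at least one other
cohort's slope at 0.05, and (5) max |DFFITS| < 2 (no single observation
drives the fit).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .prep import relative_abundance

__all__ = [
    "CascadeThresholds",
    "ModuleBinning",
    "PairModelFit",
    "AssociationEdge",
    "bin_modules",
    "fit_pair_model",
    "fit_all_pairs",
    "dffits",
    "filter_cascade",
    "build_network",
    "load_network",
]


@dataclass(frozen=True)
class CascadeThresholds:
    """The five filter-cascade thresholds (see module docstring)."""

    fdr_max: float = 0.2
    adj_r2_min: float = 0.25
    slope_p_max: float = 0.05
    interaction_p_max: float = 0.05
    dffits_max: float = 2.0

    def __post_init__(self):
        for name, v in asdict(self).items():
            if v <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class ModuleBinning:
    """Result of correlation-module binning: disjoint modules of >= 2
    co-correlated features, plus the settings used."""

    modules: dict[str, list[str]]
    min_r: float
    method: str = "spearman/complete-linkage"

    def membership(self) -> pd.DataFrame:
        rows = [
            {"module": mod, "feature": f}
            for mod, members in self.modules.items()
            for f in members
        ]
        return pd.DataFrame(rows, columns=["module", "feature"])


def bin_modules(table: pd.DataFrame, min_r: float = 0.35
                ) -> tuple[ModuleBinning, pd.DataFrame]:
    """Bin co-correlated features into summed modules.

    Pairwise Spearman correlation of relative abundances; complete-linkage
    agglomerative clustering on (1 - r); clusters cut so that every
    within-cluster pair satisfies r >= ``min_r``. Clusters with >= 2
    members become modules whose abundance is the element-wise sum of the
    member counts; remaining features pass through unbinned. Constant
    features (undefined correlation) are left unbinned with a warning.
    """
    if table.shape[1] < 2:
        raise ValueError("need at least 2 features to bin")
    rel = relative_abundance(table)
    constant = rel.columns[(rel.nunique() <= 1)]
    if len(constant):
        warnings.warn(
            f"{len(constant)} constant feature(s) left unbinned (correlation undefined)"
        )
    work = rel.drop(columns=constant)
    modules: dict[str, list[str]] = {}
    if work.shape[1] >= 2:
        r, _ = stats.spearmanr(work.to_numpy())
        r = np.atleast_2d(r)
        dist = 1.0 - r
        np.fill_diagonal(dist, 0.0)
        dist = np.clip((dist + dist.T) / 2, 0.0, None)
        z = linkage(squareform(dist, checks=False), method="complete")
        labels = fcluster(z, t=1.0 - min_r, criterion="distance")
        feat = np.asarray(work.columns)
        mod_no = 0
        for lab in np.unique(labels):
            members = sorted(feat[labels == lab])
            if len(members) >= 2:
                mod_no += 1
                modules[f"module_{mod_no:03d}"] = members
    binned = {f for members in modules.values() for f in members}
    singles = [f for f in table.columns if f not in binned]
    out = table[singles].copy()
    for mod, members in modules.items():
        out[mod] = table[members].sum(axis=1)
    return ModuleBinning(modules, min_r), out


@dataclass
class PairModelFit:
    """One immune-marker x microbial-feature interaction regression."""

    marker: str
    feature: str
    timepoint: int | None
    reference: str
    slopes: dict[str, float]            # per-cohort slope
    slope_p: dict[str, float]           # per-cohort slope p-values
    interaction_p: dict[str, float]     # slope-difference vs reference
    f_p: float                          # overall F vs depth-only null
    adj_r2: float
    max_abs_dffits: float
    n: int
    degenerate: bool = False
    fdr_p: float | None = None          # filled by filter_cascade


def dffits(residuals: np.ndarray, leverage: np.ndarray, n_params: int
           ) -> np.ndarray:
    """DFFITS from fitted-model internals.

    DFFITS_i = (externally studentized residual)_i * sqrt(h_i / (1 - h_i)).
    A perfect fit (all residuals zero) returns all zeros by the limit
    convention; exact leverage points (h_i = 1) report infinity.
    """
    e = np.asarray(residuals, dtype=float)
    h = np.asarray(leverage, dtype=float)
    n = len(e)
    out = np.zeros(n)
    rss = float(e @ e)
    scale = max(1.0, float(np.abs(e).max()) ** 2) if n else 1.0
    at_one = h >= 1.0 - 1e-12
    out[at_one] = np.inf
    if rss <= 1e-24 * scale:
        return out
    ok = ~at_one
    # deleted residual variance: remove observation i's contribution to RSS
    s2_del = (rss - e[ok] ** 2 / (1.0 - h[ok])) / (n - n_params - 1)
    s2_del = np.maximum(s2_del, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = e[ok] / np.sqrt(s2_del * (1.0 - h[ok]))
        out[ok] = t * np.sqrt(h[ok] / (1.0 - h[ok]))
    out[~np.isfinite(out) & ~at_one] = 0.0
    return out


def fit_pair_model(marker_values, feature_rel, cohorts, read_counts,
                   reference: str = "Naive", marker: str = "",
                   feature: str = "", timepoint: int | None = None
                   ) -> PairModelFit:
    """OLS of marker ~ read count + feature + cohort + feature x cohort.

    ``feature_rel`` is the feature's relative abundance per sample;
    ``read_counts`` the per-sample total (non-rarefied) read count. The
    cohort main effects and interactions are dummy-coded against
    ``reference``; per-cohort slopes and their p-values are derived from
    the reference slope plus the interaction coefficients. The overall F
    compares the model against the intercept + read-count null.
    """
    y = np.asarray(marker_values, dtype=float)
    f = np.asarray(feature_rel, dtype=float)
    rc = np.asarray(read_counts, dtype=float)
    coh = np.asarray(cohorts)
    levels = [reference] + sorted(c for c in pd.unique(coh) if c != reference)
    if reference not in coh:
        raise ValueError(f"reference cohort {reference!r} absent from data")
    if len(levels) < 2:
        raise ValueError("need at least 2 cohorts")
    for lev in levels:
        if (coh == lev).sum() < 3:
            raise ValueError(f"cohort {lev!r} has < 3 samples")
    n = len(y)
    others = levels[1:]
    dummies = np.column_stack([(coh == lev).astype(float) for lev in others]) \
        if others else np.empty((n, 0))
    x = np.column_stack([np.ones(n), rc, dummies, f, dummies * f[:, None]])
    k = x.shape[1]
    if n < k + 2:
        raise ValueError("too few samples for the interaction model")
    i_feat = 2 + len(others)
    i_inter = {lev: i_feat + 1 + j for j, lev in enumerate(others)}

    q, r = np.linalg.qr(x)
    rank = int((np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r).max())).sum())
    degenerate = rank < k
    if degenerate:
        warnings.warn(
            f"collinear design for ({marker}, {feature}); fit marked unusable"
        )
        return PairModelFit(marker, feature, timepoint, reference,
                            {lev: 0.0 for lev in levels},
                            {lev: 1.0 for lev in levels},
                            {lev: 1.0 for lev in others},
                            1.0, 0.0, np.inf, n, degenerate=True)

    beta = np.linalg.solve(r, q.T @ y)
    e = y - x @ beta
    rss = float(e @ e)
    df_res = n - k
    yc = y - y.mean()
    tss = float(yc @ yc)
    if tss <= 1e-24 * max(1.0, abs(y).max()) ** 2:
        # constant response: nothing to model
        return PairModelFit(marker, feature, timepoint, reference,
                            {lev: 0.0 for lev in levels},
                            {lev: 1.0 for lev in levels},
                            {lev: 1.0 for lev in others},
                            1.0, 0.0, 0.0, n, degenerate=True)
    s2 = rss / df_res
    rinv = np.linalg.inv(r)
    xtx_inv = rinv @ rinv.T
    cov = s2 * xtx_inv
    h = np.sum(q ** 2, axis=1)

    slopes, slope_p, inter_p = {}, {}, {}
    slopes[reference] = float(beta[i_feat])
    se_ref = np.sqrt(cov[i_feat, i_feat])
    slope_p[reference] = _t_p(beta[i_feat], se_ref, df_res)
    for lev in others:
        j = i_inter[lev]
        slopes[lev] = float(beta[i_feat] + beta[j])
        var = cov[i_feat, i_feat] + cov[j, j] + 2 * cov[i_feat, j]
        slope_p[lev] = _t_p(slopes[lev], np.sqrt(max(var, 0.0)), df_res)
        inter_p[lev] = _t_p(beta[j], np.sqrt(cov[j, j]), df_res)

    # overall F against the intercept + read-count null
    x0 = x[:, :2]
    b0, *_ = np.linalg.lstsq(x0, y, rcond=None)
    e0 = y - x0 @ b0
    rss0 = float(e0 @ e0)
    df_num = k - 2
    f_stat = ((rss0 - rss) / df_num) / (rss / df_res) if rss > 0 else np.inf
    f_p = float(stats.f.sf(f_stat, df_num, df_res)) if np.isfinite(f_stat) else 0.0

    r2 = 1.0 - rss / tss
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / df_res
    d = dffits(e, h, k)
    return PairModelFit(marker, feature, timepoint, reference, slopes,
                        slope_p, inter_p, f_p, float(adj_r2),
                        float(np.max(np.abs(d))), n)


def _t_p(est: float, se: float, df: int) -> float:
    if se <= 0:
        return 0.0 if est != 0 else 1.0
    return float(2 * stats.t.sf(abs(est) / se, df))


def fit_all_pairs(panel: pd.DataFrame, table: pd.DataFrame, meta: pd.DataFrame,
                  markers: list[str] | None = None,
                  reference: str = "Naive",
                  timepoint: int | None = None) -> list[PairModelFit]:
    """Fit the pair model for every (marker, feature) combination.

    ``table`` is the (non-rarefied, prevalence-filtered, possibly
    module-binned) count table; relative abundances and total read counts
    are derived from it. Rows are aligned on sample ID across inputs.
    """
    ids = table.index.intersection(panel.index).intersection(meta.index)
    table, panel, meta = table.loc[ids], panel.loc[ids], meta.loc[ids]
    if markers is None:
        markers = list(panel.columns)
    rel = relative_abundance(table)
    rc = table.sum(axis=1).to_numpy(dtype=float)
    coh = meta["cohort"].to_numpy()
    fits = []
    for marker in markers:
        y = panel[marker]
        mask = y.notna().to_numpy()
        for feature in table.columns:
            fits.append(fit_pair_model(
                y.to_numpy(dtype=float)[mask], rel[feature].to_numpy()[mask],
                coh[mask], rc[mask], reference=reference,
                marker=marker, feature=feature, timepoint=timepoint,
            ))
    return fits


@dataclass(frozen=True)
class AssociationEdge:
    """A surviving immune-microbe association (one network edge)."""

    immune: str
    feature: str
    sign: str                # '+' or '-': sign of the reference-cohort slope
    p_slope: float           # reference-cohort slope p-value
    width: float             # -log10(p_slope), the drawn edge width

    def to_dict(self) -> dict:
        return asdict(self)


def filter_cascade(fits: list[PairModelFit],
                   thresholds: CascadeThresholds | None = None,
                   mode: str = "naive_specific") -> list[AssociationEdge]:
    """Apply the five-criterion cascade to one timepoint's fits.

    The FDR family is all fits supplied (all marker x feature models of
    one timepoint); mixing timepoints is an error. ``mode``:

    * ``naive_specific`` — the reference (naive) slope must be significant
      and differ from at least one other cohort's slope;
    * ``exp_vs_hc`` — at least one of the two cohort slopes must be
      significant and the two must differ from each other.
    """
    if thresholds is None:
        thresholds = CascadeThresholds()
    if not fits:
        return []
    tps = {f.timepoint for f in fits}
    if len(tps) > 1:
        raise ValueError(f"fits span multiple timepoints: {sorted(tps)}")
    fdr = multipletests([f.f_p for f in fits], method="fdr_bh")[1]
    edges = []
    for fit, q in zip(fits, fdr):
        fit.fdr_p = float(q)
        if fit.degenerate:
            continue
        if not (q < thresholds.fdr_max and fit.adj_r2 > thresholds.adj_r2_min
                and fit.max_abs_dffits < thresholds.dffits_max):
            continue
        ref = fit.reference
        if mode == "naive_specific":
            ok = (fit.slope_p[ref] < thresholds.slope_p_max
                  and any(p < thresholds.interaction_p_max
                          for p in fit.interaction_p.values()))
        elif mode == "exp_vs_hc":
            ok = (any(p < thresholds.slope_p_max for p in fit.slope_p.values())
                  and any(p < thresholds.interaction_p_max
                          for p in fit.interaction_p.values()))
        else:
            raise ValueError("mode must be 'naive_specific' or 'exp_vs_hc'")
        if not ok:
            continue
        p_ref = fit.slope_p[ref]
        edges.append(AssociationEdge(
            immune=fit.marker, feature=fit.feature,
            sign="+" if fit.slopes[ref] >= 0 else "-",
            p_slope=p_ref,
            width=float(-np.log10(max(p_ref, 1e-300))),
        ))
    return edges


def build_network(edges: list[AssociationEdge],
                  immune_nodes: list[str] | None = None) -> nx.Graph:
    """Assemble the bipartite immune-microbe network.

    ``immune_nodes`` declares the marker panel so that markers without any
    surviving association still appear as isolated nodes.
    """
    seen = set()
    for e in edges:
        key = (e.immune, e.feature)
        if key in seen:
            raise ValueError(f"duplicate edge {key}")
        seen.add(key)
    g = nx.Graph()
    for m in immune_nodes or []:
        g.add_node(m, type="immune")
    for e in edges:
        g.add_node(e.immune, type="immune")
        g.add_node(e.feature, type="microbe")
        g.add_edge(e.immune, e.feature, sign=e.sign,
                   p_slope=e.p_slope, width=e.width)
    return g


def degree_table(g: nx.Graph) -> pd.DataFrame:
    rows = [{"node": n, "type": d["type"], "degree": g.degree(n)}
            for n, d in g.nodes(data=True)]
    return pd.DataFrame(rows, columns=["node", "type", "degree"])


def export_network(g: nx.Graph, out_json: str | Path,
                   out_tsv: str | Path | None = None) -> None:
    """Write the network as JSON (node + edge lists) and optionally an
    edge TSV."""
    payload = {
        "nodes": [{"id": n, "type": d["type"]} for n, d in sorted(g.nodes(data=True))],
        "edges": [
            {"immune": a if g.nodes[a]["type"] == "immune" else b,
             "feature": b if g.nodes[a]["type"] == "immune" else a,
             "sign": d["sign"], "p_slope": d["p_slope"], "width": d["width"]}
            for a, b, d in g.edges(data=True)
        ],
    }
    with open(out_json, "w") as fh:
        json.dump(payload, fh, indent=2)
    if out_tsv is not None:
        pd.DataFrame(payload["edges"]).to_csv(out_tsv, sep="\t", index=False)


def load_network(path: str | Path) -> nx.Graph:
    """Re-import a JSON export written by :func:`export_network`."""
    with open(path) as fh:
        payload = json.load(fh)
    edges = [AssociationEdge(e["immune"], e["feature"], e["sign"],
                             e["p_slope"], e["width"])
             for e in payload["edges"]]
    immune = [n["id"] for n in payload["nodes"] if n["type"] == "immune"]
    return build_network(edges, immune_nodes=immune)
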