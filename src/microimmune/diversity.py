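"""Alpha diversity, phylogenetic beta diversity, ordination, and
strata-restricted PERMANOVA.

Shannon entropy defaults to log base 2. Weighted UniFrac defaults to the
raw (unnormalized) variant: d(A, B) = sum over branches of
branch_length * |p_A - p_B|, where p_X is the fraction of sample X's reads
on leaves descending from the branch. PCoA drops negative eigenvalues from
both the coordinates and the proportion-explained denominator, and orients
each axis so the lexicographically smallest sample has a non-negative
coordinate (removing reflection nondeterminism). PERMANOVA partitions the
Gower-centered distance matrix sequentially (Type-I) over an ordered term
list, supports continuous and categorical covariates, and restricts
permutations to within-strata blocks when a strata variable is given.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import beta_diversity

__all__ = [
    "shannon",
    "weighted_unifrac",
    "pcoa",
    "biplot_features",
    "permanova",
    "OrdinationResult",
    "PermanovaResult",
]


def shannon(counts, base: float = 2.0) -> float:
    """Shannon entropy of one sample's feature counts (default: bits)."""
    c = np.asarray(counts, dtype=float)
    if c.sum() <= 0:
        raise ValueError("Shannon entropy needs a sample with positive total count")
    p = c[c > 0] / c.sum()
    return float(-(p * (np.log(p) / np.log(base))).sum())


def weighted_unifrac(table: pd.DataFrame, tree: TreeNode,
                     normalized: bool = False) -> DistanceMatrix:
    """Weighted UniFrac distances between all samples of a count table.

    ``table`` is samples x features; every feature must be a leaf of the
    rooted ``tree``. The default is the raw variant (see module docstring);
    ``normalized=True`` divides by the abundance-weighted total branch
    length, bounding distances by 1.
    """
    leaves = {n.name for n in tree.tips()}
    missing = [f for f in table.columns if f not in leaves]
    if missing:
        raise ValueError(f"features missing from tree: {', '.join(missing[:5])}")
    for node in tree.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            raise ValueError(f"negative branch length on node {node.name!r}")
    totals = table.sum(axis=1)
    if (totals <= 0).any():
        bad = ", ".join(table.index[totals <= 0])
        raise ValueError(f"samples with zero total count: {bad}")
    return beta_diversity(
        "weighted_unifrac",
        table.to_numpy(dtype=float),
        ids=list(table.index),
        taxa=list(table.columns),
        tree=tree,
        normalized=normalized,
    )


@dataclass
class OrdinationResult:
    """PCoA output: retained (positive) eigenvalues, per-axis proportion of
    explained variance, sample scores, and optional biplot feature scores."""

    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    samples: pd.DataFrame                     # index: sample ids, cols PC1..PCk
    features: pd.DataFrame | None = None      # biplot coordinates + importance

    @property
    def axes(self) -> list[str]:
        return list(self.samples.columns)


def pcoa(dm: DistanceMatrix, n_axes: int = 4) -> OrdinationResult:
    """Principal coordinates analysis via Gower double-centering.

    Eigendecomposition of -1/2 J D^2 J; coordinates are eigenvectors scaled
    by sqrt(eigenvalue) for positive eigenvalues only. Negative eigenvalues
    (non-Euclidean input) are excluded from the coordinates and from the
    proportion-explained denominator.
    """
    if n_axes < 1:
        raise ValueError("n_axes must be >= 1")
    d = np.asarray(dm.data, dtype=float)
    if not np.allclose(d, d.T) or np.any(np.diag(d) != 0):
        raise ValueError("input is not a valid distance matrix")
    ids = list(dm.ids)
    n = len(ids)
    g = _gower(d)
    eigvals, eigvecs = np.linalg.eigh(g)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(abs(eigvals[0]), 1.0) * 1e-10 if n else 0.0
    positive = eigvals > tol
    k = min(n_axes, int(positive.sum()))
    pos_sum = eigvals[positive].sum()
    if k == 0:
        k_out = min(n_axes, n)
        coords = np.zeros((n, k_out))
        retained = np.zeros(k_out)
        prop = np.zeros(k_out)
    else:
        retained = eigvals[:k]
        coords = eigvecs[:, :k] * np.sqrt(retained)
        prop = retained / pos_sum
        coords = _orient_axes(coords, ids)
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    samples = pd.DataFrame(coords, index=ids, columns=cols)
    return OrdinationResult(np.asarray(retained), np.asarray(prop), samples)


def _gower(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    a = -0.5 * d ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _orient_axes(coords: np.ndarray, ids: list[str]) -> np.ndarray:
    """Flip each axis so the lexicographically smallest sample scores >= 0
    (ties broken by the next sample in lexicographic order)."""
    order = np.argsort(np.asarray(ids, dtype=object))
    out = coords.copy()
    for ax in range(out.shape[1]):
        for i in order:
            v = out[i, ax]
            if v != 0:
                if v < 0:
                    out[:, ax] = -out[:, ax]
                break
    return out


def biplot_features(ord_result: OrdinationResult, rel_abund: pd.DataFrame
                    ) -> pd.DataFrame:
    """Feature coordinates for a PCoA biplot.

    Each feature is placed at the abundance-weighted mean of the sample
    scores (weights: that feature's relative abundance across samples,
    normalized to sum 1). Importance is the Euclidean norm over the
    retained axes; output is sorted by decreasing importance.
    """
    samples = ord_result.samples
    if set(rel_abund.index) != set(samples.index):
        raise ValueError("ordination and abundance tables cover different samples")
    rel = rel_abund.loc[samples.index]
    totals = rel.sum(axis=0)
    zero = totals == 0
    if zero.any():
        warnings.warn(
            f"excluding {int(zero.sum())} feature(s) with zero total abundance"
        )
        rel = rel.loc[:, ~zero]
        totals = totals[~zero]
    weights = rel.div(totals, axis=1)                      # columns sum to 1
    coords = weights.T @ samples                           # features x axes
    coords["importance"] = np.linalg.norm(coords.to_numpy(), axis=1)
    return coords.sort_values("importance", ascending=False)


@dataclass
class PermanovaResult:
    """Sequential (Type-I) distance-based ANOVA table."""

    table: pd.DataFrame          # index: terms + Residual + Total
    n_permutations: int
    strata: str | None = None

    def p_value(self, term: str) -> float:
        return float(self.table.loc[term, "p"])


def _term_matrix(meta: pd.DataFrame, term: str) -> np.ndarray:
    """Model-matrix columns for one term; ':' denotes an interaction."""
    parts = term.split(":")
    mats = []
    for part in parts:
        part = part.strip()
        if part not in meta.columns:
            raise ValueError(f"term {part!r} not in metadata")
        col = meta[part]
        if pd.api.types.is_numeric_dtype(col):
            x = col.to_numpy(dtype=float)[:, None]
            if np.allclose(x, x[0]):
                raise ValueError(f"term {part!r} is constant across samples")
        else:
            levels = sorted(col.astype(str).unique())
            if len(levels) < 2:
                raise ValueError(f"term {part!r} is constant across samples")
            x = np.column_stack([
                (col.astype(str) == lev).to_numpy(dtype=float)
                for lev in levels[1:]
            ])
        mats.append(x)
    out = mats[0]
    for m in mats[1:]:
        out = np.einsum("ij,ik->ijk", out, m).reshape(len(out), -1)
    return out


def _hat(x: np.ndarray) -> np.ndarray:
    q, r = np.linalg.qr(x)
    rank = int((np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r).max())).sum())
    q = q[:, :rank]
    return q @ q.T


def permanova(dm: DistanceMatrix, meta: pd.DataFrame, terms: list[str],
              strata: str | None = None, n_perm: int = 999,
              seed: int = 0) -> PermanovaResult:
    """Multi-term PERMANOVA with optional within-strata permutations.

    Terms are fitted sequentially in the order given (order-dependent
    sums of squares). The permutation p-value for each term is
    (1 + #{F* >= F_obs}) / (1 + n_perm), permuting sample labels of the
    distance matrix; with ``strata``, labels are shuffled only within
    strata blocks (e.g. participant), preserving the block structure.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    meta = meta.loc[list(dm.ids)]
    n = len(meta)
    g = _gower(np.asarray(dm.data, dtype=float))
    ss_total = float(np.trace(g))

    # cumulative hat matrices: intercept, then term by term
    hats = [np.full((n, n), 1.0 / n)]
    dfs = []
    x = np.ones((n, 1))
    for term in terms:
        x = np.hstack([x, _term_matrix(meta, term)])
        h = _hat(x)
        dfs.append(int(round(np.trace(h) - np.trace(hats[-1]))))
        hats.append(h)
    h_full = hats[-1]
    df_res = n - int(round(np.trace(h_full)))
    if df_res <= 0:
        raise ValueError("saturated model: no residual degrees of freedom")
    resid_proj = np.eye(n) - h_full
    term_projs = [hats[i + 1] - hats[i] for i in range(len(terms))]

    def f_stats(gm: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
        ss_terms = np.array([float(np.sum(p * gm)) for p in term_projs])
        ss_res = float(np.sum(resid_proj * gm))
        # a residual SS at cancellation-noise level is an exact fit: F = inf
        if ss_res <= 1e-12 * abs(ss_total):
            f = np.full(len(ss_terms), np.inf)
            return ss_terms, f, max(ss_res, 0.0)
        f = (ss_terms / np.asarray(dfs)) / (ss_res / df_res)
        return ss_terms, f, ss_res

    ss_terms, f_obs, ss_res = f_stats(g)
    # tie tolerance: permutations reproducing the observed partition must
    # count as exceedances despite float jitter
    f_thresh = np.where(np.isfinite(f_obs),
                        f_obs * (1 - 1e-9) - 1e-12, np.inf)

    rng = np.random.default_rng(seed)
    if strata is not None:
        blocks = [np.flatnonzero((meta[strata] == v).to_numpy())
                  for v in meta[strata].unique()]
        if all(len(b) == 1 for b in blocks):
            warnings.warn("all strata blocks have size 1: test is degenerate")
    exceed = np.zeros(len(terms))
    idx = np.arange(n)
    for _ in range(n_perm):
        if strata is None:
            perm = rng.permutation(n)
        else:
            perm = idx.copy()
            for b in blocks:
                perm[b] = b[rng.permutation(len(b))]
        gp = g[np.ix_(perm, perm)]
        _, f_perm, _ = f_stats(gp)
        exceed += f_perm >= f_thresh
    p = (1.0 + exceed) / (1.0 + n_perm)

    rows = []
    for i, term in enumerate(terms):
        rows.append({"df": dfs[i], "SS": ss_terms[i],
                     "R2": ss_terms[i] / ss_total, "F": f_obs[i], "p": p[i]})
    rows.append({"df": df_res, "SS": ss_res, "R2": ss_res / ss_total,
                 "F": np.nan, "p": np.nan})
    rows.append({"df": n - 1, "SS": ss_total, "R2": 1.0,
                 "F": np.nan, "p": np.nan})
    table = pd.DataFrame(rows, index=[*terms, "Residual", "Total"])
    return PermanovaResult(table, n_perm, strata)
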