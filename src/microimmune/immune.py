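"""Immune-marker statistics: rank-based group comparisons, the
cohort-by-week fixed-effects model with participant-clustered errors, and
backward-stepwise predictive models with forced-in covariates.

Notes on test choices:

* Inter-cohort comparisons use Kruskal-Wallis with a Dunn post hoc
  (tie-corrected z from pooled mean ranks; Benjamini-Hochberg adjustment
  within each pairwise family by default).
* Intra-cohort week-0 vs week-24 comparisons are paired; the paired rank
  test implemented here is the Wilcoxon signed-rank test (exact null for
  small n without ties, normal approximation with tie correction
  otherwise, zero differences dropped).
* The longitudinal linear model is OLS of marker ~ cohort * week with
  cluster-robust (sandwich) standard errors grouped by participant,
  using the G/(G-1) x (n-1)/(n-k) small-sample factor.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "kruskal_dunn",
    "paired_location_test",
    "fit_m1",
    "stepwise_select",
    "StepwiseResult",
]


def kruskal_dunn(values, groups, adjust: str | None = "fdr_bh") -> dict:
    """Kruskal-Wallis omnibus test with Dunn's pairwise post hoc.

    Returns the tie-corrected H statistic, omnibus p, and a pairwise table
    of Dunn z statistics with raw and (by default) Benjamini-Hochberg
    adjusted p-values. All-tied input is degenerate: H = 0, p = 1.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    for lab in labels:
        if (groups == lab).sum() < 2:
            raise ValueError(f"group {lab!r} has < 2 observations")
    if np.all(values == values[0]):
        pairs = pd.DataFrame(
            [{"group1": a, "group2": b, "z": 0.0, "p": 1.0, "p_adj": 1.0}
             for a, b in itertools.combinations(labels, 2)]
        )
        return {"H": 0.0, "p": 1.0, "pairwise": pairs, "degenerate": True}

    h, p_omni = stats.kruskal(*[values[groups == lab] for lab in labels])

    n = len(values)
    ranks = stats.rankdata(values)
    mean_rank = {lab: ranks[groups == lab].mean() for lab in labels}
    sizes = {lab: int((groups == lab).sum()) for lab in labels}
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (12.0 * (n - 1))
    rows = []
    for a, b in itertools.combinations(labels, 2):
        var = (n * (n + 1) / 12.0 - tie_term) * (1.0 / sizes[a] + 1.0 / sizes[b])
        z = (mean_rank[a] - mean_rank[b]) / np.sqrt(var)
        rows.append({"group1": a, "group2": b, "z": float(z),
                     "p": float(2 * stats.norm.sf(abs(z)))})
    pairs = pd.DataFrame(rows)
    if adjust is not None:
        pairs["p_adj"] = multipletests(pairs["p"], method=adjust)[1]
    else:
        pairs["p_adj"] = pairs["p"]
    return {"H": float(h), "p": float(p_omni), "pairwise": pairs,
            "degenerate": False}


def paired_location_test(week0: pd.Series, week24: pd.Series) -> dict:
    """Paired rank test of week-24 vs week-0 values matched by participant.

    Implemented as the Wilcoxon signed-rank test on within-participant
    differences. Pairs with a missing value are dropped; all-zero
    differences are degenerate (p = 1).
    """
    paired = pd.concat([week0.rename("w0"), week24.rename("w24")],
                       axis=1, join="inner").dropna()
    if len(paired) < 3:
        raise ValueError("need at least 3 complete pairs")
    diffs = (paired["w24"] - paired["w0"]).to_numpy()
    if np.all(diffs == 0):
        return {"statistic": 0.0, "p": 1.0, "n": len(paired), "degenerate": True}
    nz = diffs[diffs != 0]
    method = "exact" if (len(nz) <= 25 and len(np.unique(np.abs(nz))) == len(nz)) \
        else "approx"
    res = stats.wilcoxon(diffs, zero_method="wilcox", method=method,
                         correction=(method == "approx"))
    return {"statistic": float(res.statistic), "p": float(res.pvalue),
            "n": len(paired), "degenerate": False}


def _cluster_robust_cov(model, fit, groups: np.ndarray) -> np.ndarray:
    """Sandwich covariance clustered on ``groups`` with the
    G/(G-1) x (n-1)/(n-k) small-sample factor."""
    x = model.exog
    e = fit.resid.to_numpy() if hasattr(fit.resid, "to_numpy") else np.asarray(fit.resid)
    n, k = x.shape
    bread = np.linalg.inv(x.T @ x)
    meat = np.zeros((k, k))
    for g in pd.unique(groups):
        xg = x[groups == g]
        eg = e[groups == g]
        s = xg.T @ eg
        meat += np.outer(s, s)
    n_groups = len(pd.unique(groups))
    if n_groups < 2:
        raise ValueError("cluster-robust errors need >= 2 clusters")
    factor = (n_groups / (n_groups - 1)) * ((n - 1) / (n - k))
    return factor * bread @ meat @ bread


def fit_m1(panel: pd.DataFrame, meta: pd.DataFrame, response: str,
           location: str | None = None) -> pd.DataFrame:
    """Fixed-effects OLS of an immune marker on cohort, week, and their
    interaction, with participant-clustered standard errors.

    Reference levels are healthy controls and week 0, so the coefficients
    read as: each cohort's offset from HC at baseline, the change over
    time in HC, and each cohort's extra change over time relative to HC.
    ``location`` restricts the fit to one site (stratified analysis).
    Samples with a missing response are dropped (no imputation here).
    """
    data = meta.join(panel[[response]], how="inner").dropna(subset=[response])
    if location is not None:
        data = data[data["location"] == location]
    for col, ref in (("cohort", "HC"), ("week", 0)):
        levels = data[col].unique()
        if len(levels) < 2:
            raise ValueError(f"{col!r} has a single level in this stratum")
        if ref not in levels:
            raise ValueError(
                f"reference level {ref!r} of {col!r} is absent in this stratum"
            )
    formula = (f"{response} ~ C(cohort, Treatment('HC')) * C(week)")
    model = smf.ols(formula, data=data)
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        raise ValueError("singular design: some cohort x week cell is empty")
    fit = model.fit()
    cov = _cluster_robust_cov(model, fit, data["pid"].to_numpy())
    se = np.sqrt(np.diag(cov))
    coefs = fit.params
    df = len(pd.unique(data["pid"])) - 1
    tvals = coefs.to_numpy() / se
    pvals = 2 * stats.t.sf(np.abs(tvals), df)
    return pd.DataFrame({
        "coef": coefs, "se_cluster": se, "t": tvals, "p": pvals,
        "direction": np.sign(coefs),
    })


@dataclass
class StepwiseResult:
    """Final backward-elimination model plus an audit trace of every step."""

    response: str
    terms: list[str]
    forced: list[str]
    coef_table: pd.DataFrame
    model_p: float
    model_ns: bool            # overall F p >= 0.05 ("Model NS")
    criterion: str
    trace: list[dict] = field(default_factory=list)
    n: int = 0


def _term_label(data: pd.DataFrame, term: str) -> str:
    return f"C({term})" if not pd.api.types.is_numeric_dtype(data[term]) else term


def stepwise_select(data: pd.DataFrame, response: str, candidates: list[str],
                    forced: list[str] | None = None,
                    criterion: str = "aic",
                    p_threshold: float = 0.05) -> StepwiseResult:
    """Backward stepwise OLS feature selection with forced-in covariates.

    Starts from the full model (forced + candidates) and removes, one at a
    time, the candidate whose removal most improves the criterion
    (``"aic"``; or ``"p"`` drops the least-significant candidate while any
    exceeds ``p_threshold``). Forced-in terms are never removed. The final
    model is refit and reported with per-term p-values and an overall-F
    significance flag.
    """
    forced = list(forced or [])
    data = data.dropna(subset=[response] + forced + candidates).copy()
    usable = []
    for c in candidates:
        if not pd.api.types.is_numeric_dtype(data[c]) and data[c].nunique() < 2:
            warnings.warn(f"candidate {c!r} has a single level; dropped")
            continue
        usable.append(c)
    candidates = usable
    if len(data) <= len(candidates) + len(forced) + 1:
        raise ValueError("too few observations for the candidate pool")

    def _fit(terms: list[str]):
        rhs = " + ".join([_term_label(data, t) for t in terms]) or "1"
        return smf.ols(f"{response} ~ {rhs}", data=data).fit()

    current = forced + candidates
    fit = _fit(current)
    trace = [{"step": 0, "action": "start", "terms": list(current),
              "aic": float(fit.aic)}]
    step = 0
    while True:
        removable = [t for t in current if t not in forced]
        if not removable:
            break
        if criterion == "aic":
            best_term, best_fit, best_aic = None, None, fit.aic
            for t in removable:
                cand_fit = _fit([u for u in current if u != t])
                if cand_fit.aic < best_aic - 1e-12:
                    best_term, best_fit, best_aic = t, cand_fit, cand_fit.aic
            if best_term is None:
                break
            current = [u for u in current if u != best_term]
            fit = best_fit
            step += 1
            trace.append({"step": step, "action": f"drop {best_term}",
                          "terms": list(current), "aic": float(fit.aic)})
        elif criterion == "p":
            pvals = {}
            for t in removable:
                reduced = _fit([u for u in current if u != t])
                f_p = fit.compare_f_test(reduced)[1]
                pvals[t] = f_p
            worst = max(pvals, key=pvals.get)
            if pvals[worst] <= p_threshold:
                break
            current = [u for u in current if u != worst]
            fit = _fit(current)
            step += 1
            trace.append({"step": step, "action": f"drop {worst}",
                          "terms": list(current), "p": float(pvals[worst])})
        else:
            raise ValueError("criterion must be 'aic' or 'p'")

    coef_table = pd.DataFrame({"coef": fit.params, "se": fit.bse, "p": fit.pvalues})
    model_p = float(fit.f_pvalue) if current else 1.0
    if np.isnan(model_p):
        model_p = 1.0
    return StepwiseResult(
        response=response, terms=current, forced=forced,
        coef_table=coef_table, model_p=model_p,
        model_ns=model_p >= 0.05, criterion=criterion, trace=trace,
        n=int(fit.nobs),
    )
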