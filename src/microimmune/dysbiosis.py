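"""Reference-based dysbiosis scoring and delta-versus-baseline regressions.

A sample's dysbiosis score is its mean weighted-UniFrac distance to all
healthy-control samples collected at the same week, so the score carries
the units of the underlying distance. Delta regressions fit, per stratum,
ordinary least squares of the week-24-minus-week-0 change on the baseline
value — the regression-to-the-mean design used for both Shannon entropy
and dysbiosis.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix

__all__ = ["dysbiosis_score", "delta_regression", "cotrimoxazole_correlation"]


def dysbiosis_score(dm: DistanceMatrix, meta: pd.DataFrame,
                    include_hc: bool = False) -> pd.DataFrame:
    """Mean distance of each sample to the same-week healthy controls.

    By default scored for non-HC samples only. With ``include_hc=True``,
    HC samples are scored against the other HC samples of their week
    (self excluded) — a documented extension used for HC-side correlates.
    """
    meta = meta.loc[list(dm.ids)]
    d = pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids)
    records = []
    for week, wk_meta in meta.groupby("week"):
        hc_ids = wk_meta.index[wk_meta["cohort"] == "HC"]
        if len(hc_ids) == 0:
            raise ValueError(f"no healthy-control samples at week {week}")
        targets = wk_meta.index if include_hc else wk_meta.index[wk_meta["cohort"] != "HC"]
        for sid in targets:
            ref = hc_ids.drop(sid) if sid in hc_ids else hc_ids
            if len(ref) == 0:
                continue  # single HC cannot be scored against itself
            row = meta.loc[sid]
            records.append({
                "sample_id": sid, "pid": row["pid"], "cohort": row["cohort"],
                "location": row.get("location"), "week": week,
                "score": float(d.loc[sid, ref].mean()),
            })
    return pd.DataFrame(records).set_index("sample_id")


def _paired(values: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-(pid, week) values to one baseline/delta row per pid."""
    wide = values.pivot_table(index="pid", columns="week", values="value")
    missing = wide.index[wide.isna().any(axis=1)]
    if len(missing):
        warnings.warn(f"excluding {len(missing)} participant(s) missing a timepoint")
    wide = wide.dropna()
    keys = values.drop_duplicates("pid").set_index("pid")
    out = pd.DataFrame({
        "baseline": wide[0],
        "delta": wide[24] - wide[0],
    })
    for col in ("cohort", "location"):
        if col in keys.columns:
            out[col] = keys.loc[out.index, col]
    return out


def delta_regression(values: pd.DataFrame,
                     strata: tuple[str, ...] = ("cohort",)) -> pd.DataFrame:
    """Per-stratum OLS of delta (week 24 minus 0) on the baseline value.

    ``values`` needs columns pid, week (0/24), value, and the stratum keys
    (cohort, and optionally location). Strata with fewer than 3 complete
    pairs are skipped with a warning. Returns one row per stratum with
    intercept, slope, slope SE, slope p, R-squared, and n.
    """
    paired = _paired(values)
    rows = []
    for key, grp in paired.groupby(list(strata)):
        key = key if isinstance(key, tuple) else (key,)
        if len(grp) < 3:
            warnings.warn(f"stratum {key} has < 3 complete pairs; skipped")
            continue
        x, y = grp["baseline"].to_numpy(), grp["delta"].to_numpy()
        if np.allclose(y, y[0]) and np.allclose(y, 0):
            rows.append(dict(zip(strata, key), intercept=0.0, slope=0.0,
                             slope_se=0.0, slope_p=1.0, r_squared=0.0, n=len(grp)))
            continue
        fit = stats.linregress(x, y)
        rows.append(dict(
            zip(strata, key),
            intercept=float(fit.intercept), slope=float(fit.slope),
            slope_se=float(fit.stderr), slope_p=float(fit.pvalue),
            r_squared=float(fit.rvalue ** 2), n=len(grp),
        ))
    return pd.DataFrame(rows)


def cotrimoxazole_correlation(scores: pd.Series, months: pd.Series) -> dict:
    """Pearson and Spearman correlation of a diversity/dysbiosis measure
    with months of cotrimoxazole exposure (both reported, since either
    coefficient is defensible for exposure data with a point mass at 0)."""
    x = pd.concat([scores.rename("score"), months.rename("months")], axis=1).dropna()
    pear = stats.pearsonr(x["score"], x["months"])
    spear = stats.spearmanr(x["score"], x["months"])
    return {
        "pearson_r": float(pear.statistic), "pearson_p": float(pear.pvalue),
        "spearman_rho": float(spear.statistic), "spearman_p": float(spear.pvalue),
        "n": len(x),
    }
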