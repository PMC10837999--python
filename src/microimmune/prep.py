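"""Cohort preparation: viremia labeling, the exclusion cascade, immune
imputation, rarefaction, prevalence filtering, and relative abundance.

The exclusion rules operate on strict viral-load thresholds exactly as
stated in the study design:

* an ART-naive participant whose *baseline* viral load is below 20
  copies/mL is inconsistent with declared (untreated) status and is
  excluded from all analyses;
* an ART-experienced participant viremic (> 200 copies/mL) at baseline is
  excluded, since the aim is to evaluate successful therapy;
* longitudinal analyses additionally drop participants with only one visit
  and naive participants who did not reach virologic control
  (< 200 copies/mL) at week 24.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

__all__ = [
    "FilterReport",
    "label_viremia",
    "filter_baseline",
    "filter_longitudinal",
    "impute_immune",
    "rarefy",
    "prevalence_filter",
    "relative_abundance",
    "round_pct",
]


def round_pct(numerator: int, denominator: int) -> float:
    """Percentage rounded half-up to one decimal (matching printed tables)."""
    pct = Decimal(100 * numerator) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class FilterReport:
    """Bookkeeping for one exclusion stage: counts are conserved,
    ``n_input = n_retained + sum(excluded-by-rule)`` over participants."""

    stage: str
    n_input: int
    n_retained: int
    excluded: dict[str, list[str]] = field(default_factory=dict)
    n_samples_retained: int | None = None

    @property
    def n_excluded(self) -> int:
        return sum(len(v) for v in self.excluded.values())

    def rule_counts(self) -> dict[str, int]:
        return {rule: len(pids) for rule, pids in self.excluded.items()}

    def to_dict(self) -> dict:
        d = {
            "stage": self.stage,
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "excluded_counts": self.rule_counts(),
            "excluded_pids": self.excluded,
        }
        if self.n_samples_retained is not None:
            d["n_samples_retained"] = self.n_samples_retained
        return d


def label_viremia(meta: pd.DataFrame) -> pd.DataFrame:
    """Attach ``inconsistent_naive_baseline`` and ``viremic`` flags.

    Thresholds are strict inequalities: baseline naive viral load < 20 is
    inconsistent with untreated status; naive week-24 or experienced
    baseline viral load > 200 copies/mL is viremic. Healthy controls are
    never flagged.
    """
    out = meta.copy()
    non_hc = out["cohort"] != "HC"
    missing = non_hc & out["viral_load"].isna()
    if missing.any():
        bad = ", ".join(out.index[missing])
        raise ValueError(f"missing viral load on non-HC samples: {bad}")
    vl = out["viral_load"]
    out["inconsistent_naive_baseline"] = (
        (out["cohort"] == "Naive") & (out["week"] == 0) & (vl < 20)
    )
    out["viremic"] = (
        ((out["cohort"] == "Naive") & (out["week"] == 24) & (vl > 200))
        | ((out["cohort"] == "Exp") & (out["week"] == 0) & (vl > 200))
    )
    return out


def filter_baseline(meta: pd.DataFrame) -> tuple[list[str], FilterReport]:
    """Baseline-stage exclusions; returns retained pids and a report.

    ``meta`` must carry the flags from :func:`label_viremia`.
    """
    _require_flags(meta)
    all_pids = sorted(meta["pid"].unique())
    inconsistent = sorted(
        meta.loc[meta["inconsistent_naive_baseline"], "pid"].unique()
    )
    exp_viremic = sorted(
        meta.loc[(meta["cohort"] == "Exp") & (meta["week"] == 0) & meta["viremic"], "pid"].unique()
    )
    dropped = set(inconsistent) | set(exp_viremic)
    retained = [p for p in all_pids if p not in dropped]
    report = FilterReport(
        stage="baseline",
        n_input=len(all_pids),
        n_retained=len(retained),
        excluded={
            "inconsistent_naive_baseline": inconsistent,
            "exp_viremic_baseline": exp_viremic,
        },
    )
    return retained, report


def filter_longitudinal(meta: pd.DataFrame) -> tuple[list[str], FilterReport]:
    """Longitudinal-stage exclusions on the baseline-retained roster.

    Drops participants missing either visit and naive participants viremic
    at week 24. The result is a strict two-samples-per-participant set.
    """
    _require_flags(meta)
    baseline_pids, _ = filter_baseline(meta)
    sub = meta[meta["pid"].isin(baseline_pids)]
    counts = sub.groupby("pid").size()
    if (counts > 2).any():
        bad = ", ".join(counts.index[counts > 2])
        raise ValueError(f"participants with more than 2 samples: {bad}")
    incomplete = sorted(counts.index[counts < 2])
    naive_failed = sorted(
        sub.loc[(sub["cohort"] == "Naive") & (sub["week"] == 24) & sub["viremic"], "pid"].unique()
    )
    naive_failed = [p for p in naive_failed if p not in incomplete]
    dropped = set(incomplete) | set(naive_failed)
    retained = [p for p in sorted(counts.index) if p not in dropped]
    report = FilterReport(
        stage="longitudinal",
        n_input=len(baseline_pids),
        n_retained=len(retained),
        excluded={
            "lost_to_follow_up": incomplete,
            "naive_week24_viremic": naive_failed,
        },
        n_samples_retained=2 * len(retained),
    )
    return retained, report


def _require_flags(meta: pd.DataFrame) -> None:
    for col in ("inconsistent_naive_baseline", "viremic"):
        if col not in meta.columns:
            raise ValueError("run label_viremia first (flag columns missing)")


def impute_immune(panel: pd.DataFrame, meta: pd.DataFrame,
                  markers: tuple[str, ...] | None = None,
                  stratify: bool = True) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean-impute missing CD4-lineage marker values.

    Each missing value is replaced by the mean of the non-missing values of
    that marker within the same cohort x week stratum (``stratify=False``
    uses the global per-marker mean instead, as a sensitivity option).
    Returns the imputed panel and a log of imputed cells.
    """
    from .defs import CD4_MARKERS

    if markers is None:
        markers = CD4_MARKERS
    out = panel.copy()
    log_rows = []
    strata = (
        meta.loc[panel.index, ["cohort", "week"]]
        if stratify
        else pd.DataFrame({"cohort": "all", "week": "all"}, index=panel.index)
    )
    for marker in markers:
        if marker not in out.columns:
            continue
        for (cohort, week), idx in strata.groupby(["cohort", "week"]).groups.items():
            col = out.loc[idx, marker]
            missing = col.isna()
            if not missing.any():
                continue
            observed = col[~missing]
            if observed.empty:
                raise ValueError(
                    f"no observed values of {marker} in stratum ({cohort}, {week})"
                )
            mean = observed.mean()
            out.loc[col.index[missing], marker] = mean
            for sid in col.index[missing]:
                log_rows.append({"sample_id": sid, "marker": marker,
                                 "stratum": f"{cohort}/{week}", "imputed": mean})
    log = pd.DataFrame(log_rows, columns=["sample_id", "marker", "stratum", "imputed"])
    return out, log


def rarefy(table: pd.DataFrame, depth: int, seed: int
           ) -> tuple[pd.DataFrame, list[str]]:
    """Subsample each sample to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` total reads are dropped and returned
    in the log. One RNG stream is consumed in sample-ID sort order, so the
    result is reproducible regardless of input row order.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be >= 1")
    rng = np.random.default_rng(seed)
    kept_rows = {}
    dropped: list[str] = []
    for sid in sorted(table.index):
        counts = table.loc[sid].to_numpy(dtype=np.int64)
        total = counts.sum()
        if total < depth:
            dropped.append(sid)
            continue
        if total == depth:
            kept_rows[sid] = counts
        else:
            kept_rows[sid] = rng.multivariate_hypergeometric(counts, depth)
    out = pd.DataFrame.from_dict(kept_rows, orient="index", columns=table.columns)
    out = out.loc[[s for s in table.index if s in kept_rows]]
    return out, dropped


def prevalence_filter(table: pd.DataFrame, threshold: float = 0.2) -> pd.DataFrame:
    """Keep features present (count > 0) in strictly more than
    ``threshold`` of samples."""
    if table.empty:
        raise ValueError("empty feature table")
    if not 0 <= threshold < 1:
        raise ValueError("threshold must be in [0, 1)")
    presence = (table > 0).sum(axis=0)
    keep = presence > threshold * len(table)
    return table.loc[:, keep]


def relative_abundance(table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample proportions (each row sums to 1)."""
    totals = table.sum(axis=1)
    zero = totals == 0
    if zero.any():
        bad = ", ".join(table.index[zero])
        raise ValueError(f"zero-total samples: {bad}")
    return table.div(totals, axis=0)
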