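"""Synthetic two-timepoint HIV cohort generator.

Emulates a three-cohort (ART-naive, ART-experienced, healthy control),
two-location (rural, urban), two-week (0, 24) longitudinal design with
repeated measures per participant:

* compositional ASV counts drawn Dirichlet-multinomial, with two designated
  feature blocks ("Prevotella-like" and "Bacteroides-like") carrying a
  rural/urban gradient so that the leading beta-diversity axis separates
  locations;
* per-cohort viral-load distributions (log-normal with point masses at zero
  for suppressed participants) that drive the downstream exclusion rules;
* immune markers built additively from marker baselines, cohort effects,
  planted linear microbe->immune slopes restricted to one cohort,
  a per-participant random intercept, and Gaussian noise;
* completely-at-random missingness on the CD4-lineage markers.

Everything is deterministic given ``SynthConfig.seed``: one master
``SeedSequence`` is split into fixed, named substreams (tree, roster,
counts, immune, missingness) so that, e.g., adding features does not
reshuffle the metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from .defs import COHORTS, LOCATIONS, MARKERS, PCT_MARKERS, CD4_MARKERS

__all__ = [
    "SynthConfig",
    "PlantedEdge",
    "generate_tree",
    "generate_dataset",
    "write_dataset",
    "study_roster",
]

# Healthy-control marker baselines (percent of parent T cells; IL-6 pg/mL,
# CRP mg/L) and additive cohort shifts, chosen to mirror the qualitative
# ordering seen in untreated vs treated HIV: activation/exhaustion highest in
# untreated infection, partially resolved on therapy; CD103+ trafficking
# cells depleted in untreated infection.
MARKER_BASELINE = {
    "cd4_cd38_hladr_pct": 2.0,
    "cd8_cd38_hladr_pct": 6.0,
    "cd4_pd1_pct": 10.0,
    "cd8_pd1_pct": 12.0,
    "cd4_cd103_pct": 2.0,
    "cd8_cd103_pct": 4.0,
    "il6": 2.0,
    "crp": 2.0,
}

COHORT_EFFECT = {
    "Naive": {
        "cd4_cd38_hladr_pct": 6.0,
        "cd8_cd38_hladr_pct": 12.0,
        "cd4_pd1_pct": 10.0,
        "cd8_pd1_pct": 10.0,
        "cd4_cd103_pct": -1.0,
        "cd8_cd103_pct": -2.0,
        "il6": 3.0,
        "crp": 2.0,
    },
    "Exp": {
        "cd4_cd38_hladr_pct": 2.0,
        "cd8_cd38_hladr_pct": 4.0,
        "cd4_pd1_pct": 4.0,
        "cd8_pd1_pct": 4.0,
        "cd4_cd103_pct": 1.0,
        "cd8_cd103_pct": 2.0,
        "il6": 1.0,
        "crp": 1.0,
    },
    "HC": {m: 0.0 for m in MARKERS},
}

# Change from week 0 to 24 within the ART-naive cohort (treatment response);
# other cohorts are modelled as stable over 24 weeks.
NAIVE_WEEK_EFFECT = {
    "cd4_cd38_hladr_pct": -3.0,
    "cd8_cd38_hladr_pct": -6.0,
    "cd4_pd1_pct": -5.0,
    "cd8_pd1_pct": -5.0,
    "cd4_cd103_pct": 1.0,
    "cd8_cd103_pct": 1.5,
    "il6": -1.5,
    "crp": -1.0,
}


@dataclass(frozen=True)
class PlantedEdge:
    """A ground-truth linear microbe->immune effect restricted to one cohort.

    ``marker`` gains ``slope *`` (relative abundance of ``feature``) for every
    sample whose participant belongs to ``cohort``.
    """

    feature: int
    marker: str
    cohort: str = "Naive"
    slope: float = 80.0


@dataclass
class SynthConfig:
    """Parameters of the synthetic cohort.

    Default rates mirror the study design the generator emulates:
    ``viremia_rates`` are the per-cohort probabilities of the three
    viral-load states that trigger exclusions (baseline viral load < 20 in a
    supposedly untreated participant; failure to suppress below 200 copies/mL
    at week 24 on new therapy; baseline viremia above 200 copies/mL despite
    established therapy), and ``dropout_rate`` is the chance of missing the
    week-24 visit.
    """

    seed: int = 0
    n_per_cell: int = 20              # participants per cohort x location cell
    n_features: int = 60
    depth_mean: float = 25000.0       # negative-binomial sequencing depth
    depth_dispersion: float = 10.0    # NB size parameter; larger = tighter
    gradient_strength: float = 1.0    # log-fold rural/urban block shift
    dirichlet_concentration: float = 50.0
    planted_edges: list[PlantedEdge] = field(default_factory=list)
    cohort_effect_scale: float = 1.0  # 0 disables cohort/week nuisance effects
    immune_noise_sd: float = 1.0
    pid_intercept_sd: float = 0.5
    missing_rate: float = 0.07
    dropout_rate: float = 0.10
    viremia_rates: dict[str, float] = field(
        default_factory=lambda: {
            "naive_baseline_inconsistent": 14 / 81,
            "naive_week24_failure": 15 / 67,
            "exp_baseline_viremic": 6 / 39,
        }
    )

    def validate(self) -> None:
        if self.n_per_cell < 1:
            raise ValueError("n_per_cell must be >= 1")
        if self.n_features < 2:
            raise ValueError("n_features must be >= 2")
        for name in ("immune_noise_sd", "pid_intercept_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("missing_rate", "dropout_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        for key, rate in self.viremia_rates.items():
            if not 0 <= rate <= 1:
                raise ValueError(f"viremia_rates[{key!r}] must be in [0, 1]")
        for e in self.planted_edges:
            if not 0 <= e.feature < self.n_features:
                raise ValueError(f"planted edge references unknown feature {e.feature}")
            if e.marker not in MARKERS:
                raise ValueError(f"planted edge references unknown marker {e.marker!r}")
            if e.cohort not in COHORTS:
                raise ValueError(f"planted edge references unknown cohort {e.cohort!r}")


def _substream(seed: int, key: int) -> np.random.Generator:
    """Named substream ``key`` of the master seed (fixed offsets, stable order)."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


_TREE, _ROSTER, _COUNTS, _IMMUNE, _MISSING = range(5)


def generate_tree(n_leaves: int, seed: int) -> TreeNode:
    """Random rooted binary phylogeny over ``feature_0001 ...`` leaves.

    All branch lengths (every node except the root) are drawn Exp(rate 1),
    as a single vector *before* any topology draw so the total branch length
    can be replayed from the same RNG stream. Topology is built by random
    sequential pairwise joining.
    """
    if n_leaves < 2:
        raise ValueError("a rooted binary tree needs at least 2 leaves")
    rng = _substream(seed, _TREE)
    n_branches = 2 * n_leaves - 2  # binary rooted: leaves + internals minus root
    lengths = rng.exponential(1.0, size=n_branches)
    nodes = [TreeNode(name=f"feature_{i + 1:04d}") for i in range(n_leaves)]
    li = 0
    for node in nodes:
        node.length = lengths[li]
        li += 1
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = TreeNode(children=[left, right])
        if len(nodes) > 0:  # not yet the root
            parent.length = lengths[li]
            li += 1
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return root


def _block_indices(n_features: int) -> tuple[np.ndarray, np.ndarray]:
    """First/second 10% of features form the gradient-carrying blocks."""
    k = max(1, n_features // 10)
    return np.arange(k), np.arange(k, 2 * k)


def _draw_viral_loads(cohort: str, week: int, state: str, rng: np.random.Generator) -> float:
    """One viral load (copies/mL) for a cohort/week/latent-state combination."""
    if cohort == "HC":
        return np.nan
    if cohort == "Naive":
        if week == 0:
            if state == "inconsistent":  # suppressed despite declared no ART
                return float(rng.uniform(0, 20))
            return float(rng.lognormal(np.log(26000.0), 1.5))
        if state == "failure":  # still viremic after 24 weeks of ART
            return float(200.0 + rng.lognormal(np.log(5000.0), 1.0))
        return float(rng.uniform(0, 150))  # controlled
    # Exp: on ART at both visits; suppressed participants carry a point mass at 0
    if state == "viremic":
        return float(200.0 + rng.lognormal(np.log(3000.0), 1.0))
    return 0.0 if rng.random() < 0.7 else float(rng.uniform(0, 100))


def _roster(config: SynthConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    pid_no = 0
    rates = config.viremia_rates
    for cohort in COHORTS:
        for location in LOCATIONS:
            for _ in range(config.n_per_cell):
                pid_no += 1
                pid = f"P{pid_no:04d}"
                age = float(np.round(rng.uniform(18, 65), 1))
                sex = "F" if rng.random() < 0.55 else "M"
                bmi = float(np.round(rng.normal(22.5, 3.0), 1))
                cotri = (
                    float(np.round(rng.exponential(30.0), 1)) if cohort == "Exp"
                    else (float(np.round(rng.exponential(0.3), 1)) if cohort == "Naive" else 0.0)
                )
                art_years = float(np.round(rng.uniform(1, 20), 1)) if cohort == "Exp" else np.nan
                dropout = rng.random() < config.dropout_rate

                if cohort == "Naive":
                    w0_state = "inconsistent" if rng.random() < rates["naive_baseline_inconsistent"] else "viremic"
                    w24_state = "failure" if rng.random() < rates["naive_week24_failure"] else "controlled"
                elif cohort == "Exp":
                    w0_state = "viremic" if rng.random() < rates["exp_baseline_viremic"] else "suppressed"
                    w24_state = "suppressed"
                else:
                    w0_state = w24_state = "none"

                for week, state in ((0, w0_state), (24, w24_state)):
                    if week == 24 and dropout:
                        continue
                    rows.append(
                        {
                            "sample_id": f"{pid}.w{week}",
                            "pid": pid,
                            "cohort": cohort,
                            "location": location,
                            "week": week,
                            "viral_load": _draw_viral_loads(cohort, week, state, rng),
                            "age": age,
                            "sex": sex,
                            "bmi": bmi,
                            "bmi_category": _who_bmi_category(bmi),
                            "cotrimoxazole_months": cotri,
                            "art_years": art_years,
                        }
                    )
    meta = pd.DataFrame(rows).set_index("sample_id")
    return meta


def _who_bmi_category(bmi: float) -> str:
    if bmi < 16.0:
        return "severe_thinness"
    if bmi < 17.0:
        return "moderate_thinness"
    if bmi < 18.5:
        return "mild_thinness"
    if bmi < 25.0:
        return "normal"
    if bmi < 30.0:
        return "overweight"
    return "obese"


def _compositions(config: SynthConfig, meta: pd.DataFrame, rng: np.random.Generator
                  ) -> tuple[pd.DataFrame, dict]:
    """Dirichlet-multinomial counts with a location-driven two-block gradient."""
    p = config.n_features
    prev_block, bact_block = _block_indices(p)
    # log-normal baseline mean composition, fixed per seed
    base = rng.lognormal(0.0, 1.0, size=p)
    shift = config.gradient_strength / 2.0
    mean_comp = {}
    for location in LOCATIONS:
        w = base.copy()
        sign = 1.0 if location == "rural" else -1.0
        w[prev_block] *= np.exp(sign * shift)       # Prevotella-like block up rural
        w[bact_block] *= np.exp(-sign * shift)      # Bacteroides-like block up urban
        mean_comp[location] = w / w.sum()
    depths = rng.negative_binomial(
        config.depth_dispersion,
        config.depth_dispersion / (config.depth_dispersion + config.depth_mean),
        size=len(meta),
    )
    depths = np.maximum(depths, 1)
    counts = np.empty((len(meta), p), dtype=np.int64)
    for i, (sid, row) in enumerate(meta.iterrows()):
        alpha = config.dirichlet_concentration * mean_comp[row["location"]]
        probs = rng.dirichlet(alpha)
        counts[i] = rng.multinomial(depths[i], probs)
    features = [f"feature_{j + 1:04d}" for j in range(p)]
    table = pd.DataFrame(counts, index=meta.index.copy(), columns=features)
    truth = {
        "prevotella_block": [features[j] for j in prev_block],
        "bacteroides_block": [features[j] for j in bact_block],
    }
    return table, truth


def _immune_panel(config: SynthConfig, meta: pd.DataFrame, table: pd.DataFrame,
                  rng_immune: np.random.Generator, rng_missing: np.random.Generator
                  ) -> pd.DataFrame:
    rel = table.div(table.sum(axis=1), axis=0)
    pids = meta["pid"].unique()
    intercepts = {
        pid: rng_immune.normal(0.0, config.pid_intercept_sd, size=len(MARKERS))
        for pid in pids
    }
    values = np.empty((len(meta), len(MARKERS)))
    for i, (sid, row) in enumerate(meta.iterrows()):
        for k, marker in enumerate(MARKERS):
            v = MARKER_BASELINE[marker]
            v += config.cohort_effect_scale * COHORT_EFFECT[row["cohort"]][marker]
            if row["cohort"] == "Naive" and row["week"] == 24:
                v += config.cohort_effect_scale * NAIVE_WEEK_EFFECT[marker]
            v += intercepts[row["pid"]][k]
            v += rng_immune.normal(0.0, config.immune_noise_sd)
            values[i, k] = v
    for edge in config.planted_edges:
        k = MARKERS.index(edge.marker)
        in_cohort = (meta["cohort"] == edge.cohort).to_numpy()
        # centered abundance: the slope is the planted effect, but the
        # cohort-level mean is left untouched so a planted edge does not
        # masquerade as a cohort main effect on every other feature
        x = rel.iloc[:, edge.feature].to_numpy()
        values[in_cohort, k] += edge.slope * (x - x.mean())[in_cohort]
    panel = pd.DataFrame(values, index=meta.index.copy(), columns=list(MARKERS))
    for m in PCT_MARKERS:
        panel[m] = panel[m].clip(0.0, 100.0)
    for m in ("il6", "crp"):
        panel[m] = panel[m].clip(lower=0.0)
    # CD4 easy-count failures: all three CD4-lineage markers missing together
    miss = rng_missing.random(len(panel)) < config.missing_rate
    panel.loc[miss, list(CD4_MARKERS)] = np.nan
    return panel


def generate_dataset(config: SynthConfig
                     ) -> tuple[pd.DataFrame, TreeNode, pd.DataFrame, pd.DataFrame, dict]:
    """Generate (feature table, tree, metadata, immune panel, ground truth).

    The feature table is samples x features (integer counts); metadata and
    the immune panel are indexed by sample ID. The ground-truth dict records
    block membership and the planted microbe->immune edges for test assertions.
    """
    config.validate()
    tree = generate_tree(config.n_features, config.seed)
    meta = _roster(config, _substream(config.seed, _ROSTER))
    table, truth = _compositions(config, meta, _substream(config.seed, _COUNTS))
    panel = _immune_panel(
        config, meta, table,
        _substream(config.seed, _IMMUNE), _substream(config.seed, _MISSING),
    )
    truth["planted_edges"] = [
        {"feature": f"feature_{e.feature + 1:04d}", "marker": e.marker,
         "cohort": e.cohort, "slope": e.slope}
        for e in config.planted_edges
    ]
    return table, tree, meta, panel, truth


def write_dataset(out_dir: str | Path, table: pd.DataFrame, tree: TreeNode,
                  meta: pd.DataFrame, panel: pd.DataFrame, truth: dict) -> None:
    """Write the dataset as plain text: TSVs, newick, and a ground-truth JSON.

    The feature table is written features-as-rows with a header row of
    sample IDs (the usual amplicon-table orientation).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.T.to_csv(out / "feature_table.tsv", sep="\t", index_label="feature_id")
    tree.write(str(out / "tree.nwk"))
    meta.to_csv(out / "metadata.tsv", sep="\t")
    panel.to_csv(out / "immune_panel.tsv", sep="\t")
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)


def suggest_planted_features(config: SynthConfig, k: int = 5) -> list[int]:
    """Deterministically pick ``k`` feature indices suitable for planting.

    Planted microbe->immune effects act through relative abundance, so a
    recoverable effect needs a feature that is consistently present at
    moderate abundance — the same reason association scans in practice
    restrict to prevalent taxa. This ranks the non-block features of the
    dataset this ``config`` would generate by mean relative abundance and
    returns the indices at ranks 3..(3 + k) (skipping the most dominant
    taxa, whose compositional footprint is largest). The count-generating
    RNG substream is independent of ``planted_edges``, so the returned
    indices refer to the identical count table the full config generates.
    """
    probe = SynthConfig(**{**asdict(config), "planted_edges": []})
    probe.planted_edges = []
    meta = _roster(probe, _substream(probe.seed, _ROSTER))
    table, _ = _compositions(probe, meta, _substream(probe.seed, _COUNTS))
    rel_mean = (table.div(table.sum(axis=1), axis=0)).mean(axis=0).to_numpy()
    prev_block, bact_block = _block_indices(probe.n_features)
    blocked = set(prev_block) | set(bact_block)
    order = [int(i) for i in np.argsort(rel_mean)[::-1] if i not in blocked]
    return order[2:2 + k]


def study_roster() -> pd.DataFrame:
    """Deterministic roster reproducing the published enrolment structure.

    162 enrolled participants: 81 ART-naive (14 with baseline viral load
    below 20 copies/mL, inconsistent with declared treatment status), 39
    ART-experienced (6 viremic above 200 copies/mL at baseline despite
    therapy), 42 healthy controls. Among baseline-retained participants,
    14 miss the week-24 visit (7 naive / 3 experienced / 4 HC) and 15
    naive participants fail to suppress below 200 copies/mL at week 24.
    Viral loads are fixed representative values, not draws.
    """
    rows = []
    pid_no = 0

    def add(cohort, vl0, vl24, has_w24=True):
        nonlocal pid_no
        pid_no += 1
        pid = f"S{pid_no:04d}"
        rows.append({"sample_id": f"{pid}.w0", "pid": pid, "cohort": cohort,
                     "week": 0, "viral_load": vl0})
        if has_w24:
            rows.append({"sample_id": f"{pid}.w24", "pid": pid, "cohort": cohort,
                         "week": 24, "viral_load": vl24})

    for _ in range(14):                       # naive, inconsistent baseline
        add("Naive", 10.0, 50.0)
    for _ in range(7):                        # naive, lost to follow-up
        add("Naive", 26000.0, np.nan, has_w24=False)
    for _ in range(15):                       # naive, week-24 virologic failure
        add("Naive", 26000.0, 5000.0)
    for _ in range(81 - 14 - 7 - 15):         # naive, controlled at week 24
        add("Naive", 26000.0, 50.0)
    for _ in range(6):                        # experienced, viremic at baseline
        add("Exp", 5000.0, 0.0)
    for _ in range(3):                        # experienced, lost to follow-up
        add("Exp", 0.0, np.nan, has_w24=False)
    for _ in range(39 - 6 - 3):               # experienced, suppressed throughout
        add("Exp", 0.0, 0.0)
    for _ in range(4):                        # HC, lost to follow-up
        add("HC", np.nan, np.nan, has_w24=False)
    for _ in range(42 - 4):                   # HC, both visits
        add("HC", np.nan, np.nan)
    meta = pd.DataFrame(rows).set_index("sample_id")
    return meta
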