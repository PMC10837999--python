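"""Module binning, pair interaction models, influence diagnostics, the
filter cascade, and network assembly."""

import numpy as np
import pandas as pd
import pytest

import microimmune as mi
from microimmune.pipeline import association_network, match_planted_edges


def _count_table(rng, n_samples, n_features, scale=200):
    x = rng.lognormal(2.0, 0.5, size=(n_samples, n_features))
    counts = np.rint(x * scale / x.sum(axis=1, keepdims=True) * n_features)
    return pd.DataFrame(counts.astype(int) + 1,
                        index=[f"s{i}" for i in range(n_samples)],
                        columns=[f"f{j}" for j in range(n_features)])


class TestBinModules:
    def test_duplicated_feature_forms_doubled_module(self, rng):
        table = _count_table(rng, 30, 5)
        table["f_dup"] = table["f0"]
        binning, combined = mi.bin_modules(table, min_r=0.9)
        mods = [m for m in binning.modules.values() if set(m) == {"f0", "f_dup"}]
        assert len(mods) == 1
        mod_id = [k for k, v in binning.modules.items()
                  if set(v) == {"f0", "f_dup"}][0]
        assert (combined[mod_id] == 2 * table["f0"]).all()

    def test_planted_blocks_recovered(self, rng):
        # 3 latent factors, 3 member features each, plus independent noise
        n = 120
        latent = rng.lognormal(0, 1, size=(n, 3))
        cols = {}
        for b in range(3):
            for j in range(3):
                cols[f"b{b}_m{j}"] = latent[:, b] * rng.lognormal(0, 0.15, n)
        for j in range(4):
            cols[f"indep{j}"] = rng.lognormal(0, 1, n)
        table = pd.DataFrame(
            {k: np.rint(v * 100).astype(int) + 1 for k, v in cols.items()},
            index=[f"s{i}" for i in range(n)])
        binning, combined = mi.bin_modules(table, min_r=0.35)
        blocks = [sorted(f"b{b}_m{j}" for j in range(3)) for b in range(3)]
        found = [sorted(m) for m in binning.modules.values()]
        for block in blocks:
            assert block in found
        assert combined.shape[1] == len(binning.modules) + 4

    def test_independent_features_rarely_bin(self, rng):
        zero_module_runs = 0
        for _ in range(100):
            table = _count_table(rng, 150, 10)
            binning, _ = mi.bin_modules(table, min_r=0.35)
            if not binning.modules:
                zero_module_runs += 1
        assert zero_module_runs >= 95

    def test_constant_feature_left_unbinned(self, rng):
        table = _count_table(rng, 20, 4)
        # constant relative abundance: duplicate total structure
        table["flat"] = table.sum(axis=1)       # rel abundance constant 0.5
        with pytest.warns(UserWarning, match="constant"):
            binning, combined = mi.bin_modules(table, min_r=0.35)
        assert all("flat" not in m for m in binning.modules.values())
        assert "flat" in combined.columns

    def test_modules_disjoint_and_order_invariant(self, rng):
        table = _count_table(rng, 60, 8)
        table["f0_twin"] = (table["f0"] * 1.01).astype(int) + 1
        b1, _ = mi.bin_modules(table, min_r=0.35)
        shuffled = table[list(rng.permutation(table.columns))]
        b2, _ = mi.bin_modules(shuffled, min_r=0.35)
        sets1 = sorted(tuple(sorted(m)) for m in b1.modules.values())
        sets2 = sorted(tuple(sorted(m)) for m in b2.modules.values())
        assert sets1 == sets2
        seen = set()
        for m in b1.modules.values():
            assert not (set(m) & seen)
            seen |= set(m)


def _pair_inputs(rng, n_per=20, naive_slope=0.0, noise=0.5):
    cohorts = np.repeat(["Naive", "Exp", "HC"], n_per)
    n = len(cohorts)
    rel = rng.dirichlet(np.ones(5) * 10, size=n)[:, 0]
    rc = rng.integers(8000, 30000, n).astype(float)
    y = 3.0 + naive_slope * rel * (cohorts == "Naive")
    if noise:
        y = y + rng.normal(0, noise, n)
    return y, rel, cohorts, rc


class TestFitPairModel:
    def test_constant_marker_is_degenerate(self, rng):
        y, rel, coh, rc = _pair_inputs(rng, noise=0.0)
        fit = mi.fit_pair_model(np.full_like(y, 4.2), rel, coh, rc)
        assert fit.degenerate
        assert all(v == 0.0 for v in fit.slopes.values())

    def test_noiseless_naive_only_slope_recovered(self, rng):
        cohorts = np.repeat(["Naive", "Exp", "HC"], 15)
        n = len(cohorts)
        rel = rng.dirichlet(np.ones(4) * 8, size=n)[:, 0]
        rc = rng.integers(5000, 20000, n).astype(float)
        y = 1.0 + 2e-5 * rc + 2.0 * rel * (cohorts == "Naive")
        fit = mi.fit_pair_model(y, rel, cohorts, rc)
        assert fit.slopes["Naive"] == pytest.approx(2.0, abs=1e-10)
        assert fit.slopes["Exp"] == pytest.approx(0.0, abs=1e-10)
        assert fit.slopes["HC"] == pytest.approx(0.0, abs=1e-10)

    def test_coefficients_match_normal_equations_oracle(self, rng):
        y, rel, coh, rc = _pair_inputs(rng, naive_slope=1.5)
        fit = mi.fit_pair_model(y, rel, coh, rc)
        # independent design construction and solve
        d_exp = (coh == "Exp").astype(float)
        d_hc = (coh == "HC").astype(float)
        x = np.column_stack([np.ones_like(y), rc, d_exp, d_hc,
                             rel, d_exp * rel, d_hc * rel])
        beta = np.linalg.solve(x.T @ x, x.T @ y)
        assert fit.slopes["Naive"] == pytest.approx(beta[4], abs=1e-8)
        assert fit.slopes["Exp"] == pytest.approx(beta[4] + beta[5], abs=1e-8)
        assert fit.slopes["HC"] == pytest.approx(beta[4] + beta[6], abs=1e-8)

    def test_slopes_invariant_to_reference_coding(self, rng):
        y, rel, coh, rc = _pair_inputs(rng, naive_slope=1.0)
        a = mi.fit_pair_model(y, rel, coh, rc, reference="Naive")
        b = mi.fit_pair_model(y, rel, coh, rc, reference="Exp")
        for lev in ("Naive", "Exp", "HC"):
            assert a.slopes[lev] == pytest.approx(b.slopes[lev], abs=1e-10)
            assert a.slope_p[lev] == pytest.approx(b.slope_p[lev], abs=1e-10)

    def test_tiny_cohort_rejected(self, rng):
        y, rel, coh, rc = _pair_inputs(rng, n_per=10)
        coh = coh.copy()
        coh[coh == "HC"] = "Exp"
        coh[:2] = "HC"
        with pytest.raises(ValueError, match="HC"):
            mi.fit_pair_model(y, rel, coh, rc)


class TestDffits:
    @staticmethod
    def _ols(x, y):
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        e = y - x @ beta
        h = np.diag(x @ np.linalg.inv(x.T @ x) @ x.T)
        return beta, e, h

    def test_perfect_fit_gives_all_zeros(self, rng):
        x = np.column_stack([np.ones(10), rng.normal(size=10)])
        y = x @ np.array([1.0, 2.0])        # exactly on the line
        _, e, h = self._ols(x, y)
        assert np.allclose(mi.dffits(e, h, 2), 0.0)

    def test_matches_leave_one_out_refit_oracle(self, rng):
        for _ in range(10):
            n, k = 25, 3
            x = np.column_stack([np.ones(n), rng.normal(size=(n, k - 1))])
            y = x @ rng.normal(size=k) + rng.normal(size=n)
            beta, e, h = self._ols(x, y)
            d = mi.dffits(e, h, k)
            for i in range(n):
                mask = np.arange(n) != i
                beta_i, e_i, _ = self._ols(x[mask], y[mask])
                s_i = np.sqrt(e_i @ e_i / (n - 1 - k))
                pred_change = x[i] @ beta - x[i] @ beta_i
                oracle = pred_change / (s_i * np.sqrt(h[i]))
                assert d[i] == pytest.approx(oracle, abs=1e-8)

    def test_gross_outlier_exceeds_threshold(self, rng):
        n = 20
        x = np.column_stack([np.ones(n), np.linspace(0, 1, n)])
        y = x @ np.array([0.0, 1.0]) + rng.normal(0, 0.05, n)
        y[-1] += 5.0                       # single wildly off point
        _, e, h = self._ols(x, y)
        assert np.abs(mi.dffits(e, h, 2)).max() > 2

    def test_exact_leverage_point_flagged_infinite(self):
        # two points, two params: both observations have h = 1
        x = np.array([[1.0, 0.0], [1.0, 1.0]])
        y = np.array([0.0, 1.0])
        d = mi.dffits(np.zeros(2), np.ones(2), 2)
        assert np.isinf(d).all()


def _mk_fit(marker, feature, f_p, adj_r2, slope_naive_p, inter_p, dffits_max,
            slope=1.0, timepoint=0):
    return mi.PairModelFit(
        marker=marker, feature=feature, timepoint=timepoint,
        reference="Naive",
        slopes={"Naive": slope, "Exp": 0.0, "HC": 0.0},
        slope_p={"Naive": slope_naive_p, "Exp": 0.9, "HC": 0.9},
        interaction_p={"Exp": inter_p, "HC": 0.9},
        f_p=f_p, adj_r2=adj_r2, max_abs_dffits=dffits_max, n=100,
    )


class TestFilterCascade:
    def test_empty_input_gives_empty_output(self):
        assert mi.filter_cascade([]) == []

    def test_exactly_one_fit_survives_constructed_boundary_set(self):
        good = _mk_fit("il6", "fX", 1e-6, 0.4, 0.01, 0.01, 0.5)
        fits = [
            good,
            _mk_fit("il6", "f_fdr", 0.9, 0.4, 0.01, 0.01, 0.5),      # FDR fails
            _mk_fit("il6", "f_r2", 1e-6, 0.2, 0.01, 0.01, 0.5),      # adjR2 low
            _mk_fit("il6", "f_slope", 1e-6, 0.4, 0.2, 0.01, 0.5),    # naive slope NS
            _mk_fit("il6", "f_inter", 1e-6, 0.4, 0.01, 0.5, 0.5),    # no slope diff
            _mk_fit("il6", "f_dffits", 1e-6, 0.4, 0.01, 0.01, 2.5),  # outlier-driven
        ] + [_mk_fit("crp", f"f{i}", 0.8, 0.05, 0.5, 0.5, 0.5) for i in range(4)]
        edges = mi.filter_cascade(fits)
        assert [(e.immune, e.feature) for e in edges] == [("il6", "fX")]

    def test_edge_carries_sign_and_width(self):
        fit = _mk_fit("il6", "fneg", 1e-6, 0.4, 0.01, 0.01, 0.5, slope=-2.0)
        edge = mi.filter_cascade([fit])[0]
        assert edge.sign == "-"
        assert edge.width == pytest.approx(-np.log10(0.01))

    def test_output_invariant_to_fit_ordering(self, rng):
        fits = [
            _mk_fit(f"m{i}", f"f{i}", float(p), 0.4, 0.01, 0.01, 0.5)
            for i, p in enumerate(rng.uniform(0, 0.3, size=12))
        ]
        e1 = mi.filter_cascade(list(fits))
        order = rng.permutation(len(fits))
        e2 = mi.filter_cascade([fits[i] for i in order])
        assert sorted((e.immune, e.feature) for e in e1) == \
            sorted((e.immune, e.feature) for e in e2)

    def test_mixed_timepoints_rejected(self):
        fits = [_mk_fit("il6", "a", 0.5, 0.4, 0.5, 0.5, 0.5, timepoint=0),
                _mk_fit("il6", "b", 0.5, 0.4, 0.5, 0.5, 0.5, timepoint=24)]
        with pytest.raises(ValueError, match="timepoint"):
            mi.filter_cascade(fits)

    def test_exp_vs_hc_mode_uses_either_slope(self):
        fit = mi.PairModelFit(
            marker="il6", feature="fY", timepoint=0, reference="Exp",
            slopes={"Exp": 0.1, "HC": 1.4},
            slope_p={"Exp": 0.6, "HC": 0.001},     # only the HC slope is real
            interaction_p={"HC": 0.01},
            f_p=1e-5, adj_r2=0.5, max_abs_dffits=0.4, n=80,
        )
        assert len(mi.filter_cascade([fit], mode="exp_vs_hc")) == 1
        assert len(mi.filter_cascade([fit], mode="naive_specific")) == 0


class TestNetwork:
    def _edges(self, k):
        return [mi.AssociationEdge(f"m{i % 4}", f"f{i}", "+", 0.01, 2.0)
                for i in range(k)]

    def test_no_edges_keeps_declared_immune_nodes_isolated(self):
        g = mi.build_network([], immune_nodes=["il6", "crp"])
        assert set(g.nodes) == {"il6", "crp"}
        assert g.number_of_edges() == 0

    def test_degree_table_conserves_edge_count(self):
        g = mi.build_network(self._edges(29))
        deg = mi.degree_table(g)
        assert deg[deg["type"] == "immune"]["degree"].sum() == 29
        assert deg[deg["type"] == "microbe"]["degree"].sum() == 29

    def test_duplicate_edge_rejected(self):
        edges = self._edges(3) + [mi.AssociationEdge("m0", "f0", "-", 0.02, 1.7)]
        with pytest.raises(ValueError, match="duplicate"):
            mi.build_network(edges)

    def test_json_round_trip_reproduces_edge_set(self, tmp_path):
        edges = self._edges(7)
        g = mi.build_network(edges, immune_nodes=[f"m{i}" for i in range(4)])
        mi.export_network(g, tmp_path / "net.json", tmp_path / "net.tsv")
        g2 = mi.load_network(tmp_path / "net.json")
        assert set(g.nodes) == set(g2.nodes)
        assert {frozenset(e) for e in g.edges} == {frozenset(e) for e in g2.edges}
        tsv = pd.read_csv(tmp_path / "net.tsv", sep="\t")
        assert len(tsv) == 7


class TestEndToEndRecovery:
    def test_planted_edges_recovered_through_full_pipeline(self):
        # >= 80% of planted naive-only effects recovered and <= 20% false
        # edges, averaged over 10 seeds at n_per_cell = 30
        marks = ["cd4_pd1_pct", "cd8_cd38_hladr_pct", "cd4_cd38_hladr_pct",
                 "cd8_pd1_pct", "il6"]
        total_planted = total_rec = total_edges = total_false = 0
        for seed in range(10):
            cfg = mi.SynthConfig(seed=seed, n_per_cell=30,
                                 gradient_strength=0.0, cohort_effect_scale=0.0)
            feats = mi.synth.suggest_planted_features(cfg, 5)
            cfg.planted_edges = [mi.PlantedEdge(f, m)
                                 for f, m in zip(feats, marks)]
            table, _, meta, panel, truth = mi.generate_dataset(cfg)
            edges, fits, binning = association_network(table, meta, panel,
                                                       week=0)
            rec, false = match_planted_edges(edges, truth, binning)
            total_planted += 5
            total_rec += rec
            total_edges += len(edges)
            total_false += false
        assert total_rec >= 0.8 * total_planted
        assert total_false <= 0.2 * max(total_edges, 1)
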