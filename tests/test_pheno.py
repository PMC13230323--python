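"""Two-stage trial analysis: stage-1 adjusted means, stage-2 BLUPs, and
dual-source merging."""

import numpy as np
import pandas as pd
import pytest

from flaxgs import pheno, simpop
from flaxgs.pheno import (
    EstimabilityError,
    LineValues,
    combine_sources,
    stage1_adjusted_means,
    stage1_all_experiments,
    stage2_blup,
)


def records_from(rows):
    return pd.DataFrame(
        rows, columns=["line", "experiment", "location", "year", "block", "value"]
    )


class TestStage1:
    def test_balanced_blocks_cancel(self):
        rng = np.random.default_rng(1)
        truth = {f"L{i}": rng.normal() for i in range(6)}
        rows = []
        for b in (1, 2):
            for l, v in truth.items():
                rows.append((l, "E1", "loc", 2025, b, v + (10.0 if b == 2 else 0.0)))
        rec = records_from(rows)
        lv = stage1_adjusted_means(rec, "E1")
        raw = rec.groupby("line")["value"].mean()
        np.testing.assert_allclose(
            lv.as_series()[raw.index].to_numpy(), raw.to_numpy(), atol=1e-10
        )

    def test_unbalanced_equals_normal_equations(self):
        # line L2 missing from block 2; oracle = direct OLS lsmeans
        rows = [
            ("L1", "E1", "x", 1, 1, 10.0),
            ("L2", "E1", "x", 1, 1, 12.0),
            ("L3", "E1", "x", 1, 1, 14.0),
            ("L1", "E1", "x", 1, 2, 13.0),
            ("L3", "E1", "x", 1, 2, 18.0),
        ]
        rec = records_from(rows)
        lv = stage1_adjusted_means(rec, "E1")
        lines = ["L1", "L2", "L3"]
        blocks = [1, 2]
        X = []
        for _, r in rec.iterrows():
            X.append(
                [1.0]
                + [1.0 if r["line"] == l else 0.0 for l in lines[1:]]
                + [1.0 if r["block"] == b else 0.0 for b in blocks[1:]]
            )
        beta = np.linalg.lstsq(np.array(X), rec["value"], rcond=None)[0]
        expected = {
            "L1": beta[0] + beta[3] / 2,
            "L2": beta[0] + beta[1] + beta[3] / 2,
            "L3": beta[0] + beta[2] + beta[3] / 2,
        }
        for l in lines:
            assert lv.as_series()[l] == pytest.approx(expected[l], abs=1e-10)

    def test_single_block_returns_plot_values(self):
        rows = [(f"L{i}", "E1", "x", 1, 1, float(i)) for i in range(4)]
        lv = stage1_adjusted_means(records_from(rows), "E1")
        for i in range(4):
            assert lv.as_series()[f"L{i}"] == pytest.approx(float(i))

    def test_disconnected_design_rejected(self):
        rows = [
            ("L1", "E1", "x", 1, 1, 1.0),
            ("L2", "E1", "x", 1, 1, 2.0),
            ("L3", "E1", "x", 1, 2, 3.0),  # block 2 shares no line with block 1
        ]
        with pytest.raises(EstimabilityError, match="L3"):
            stage1_adjusted_means(records_from(rows), "E1")


class TestStage2:
    def test_zero_genetic_variance_full_shrinkage(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(
            {
                "line": [f"L{i}" for i in range(20)] * 2,
                "experiment": ["E1"] * 20 + ["E2"] * 20,
                "estimate": rng.normal(size=40),
            }
        )
        res = stage2_blup(df, fix_sigma_g2=0.0)
        assert np.ptp(res.table["estimate"].to_numpy()) == pytest.approx(0.0, abs=1e-10)
        assert res.table["estimate"].iloc[0] == pytest.approx(res.meta["grand_mean"])

    def test_single_experiment_closed_form_shrinkage(self):
        rng = np.random.default_rng(3)
        y = 5 + rng.normal(0, 2, 40) + rng.normal(0, 1, 40)
        lines = [f"L{i}" for i in range(40)]
        df = pd.DataFrame({"line": lines, "experiment": "E1", "estimate": y})
        res = stage2_blup(df)
        vc = res.variance_components
        h2 = vc["sigma_g2"] / (vc["sigma_g2"] + vc["sigma_e2"])
        grand = res.meta["grand_mean"]
        expected = grand + h2 * (y - grand)
        got = res.table.set_index("line")["estimate"][lines].to_numpy()
        np.testing.assert_allclose(got, expected, atol=1e-6)

    def test_agrees_with_direct_gls_solve(self):
        rng = np.random.default_rng(4)
        lines = [f"L{i}" for i in range(30)]
        rows = []
        g = dict(zip(lines, rng.normal(0, 2, 30)))
        for e in ("E1", "E2", "E3"):
            off = {"E1": 0.0, "E2": 3.0, "E3": -2.0}[e]
            for l in lines:
                rows.append((l, e, g[l] + off + rng.normal()))
        df = pd.DataFrame(rows, columns=["line", "experiment", "estimate"])
        res = stage2_blup(df)
        vc = res.variance_components
        # direct V-inverse BLUP at the converged variance components
        X = pd.get_dummies(df["experiment"]).to_numpy(float)
        Z = pd.get_dummies(df["line"]).to_numpy(float)
        zlines = sorted(df["line"].unique())
        V = vc["sigma_g2"] * Z @ Z.T + vc["sigma_e2"] * np.eye(len(df))
        Vi = np.linalg.inv(V)
        b = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ df["estimate"].to_numpy())
        u = vc["sigma_g2"] * Z.T @ Vi @ (df["estimate"].to_numpy() - X @ b)
        got = res.table.set_index("line")["blup_deviation"][zlines].to_numpy()
        np.testing.assert_allclose(got, u, atol=1e-6)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(
            {
                "line": [f"L{i}" for i in range(25)] * 2,
                "experiment": ["E1"] * 25 + ["E2"] * 25,
                "estimate": rng.normal(size=50),
            }
        )
        res0 = stage2_blup(df)
        df2 = df.assign(estimate=df["estimate"] + 100.0)
        res1 = stage2_blup(df2)
        np.testing.assert_allclose(
            res1.table["estimate"].to_numpy(),
            res0.table["estimate"].to_numpy() + 100.0,
            atol=1e-5,
        )
        assert res1.variance_components["sigma_g2"] == pytest.approx(
            res0.variance_components["sigma_g2"], rel=1e-5
        )

    def test_blups_shrink_relative_to_means(self):
        rng = np.random.default_rng(6)
        lines = [f"L{i}" for i in range(40)]
        g = dict(zip(lines, rng.normal(0, 1, 40)))
        rows = [
            (l, e, g[l] + rng.normal(0, 1.5))
            for e in ("E1", "E2")
            for l in lines
        ]
        df = pd.DataFrame(rows, columns=["line", "experiment", "estimate"])
        res = stage2_blup(df)
        means = df.groupby("line")["estimate"].mean()
        assert res.table["estimate"].var() <= means.var() + 1e-12

    def test_blup_accuracy_matches_entry_mean_h2(self):
        # shared-check multi-experiment design recovers sqrt(h2_entry)
        diffs = []
        for seed in range(10):
            panel = simpop.simulate_founders(330, 500, seed=300 + seed)
            pop = simpop.population_from_panel(panel)
            trait = simpop.assign_trait(pop, 150, h2=0.8, seed=400 + seed)
            plan = simpop.plan_for_trait(
                trait,
                n_experiments=8,
                lines_per_experiment=37,
                checks=tuple(pop.line_ids[:5]),
                reps_per_experiment=2,
            )
            rec = simpop.simulate_trials(pop, plan, seed=500 + seed)
            st1 = stage1_all_experiments(rec)
            res = stage2_blup(st1)
            bv = dict(zip(pop.line_ids, pop.true_bv))
            tab = res.table[res.table["line"].isin(bv)]
            r = np.corrcoef(
                [bv[l] for l in tab["line"]], tab["estimate"].to_numpy()
            )[0, 1]
            diffs.append(r - np.sqrt(trait.entry_mean_h2(2)))
        assert abs(np.mean(diffs)) < 0.05


class TestCombineSources:
    def _lv(self, lines, values):
        return LineValues(
            table=pd.DataFrame({"line": lines, "estimate": values, "se": np.nan}),
            kind="stage1",
        )

    def test_identical_sources(self):
        lv = self._lv(["a", "b", "c"], [1.0, 2.0, 3.0])
        merged, r = combine_sources(lv, lv)
        assert r == pytest.approx(1.0)
        np.testing.assert_allclose(
            merged.table["estimate"].to_numpy(), [1.0, 2.0, 3.0]
        )

    def test_constant_source_flagged(self):
        a = self._lv(["a", "b", "c"], [1.0, 1.0, 1.0])
        b = self._lv(["a", "b", "c"], [1.0, 2.0, 3.0])
        merged, r = combine_sources(a, b)
        assert r is None and merged.meta["constant_source"]
        np.testing.assert_allclose(
            merged.table["estimate"].to_numpy(), [1.0, 2.0, 3.0]
        )

    def test_merged_at_least_as_accurate_as_sources(self):
        gains = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            truth = rng.normal(0, 1, 100)
            a = truth + rng.normal(0, 0.8, 100)
            b = truth + rng.normal(0, 0.8, 100)
            lines = [f"L{i}" for i in range(100)]
            merged, r = combine_sources(self._lv(lines, a), self._lv(lines, b))
            rm = np.corrcoef(truth, merged.table["estimate"])[0, 1]
            best = max(np.corrcoef(truth, a)[0, 1], np.corrcoef(truth, b)[0, 1])
            gains.append(rm - best)
        assert np.mean(gains) > 0

    def test_dual_seed_source_consistency(self):
        # independent trial sets over the same lines correlate strongly
        panel = simpop.simulate_founders(330, 400, seed=42)
        pop = simpop.population_from_panel(panel)
        trait = simpop.assign_trait(pop, 100, h2=0.8, seed=43)
        plan = simpop.plan_for_trait(
            trait,
            n_experiments=8,
            lines_per_experiment=37,
            checks=tuple(pop.line_ids[:5]),
            reps_per_experiment=2,
        )
        vals = []
        for seed in (44, 45):
            rec = simpop.simulate_trials(pop, plan, seed=seed)
            res = stage2_blup(stage1_all_experiments(rec))
            vals.append(res)
        _, r = combine_sources(*vals)
        assert r > 0.7
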