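"""Trait integration: module-trait correlation, PLS/VIP, UpSet sets."""

import itertools

import numpy as np
import pandas as pd
import pytest

from stresscape import coexpression as coex
from stresscape import diffexpr as de
from stresscape import synthetic as syn
from stresscape import traits as tr


def _samples(n):
    return [f"s{i}" for i in range(n)]


class TestModuleTraitCorr:
    def test_identity_trait_perfect_correlation(self):
        rng = np.random.default_rng(0)
        me = rng.normal(size=50)
        eig = pd.DataFrame([me], index=pd.Index([1], name="module"), columns=_samples(50))
        traits = pd.DataFrame({"t": me}, index=_samples(50))
        res = tr.module_trait_corr(eig, traits)
        row = res.table.iloc[0]
        assert row["r"] == pytest.approx(1.0)
        assert row["p"] == pytest.approx(0.0, abs=1e-30)
        assert row["significant"]

    def test_hand_dataset_matches_brute_force(self):
        x = np.array([1.0, 2.0, 4.0, 4.5, 6.0, 9.0])
        y = np.array([0.5, 1.1, 1.9, 2.4, 2.9, 4.6])
        eig = pd.DataFrame([x], index=pd.Index([1], name="module"), columns=_samples(6))
        traits = pd.DataFrame({"t": y}, index=_samples(6))
        res = tr.module_trait_corr(eig, traits)
        # brute-force Pearson from raw sums
        n = 6
        r_exp = (n * (x * y).sum() - x.sum() * y.sum()) / np.sqrt(
            (n * (x**2).sum() - x.sum() ** 2) * (n * (y**2).sum() - y.sum() ** 2)
        )
        assert res.table.iloc[0]["r"] == pytest.approx(r_exp, abs=1e-12)

    def test_null_calibration(self):
        rng = np.random.default_rng(1)
        n, sims = 100, 1000
        hits = 0
        for _ in range(sims):
            x, y = rng.normal(size=n), rng.normal(size=n)
            r = np.corrcoef(x, y)[0, 1]
            from scipy import stats as ss
            t = r * np.sqrt((n - 2) / (1 - r * r))
            hits += 2 * ss.t.sf(abs(t), n - 2) <= 1e-3
        assert hits / sims <= 0.005  # ~0.001 expected, generous MC margin

    def test_symmetry_and_affine_invariance(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=30), rng.normal(size=30)
        eig = pd.DataFrame([x], index=pd.Index([1], name="module"), columns=_samples(30))
        t1 = pd.DataFrame({"t": y}, index=_samples(30))
        r1 = tr.module_trait_corr(eig, t1).table.iloc[0]["r"]
        eig2 = pd.DataFrame([y], index=pd.Index([1], name="module"), columns=_samples(30))
        t2 = pd.DataFrame({"t": x}, index=_samples(30))
        r2 = tr.module_trait_corr(eig2, t2).table.iloc[0]["r"]
        assert r1 == pytest.approx(r2, abs=1e-12)
        t3 = pd.DataFrame({"t": 3.5 * y - 2.0}, index=_samples(30))
        r3 = tr.module_trait_corr(eig, t3).table.iloc[0]["r"]
        assert r3 == pytest.approx(r1, abs=1e-12)

    def test_missing_values_dropped_pairwise(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=20)
        y = x + rng.normal(0, 0.1, 20)
        y[:3] = np.nan
        eig = pd.DataFrame([x], index=pd.Index([1], name="module"), columns=_samples(20))
        traits = pd.DataFrame({"t": y}, index=_samples(20))
        res = tr.module_trait_corr(eig, traits)
        assert res.table.iloc[0]["n"] == 17
        assert res.table.iloc[0]["r"] > 0.9

    def test_too_few_overlapping_samples_flagged(self):
        x = np.arange(10.0)
        y = np.full(10, np.nan)
        y[:3] = [1.0, 2.0, 3.0]
        eig = pd.DataFrame([x], index=pd.Index([1], name="module"), columns=_samples(10))
        traits = pd.DataFrame({"t": y}, index=_samples(10))
        res = tr.module_trait_corr(eig, traits)
        assert not res.table.iloc[0]["testable"]

    def test_planted_loading_detected(self, full_design):
        """Traits with |loading| >= 1 on a module come out significant for
        that module's eigengene."""
        hits = total = 0
        for seed in range(10):
            cfg = syn.TruthConfig(n_genes=300, n_cyanorons=0, de_fraction=0.0)
            truth = syn.make_planted_truth(full_design, cfg, seed=seed)
            trait_table = syn.generate_traits(full_design, truth, 0.3, seed=seed)
            eig = truth.latent_factors.copy()
            eig.columns = full_design.sample_ids
            res = tr.module_trait_corr(eig, trait_table)
            for trait_name in truth.trait_loadings.index:
                for m in truth.module_ids:
                    if abs(truth.trait_loadings.loc[trait_name, m]) >= 1.0:
                        total += 1
                        sub = res.table
                        row = sub[(sub["module"] == m) & (sub["trait"] == trait_name)]
                        hits += bool(row["significant"].iloc[0])
        assert hits / total >= 0.95


class TestPlsVip:
    def test_single_predictor_vip_is_one(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=30)
        expr = pd.DataFrame([x], index=["g0"], columns=_samples(30))
        trait = pd.Series(2 * x + rng.normal(0, 0.5, 30), index=_samples(30), name="t")
        res = tr.pls_vip(expr, trait)
        assert res.table["vip"].iloc[0] == pytest.approx(1.0, abs=1e-10)

    def test_mean_square_vip_identity(self):
        rng = np.random.default_rng(5)
        for p, n_comp in [(5, 1), (20, 2), (40, 3)]:
            X = rng.normal(size=(30, p))
            y = X @ rng.normal(size=p) + rng.normal(size=30)
            expr = pd.DataFrame(X.T, index=[f"g{i}" for i in range(p)],
                                columns=_samples(30))
            trait = pd.Series(y, index=_samples(30), name="t")
            vip = tr.pls_vip(expr, trait, n_components=n_comp).table["vip"]
            assert np.mean(vip**2) == pytest.approx(1.0, abs=1e-10)

    def test_informative_gene_flagged(self):
        rng = np.random.default_rng(6)
        hits = 0
        for _ in range(100):
            X = rng.normal(size=(50, 20))
            y = X[:, 7] + 0.5 * rng.normal(size=50)
            expr = pd.DataFrame(X.T, index=[f"g{i}" for i in range(20)],
                                columns=_samples(50))
            res = tr.pls_vip(expr, pd.Series(y, index=_samples(50), name="t"))
            v = res.table.set_index("gene_id")["vip"]
            hits += (v.idxmax() == "g7") and (v["g7"] > 1)
        assert hits >= 95

    def test_constant_trait_rejected(self):
        expr = pd.DataFrame(np.random.default_rng(7).normal(size=(5, 20)),
                            index=[f"g{i}" for i in range(5)], columns=_samples(20))
        with pytest.raises(ValueError):
            tr.pls_vip(expr, pd.Series(1.0, index=_samples(20), name="t"))

    def test_too_few_samples_rejected(self):
        rng = np.random.default_rng(8)
        expr = pd.DataFrame(rng.normal(size=(5, 3)),
                            index=[f"g{i}" for i in range(5)], columns=_samples(3))
        trait = pd.Series(rng.normal(size=3), index=_samples(3), name="t")
        with pytest.raises(ValueError):
            tr.pls_vip(expr, trait, n_components=2)


def _de_result_from_patterns(patterns, conditions, times=(1.0, 6.0)):
    """Build a DEResult whose status encodes the given hit patterns:
    patterns[gene] = set of conditions where the gene is DE at time 1.0."""
    rows = []
    for g, hit in patterns.items():
        for c in conditions:
            for t in times:
                is_hit = c in hit and t == times[0]
                rows.append(
                    dict(gene_id=g, condition=c, time_h=t,
                         log2fc=2.0 if is_hit else 0.0, se=0.1,
                         p=0.001 if is_hit else 0.9,
                         padj=0.01 if is_hit else 0.95,
                         status="up" if is_hit else "ns")
                )
    return de.DEResult(table=pd.DataFrame(rows))


class TestUpset:
    conditions = ["LLHL", "LLUV", "LLLT"]

    def test_single_condition_gene(self):
        res = _de_result_from_patterns({"g0": {"LLHL"}}, self.conditions)
        up = tr.upset_classify(res, self.conditions)
        assert up.genes["g0"] == frozenset({"LLHL"})

    def test_all_conditions_gene(self):
        res = _de_result_from_patterns({"g0": set(self.conditions)}, self.conditions)
        up = tr.upset_classify(res, self.conditions)
        assert up.genes["g0"] == frozenset(self.conditions)

    def test_counts_match_power_set_enumeration(self):
        rng = np.random.default_rng(9)
        patterns = {}
        for i in range(500):
            hit = {c for c in self.conditions if rng.random() < 0.3}
            patterns[f"g{i}"] = hit
        res = _de_result_from_patterns(patterns, self.conditions)
        up = tr.upset_classify(res, self.conditions)
        # brute-force power-set enumeration
        expected = {}
        for r in range(1, 4):
            for combo in itertools.combinations(self.conditions, r):
                key = "+".join(sorted(combo))
                expected[key] = sum(
                    1 for hit in patterns.values() if hit == set(combo)
                )
        observed = up.counts.groupby("set")["n_genes"].sum().to_dict()
        for key, n in expected.items():
            assert observed.get(key, 0) == n

    def test_partition_property(self):
        rng = np.random.default_rng(10)
        patterns = {
            f"g{i}": {c for c in self.conditions if rng.random() < 0.4}
            for i in range(300)
        }
        res = _de_result_from_patterns(patterns, self.conditions)
        up = tr.upset_classify(res, self.conditions)
        ever_de = sum(1 for hit in patterns.values() if hit)
        assert up.counts["n_genes"].sum() == ever_de
        assert len(up.genes) == ever_de

    def test_module_breakdown(self):
        patterns = {"g0": {"LLHL"}, "g1": {"LLHL"}, "g2": {"LLUV"}}
        res = _de_result_from_patterns(patterns, self.conditions)
        table = pd.DataFrame({"gene_id": ["g0", "g1", "g2"], "module": [1, 2, 1],
                              "submodule": ""})
        up = tr.upset_classify(res, self.conditions, coex.ModuleAssignment(table=table))
        c = up.counts.set_index(["set", "module"])["n_genes"]
        assert c[("LLHL", 1)] == 1 and c[("LLHL", 2)] == 1 and c[("LLUV", 1)] == 1

    def test_empty_universe_rejected(self):
        res = _de_result_from_patterns({"g0": set()}, self.conditions)
        with pytest.raises(ValueError):
            tr.upset_classify(res, [])

    def test_missing_condition_rejected(self):
        res = _de_result_from_patterns({"g0": set()}, ["LLHL"])
        with pytest.raises(ValueError):
            tr.upset_classify(res, ["LLHL", "HLUV"])
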