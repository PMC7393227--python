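"""Generator contracts: design arithmetic, determinism, planted structure."""

import numpy as np
import pandas as pd
import pytest

from stresscape import synthetic as syn


class TestDesign:
    def test_shared_t0_gives_study_sample_count(self, full_design):
        assert full_design.n_samples == 154

    def test_unshared_t0_gives_naive_sum(self):
        d = syn.generate_design(syn.default_design_config(share_t0=False))
        assert d.n_samples == 7 * 5 * 3 + 2 * 8 * 4 == 169

    def test_minimal_design_counts_samples_directly(self):
        cfg = syn.DesignConfig(
            conditions=(syn.ConditionSpec("LL", "X", (0, 1), 1),), share_t0=False
        )
        assert syn.generate_design(cfg).n_samples == 2

    def test_sample_triples_unique(self, full_design):
        t = full_design.table
        assert not t["sample_id"].duplicated().any()
        assert not t[["condition", "time_h", "replicate"]].duplicated().any()

    def test_every_shift_condition_resolves_shared_reference(self, full_design):
        for acc, cond in [("LL", "LLUV"), ("HL", "HLLT")]:
            refs = full_design.reference_samples(cond)
            assert len(refs) == 3
            assert all(r.startswith(f"{acc}_T0") for r in refs)

    def test_ld_reference_is_six_am(self, full_design):
        refs = full_design.reference_samples("LD21")
        t = full_design.table.set_index("sample_id")
        assert len(refs) == 4
        assert (t.loc[refs, "time_h"] == 6.0).all()

    def test_rejects_empty_or_unreplicated_config(self):
        with pytest.raises(ValueError):
            syn.DesignConfig(conditions=())
        with pytest.raises(ValueError):
            syn.ConditionSpec("LL", "X", (0, 1), 0)


class TestCounts:
    def test_same_seed_bit_identical(self, full_design):
        truth = syn.make_planted_truth(full_design, syn.TruthConfig(n_genes=60), seed=5)
        a = syn.generate_counts(full_design, truth, seed=5)
        b = syn.generate_counts(full_design, truth, seed=5)
        assert a.counts.equals(b.counts)

    def test_null_poisson_limit_means_match_baseline(self, two_group_design):
        # alpha -> 0, no effects, no library spread: sample means converge
        truth = syn.make_planted_truth(
            two_group_design,
            syn.TruthConfig(n_genes=200, module_fractions=(0.0,), mirror_pair=None,
                            de_fraction=0.0, n_cyanorons=0),
            seed=1,
        )
        truth.nb_dispersion[:] = 0.0
        truth.baseline_mean[:] = 1000.0
        cm = syn.generate_counts(two_group_design, truth, seed=1, library_size_sd=0.0)
        means = cm.counts.mean(axis=1)
        assert np.allclose(means, 1000.0, rtol=0.05)

    def test_planted_lfc_doubles_mean_ratio(self):
        # planted log2FC = 2 -> stress/control normalized mean ratio ~ 4
        cfg = syn.DesignConfig(
            conditions=(syn.ConditionSpec("LL", "LLHL", (0, 6), 1000),), share_t0=False
        )
        d = syn.generate_design(cfg)
        truth = syn.make_planted_truth(
            d, syn.TruthConfig(n_genes=20, module_fractions=(0.0,), mirror_pair=None,
                               de_fraction=0.0, n_cyanorons=0), seed=2
        )
        truth.nb_dispersion[:] = 0.1
        truth.de_truth[("LLHL", 6.0)][3] = 2.0
        cm = syn.generate_counts(d, truth, seed=2, library_size_sd=0.0)
        stress = d.samples_of("LLHL", 6.0)
        ctrl = d.samples_of("LLHL", 0.0)
        ratio = cm.counts.loc[truth.gene_ids[3], stress].mean() / cm.counts.loc[
            truth.gene_ids[3], ctrl
        ].mean()
        assert ratio == pytest.approx(4.0, rel=0.1)

    def test_dimension_mismatch_rejected(self, full_design, two_group_design):
        truth = syn.make_planted_truth(two_group_design, syn.TruthConfig(n_genes=30), seed=0)
        with pytest.raises(ValueError, match="latent factors"):
            syn.generate_counts(full_design, truth, seed=0)


class TestTruth:
    def test_latent_factors_zero_mean_and_mirrored(self, full_design):
        truth = syn.make_planted_truth(full_design, syn.TruthConfig(n_genes=100), seed=7)
        f = truth.latent_factors.to_numpy()
        assert np.allclose(f.mean(axis=1), 0.0, atol=1e-12)
        assert np.allclose(f[1], -f[0])

    def test_cyanoron_runs_share_module_and_min_length(self, full_design):
        cfg = syn.TruthConfig(n_genes=300, n_cyanorons=4)
        truth = syn.make_planted_truth(full_design, cfg, seed=9)
        assert truth.cyanoron_truth
        for s, e, m in truth.cyanoron_truth:
            assert e - s + 1 >= cfg.cyanoron_length[0]
            assert (truth.module_labels[s : e + 1] == m).all()

    def test_planted_lfc_queryable(self, full_design):
        truth = syn.make_planted_truth(full_design, syn.TruthConfig(n_genes=100), seed=3)
        any_nonzero = any(
            truth.planted_lfc(g, c, t) != 0
            for (c, t) in truth.de_truth
            for g in range(100)
        )
        assert any_nonzero
        assert truth.planted_lfc(0, "LLHL", 999.0) == 0.0


class TestTraits:
    def test_noiseless_identity_and_sign_flip(self, full_design):
        truth = syn.make_planted_truth(
            full_design, syn.TruthConfig(n_genes=50),
            seed=4,
            traits={"pos": {1: 1.0}, "neg": {1: -1.0}},
        )
        t = syn.generate_traits(full_design, truth, noise_sd=0.0, seed=4)
        f1 = truth.latent_factors.loc[1].to_numpy()
        assert np.allclose(t["pos"].to_numpy(), f1)
        assert np.corrcoef(t["neg"], f1)[0, 1] == pytest.approx(-1.0)

    def test_noisy_trait_recoverably_correlated(self, full_design):
        hits = 0
        for seed in range(20):
            truth = syn.make_planted_truth(
                full_design, syn.TruthConfig(n_genes=50), seed=seed,
                traits={"t": {1: 1.0}},
            )
            t = syn.generate_traits(full_design, truth, noise_sd=0.3, seed=seed)
            r = np.corrcoef(t["t"], truth.latent_factors.loc[1])[0, 1]
            hits += abs(r) > 0.9
        assert hits >= 19

    def test_negative_noise_rejected(self, full_design):
        truth = syn.make_planted_truth(full_design, syn.TruthConfig(n_genes=20), seed=0)
        with pytest.raises(ValueError):
            syn.generate_traits(full_design, truth, noise_sd=-1.0, seed=0)


class TestAnnotation:
    def test_construction_keeps_planted_runs_adjacent(self, full_design):
        truth = syn.make_planted_truth(
            full_design, syn.TruthConfig(n_genes=10, n_cyanorons=0), seed=0
        )
        truth.cyanoron_truth = [(2, 6, 1)]
        truth.module_labels[2:7] = 1
        ann = syn.generate_annotation(10, truth, seed=0)
        idx = ann.table.set_index("gene_id")["genome_index"]
        members = [truth.gene_ids[i] for i in range(2, 7)]
        assert sorted(idx[members]) == list(range(2, 7))

    def test_default_gene_count(self, full_design):
        truth = syn.make_planted_truth(full_design, syn.TruthConfig(), seed=0)
        ann = syn.generate_annotation(2634, truth, seed=0)
        assert ann.n_genes == 2634

    def test_coordinates_sorted_non_overlapping(self):
        ann = syn.generate_annotation(100, seed=1)
        t = ann.table
        assert (t["start"].to_numpy()[1:] > t["end"].to_numpy()[:-1]).all()

    def test_too_few_genes_rejected(self, full_design):
        truth = syn.make_planted_truth(
            full_design, syn.TruthConfig(n_genes=300, n_cyanorons=2), seed=0
        )
        with pytest.raises(ValueError):
            syn.generate_annotation(10, truth, seed=0)


class TestKinetics:
    def test_no_repair_limit_series_identical(self):
        c, i = syn.generate_kinetics(0.2, 0.0, noise_sd=0.0)
        assert np.allclose(c.values, i.values)

    def test_coefficient_difference_is_repair_rate(self):
        c, i = syn.generate_kinetics(0.2, 0.3, y0=0.6, noise_sd=0.0)
        t = c.times
        assert np.allclose(c.values, 0.6 * np.exp(-0.2 * t))
        assert np.allclose(i.values, 0.6 * np.exp(-0.5 * t))

    def test_values_clipped_to_unit_interval(self):
        c, i = syn.generate_kinetics(0.1, 0.1, y0=0.99, noise_sd=0.5, seed=3)
        for s in (c, i):
            assert ((s.values >= 0) & (s.values <= 1)).all()

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            syn.generate_kinetics(-0.1, 0.1)
        with pytest.raises(ValueError):
            syn.generate_kinetics(0.1, 0.1, noise_sd=-1)
        with pytest.raises(ValueError):
            syn.generate_kinetics(0.1, 0.1, times=np.array([]))


class TestSpectrum:
    def test_configured_heights_at_peak_centres(self):
        s = syn.generate_spectrum((2.0, 1.0, 0.5))
        w, y = s["wavelength_nm"].to_numpy(), s["intensity"].to_numpy()
        for center, h in [(570, 2.0), (650, 1.0), (680, 0.5)]:
            assert y[np.argmin(np.abs(w - center))] == pytest.approx(h, rel=1e-3)

    def test_grid_must_cover_peaks(self):
        with pytest.raises(ValueError):
            syn.generate_spectrum((1, 1, 1), grid=np.arange(600.0, 660.0))

    def test_negative_heights_rejected(self):
        with pytest.raises(ValueError):
            syn.generate_spectrum((-1, 1, 1))


def test_generators_deterministic_across_calls(full_design):
    """Any generator called twice with the same seed yields identical output."""
    t1 = syn.make_planted_truth(full_design, syn.TruthConfig(n_genes=80), seed=13)
    t2 = syn.make_planted_truth(full_design, syn.TruthConfig(n_genes=80), seed=13)
    assert np.array_equal(t1.module_labels, t2.module_labels)
    assert t1.latent_factors.equals(t2.latent_factors)
    tr1 = syn.generate_traits(full_design, t1, 0.3, seed=13)
    tr2 = syn.generate_traits(full_design, t2, 0.3, seed=13)
    assert tr1.equals(tr2)
    a1 = syn.generate_annotation(80, t1, seed=13)
    a2 = syn.generate_annotation(80, t2, seed=13)
    assert a1.table.equals(a2.table)
    s1 = syn.generate_spectrum((1, 1, 1), noise_sd=0.05, seed=13)
    s2 = syn.generate_spectrum((1, 1, 1), noise_sd=0.05, seed=13)
    assert s1.equals(s2)
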