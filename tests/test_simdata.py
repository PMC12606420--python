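"""Simulator behavior: founder panels, mosaics, selection, sequencing."""

import numpy as np
import pytest

import xqtlmap as xm
from xqtlmap.simdata import ConfigError


def _uniform_weights(F=8):
    return np.full(F, 1.0 / F)


class TestSimulateFounders:
    def test_seeded_determinism(self, small_config):
        p1 = xm.simulate_founders(small_config)
        p2 = xm.simulate_founders(small_config)
        assert np.array_equal(p1.alleles, p2.alleles)
        assert p1.snps.equals(p2.snps)

    def test_informative_fraction_extremes(self):
        cfg_all = xm.SimConfig(seed=1, chrom_lengths_cm={"chr1": 10.0},
                               snps_per_cm=20, informative_fraction=1.0)
        cfg_none = xm.SimConfig(seed=1, chrom_lengths_cm={"chr1": 10.0},
                                snps_per_cm=20, informative_fraction=0.0)
        assert xm.simulate_founders(cfg_all).informative_mask().all()
        assert not xm.simulate_founders(cfg_none).informative_mask().any()

    def test_two_founder_panel_all_informative(self):
        cfg = xm.SimConfig(seed=3, n_founders=2, chrom_lengths_cm={"chr1": 5.0},
                           snps_per_cm=10)
        panel = xm.simulate_founders(cfg)
        assert (panel.alleles[:, 0] != panel.alleles[:, 1]).all()

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            xm.SimConfig(n_founders=1)
        with pytest.raises(ConfigError):
            xm.SimConfig(chrom_lengths_cm={})


class TestBasePopulation:
    def test_degenerate_weights_single_founder(self, toy_map, rng):
        w = np.zeros(8)
        w[0] = 1.0
        pop = xm.simulate_base_population(toy_map, 20, 10, w, rng)
        fo = pop.founder_of_origin("chr1", np.linspace(0.1, 19.9, 7))
        assert (fo == 0).all()

    def test_locus_frequencies_match_weights(self, toy_map, rng):
        n = 10_000
        pop = xm.simulate_base_population(toy_map, n, 5, _uniform_weights(), rng)
        loci = rng.uniform(0, 20, size=10)
        freqs = pop.founder_frequencies("chr1", np.sort(loci), 8)
        sd = np.sqrt((1 / 8) * (7 / 8) / (2 * n))
        assert np.all(np.abs(freqs - 1 / 8) < 3 * sd + 1e-12)

    def test_breakpoints_scale_with_generations(self, toy_map, rng):
        def mean_breaks(gens):
            pop = xm.simulate_base_population(toy_map, 2000, gens,
                                              _uniform_weights(), rng)
            d = pop._data["chr1"]
            return np.diff(d["offsets"]).mean()

        m1, m2 = mean_breaks(10), mean_breaks(20)
        # Poisson mean = generations * 0.2 Morgans
        assert m1 == pytest.approx(2.0, rel=0.1)
        assert m2 / m1 == pytest.approx(2.0, rel=0.15)

    def test_segments_tile_chromosome(self, toy_map, rng):
        pop = xm.simulate_base_population(toy_map, 5, 30, _uniform_weights(), rng)
        for ind in pop:
            for homolog in ind.segments["chr1"]:
                assert homolog[0][0] == 0.0
                assert homolog[-1][1] == pytest.approx(20.0)
                for (s0, e0, _), (s1, e1, _) in zip(homolog, homolog[1:]):
                    assert e0 == pytest.approx(s1)  # no gaps, no overlap

    def test_off_simplex_weights_rejected(self, toy_map, rng):
        with pytest.raises(ConfigError):
            xm.simulate_base_population(toy_map, 5, 5, np.full(8, 0.2), rng)


class TestViabilitySelection:
    def test_neutral_selection_preserves_frequencies(self, toy_map, rng):
        pop = xm.simulate_base_population(toy_map, 8000, 10, _uniform_weights(), rng)
        survivors, frac = xm.apply_viability_selection(
            pop, xm.QTLEffectModel(), 0.5, rng)
        assert frac == pytest.approx(0.5, abs=0.03)
        f = survivors.founder_frequencies("chr1", np.array([10.0]), 8)
        assert np.all(np.abs(f - 1 / 8) < 0.03)

    def test_lethal_founder_absent_among_survivors(self, toy_map, rng):
        s = np.zeros(8)
        s[2] = -1.0
        model = xm.QTLEffectModel(loci=[("chr1", 10.0, s)])
        pop = xm.simulate_base_population(toy_map, 4000, 10, _uniform_weights(), rng)
        survivors, _ = xm.apply_viability_selection(pop, model, 0.3, rng)
        f = survivors.founder_frequencies("chr1", np.array([10.0]), 8)
        assert f[0, 2] == 0.0

    def test_small_s_frequency_shift_matches_pqs(self, toy_map):
        rng = np.random.default_rng(7)
        s_val, p0 = 0.1, 1 / 8
        s = np.zeros(8)
        s[0] = s_val
        model = xm.QTLEffectModel(loci=[("chr1", 10.0, s)])
        deltas = []
        for _ in range(20):
            pop = xm.simulate_base_population(toy_map, 5000, 10,
                                              _uniform_weights(), rng)
            sel, _ = xm.apply_viability_selection(pop, model, 0.1, rng)
            before = pop.founder_frequencies("chr1", np.array([10.0]), 8)[0, 0]
            after = sel.founder_frequencies("chr1", np.array([10.0]), 8)[0, 0]
            deltas.append(after - before)
        expected = p0 * (1 - p0) * s_val
        se = np.std(deltas) / np.sqrt(len(deltas))
        assert np.mean(deltas) == pytest.approx(expected, abs=3 * se + 0.002)

    def test_invalid_target_rejected(self, toy_map, rng):
        pop = xm.simulate_base_population(toy_map, 10, 5, _uniform_weights(), rng)
        with pytest.raises(ConfigError):
            xm.apply_viability_selection(pop, xm.QTLEffectModel(), 0.0, rng)


class TestSequencePool:
    def test_fixed_ref_site_with_zero_error(self, toy_map, rng):
        cfg = xm.SimConfig(seed=5, n_founders=8, chrom_lengths_cm={"chr1": 20.0},
                           snps_per_cm=10)
        panel = xm.simulate_founders(cfg)
        w = np.zeros(8)
        w[0] = 1.0  # pool fixed for founder 1
        pop = xm.simulate_base_population(toy_map, 50, 5, w, rng)
        counts = xm.sequence_pool(pop, panel, toy_map, 30.0, 0.0, rng)
        ref_sites = panel.alleles[:, 0] == 1
        assert (counts.alt_count[ref_sites] == 0).all()
        assert (counts.ref_count[~ref_sites] == 0).all()

    def test_zero_coverage_gives_empty_depth(self, toy_map, rng, small_experiment):
        _, _, panel, gmap = small_experiment
        pop = xm.simulate_base_population(toy_map, 10, 5, _uniform_weights(), rng)
        counts = xm.sequence_pool(pop, panel, toy_map, 0.0, 0.001, rng)
        assert (counts.depth == 0).all()

    def test_high_coverage_concentrates_on_truth(self, toy_map, rng):
        cfg = xm.SimConfig(seed=6, chrom_lengths_cm={"chr1": 20.0}, snps_per_cm=5)
        panel = xm.simulate_founders(cfg)
        pop = xm.simulate_base_population(toy_map, 200, 10, _uniform_weights(), rng)
        counts = xm.sequence_pool(pop, panel, toy_map, 10_000.0, 0.0, rng)
        obs = counts.ref_count / counts.depth
        snp_cm = toy_map.cm("chr1", panel.snps["pos"].to_numpy())
        fo = pop.founder_of_origin("chr1", snp_cm)
        truth = (panel.alleles[np.arange(panel.n_snps)[None, :], fo] == 1).mean(axis=0)
        assert np.all(np.abs(obs - truth) < 0.02)


class TestSimulateExperiment:
    def test_paper_design_emits_29_pools(self):
        cfg = xm.SimConfig(seed=9, n_replicates=12, pool_size_range=(60, 60),
                           survival_target=0.3,
                           duplicate_control_replicates=(5, 6, 8, 11, 12),
                           chrom_lengths_cm={"chr1": 10.0}, snps_per_cm=10)
        pools, truth, _ = xm.simulate_experiment(cfg)
        assert len(pools) == 29
        meta = xm.pool_metadata(pools)
        assert (meta["treatment"] == "selected").sum() == 12
        assert (meta["duplicate_label"] == "B").sum() == 5

    def test_no_qtl_model_records_zero_planted_qtl(self, small_experiment):
        _, truth, _, _ = small_experiment
        assert truth.qtl == []

    def test_seeded_runs_are_byte_identical(self, small_config):
        pools1, _, _ = xm.simulate_experiment(small_config)
        pools2, _, _ = xm.simulate_experiment(small_config)
        for a, b in zip(pools1, pools2):
            assert a.pool_id == b.pool_id
            assert np.array_equal(a.ref_count, b.ref_count)
            assert np.array_equal(a.alt_count, b.alt_count)

    def test_truth_tracks_lie_on_simplex(self, small_experiment):
        _, truth, _, _ = small_experiment
        for by_chrom in truth.pool_freqs.values():
            for freqs in by_chrom.values():
                assert np.all(freqs >= 0)
                assert np.allclose(freqs.sum(axis=1), 1.0, atol=1e-9)

    def test_selection_direction_property(self):
        """A founder with positive s rises in selected relative to control pools."""
        s = np.zeros(8)
        s[0] = 0.5
        cfg = xm.SimConfig(seed=11, n_replicates=6, pool_size_range=(150, 150),
                           survival_target=0.1, duplicate_control_replicates=(),
                           chrom_lengths_cm={"chr1": 20.0}, snps_per_cm=10,
                           founder_weights={"chr1": np.array([0.25] + [0.75 / 7] * 7)})
        model = xm.QTLEffectModel(loci=[("chr1", 10.0, s)])
        pools, truth, _ = xm.simulate_experiment(cfg, model)
        centers = truth.centers_cm["chr1"]
        w = int(np.argmin(np.abs(centers - 10.0)))
        sel = np.mean([truth.pool_freqs[p.pool_id]["chr1"][w, 0]
                       for p in pools if p.treatment == "selected"])
        ctl = np.mean([truth.pool_freqs[p.pool_id]["chr1"][w, 0]
                       for p in pools if p.treatment == "control"])
        assert sel - ctl > 0
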