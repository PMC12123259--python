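"""Generator determinism, kernel shape, ranges and site sampling."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from rewirenet import synthdata as sd
from rewirenet.dataio import CONSUMER, RESOURCE
from rewirenet.synthdata import ConfigError, SynthConfig


class TestConfig:
    def test_rejects_nonpositive_counts(self):
        with pytest.raises(ConfigError):
            SynthConfig(n_resource=0)

    @pytest.mark.parametrize("field,value", [("p_max", 1.2), ("p_detect", -0.1), ("delta_cat", 2.0)])
    def test_rejects_out_of_range_probabilities(self, field, value):
        with pytest.raises(ConfigError):
            SynthConfig(**{field: value})


class TestTraits:
    def test_deterministic_given_seed(self, small_config):
        r1, c1 = sd.gen_traits(small_config)
        r2, c2 = sd.gen_traits(small_config)
        assert r1.data.equals(r2.data) and c1.data.equals(c2.data)

    def test_schema_shape(self, small_eco):
        res, con = small_eco.resource, small_eco.consumer
        assert res.trophic_level == RESOURCE and con.trophic_level == CONSUMER
        assert len(res.numeric_traits()) >= 3 and len(res.categorical_traits()) >= 1
        assert len(con.numeric_traits()) >= 3 and len(con.categorical_traits()) >= 1
        assert res.data["taxon_group"].nunique() > 1

    def test_matching_trait_lognormal_mean(self):
        # law-of-large-numbers check on the corolla generator
        cfg = SynthConfig(seed=7, n_resource=10_000)
        res, _ = sd.gen_traits(cfg)
        logs = np.log(res.data["corolla_length"])
        se = logs.std() / math.sqrt(len(logs))
        assert abs(logs.mean() - cfg.corolla_log_mean) < 3 * se


class TestKernel:
    def test_peak_at_perfect_match(self):
        cfg = SynthConfig(p_max=0.8)
        r = pd.Series({"corolla_length": 10.0, "flower_color": "red"})
        c = pd.Series({"bill_length": 10.0, "color_preference": "red"})
        assert sd.true_link_prob(r, c, cfg, sigma=1.0) == pytest.approx(0.8)

    def test_wide_tolerance_limit_with_mismatch(self):
        cfg = SynthConfig(p_max=0.8, delta_cat=0.25)
        r = pd.Series({"corolla_length": 5.0, "flower_color": "red"})
        c = pd.Series({"bill_length": 30.0, "color_preference": "white"})
        assert sd.true_link_prob(r, c, cfg, sigma=1e9) == pytest.approx(0.8 * 0.75, rel=1e-6)

    def test_hand_evaluated_value(self):
        cfg = SynthConfig(p_max=0.9, delta_cat=0.5)
        r = pd.Series({"corolla_length": 10.0, "flower_color": "red"})
        c = pd.Series({"bill_length": 12.0, "color_preference": "red"})
        assert sd.true_link_prob(r, c, cfg, sigma=2.0) == pytest.approx(0.9 * math.exp(-0.5), abs=1e-9)

    def test_rejects_nonpositive_sigma(self):
        r = pd.Series({"corolla_length": 10.0, "flower_color": "red"})
        c = pd.Series({"bill_length": 12.0, "color_preference": "red"})
        with pytest.raises(ConfigError):
            sd.true_link_prob(r, c, SynthConfig(), sigma=0.0)

    def test_monotone_in_trait_gap(self):
        cfg = SynthConfig(p_max=0.9, delta_cat=0.3)
        c = pd.Series({"bill_length": 15.0, "color_preference": "red"})
        gaps = np.linspace(0, 25, 40)
        ps = [
            sd.true_link_prob(
                pd.Series({"corolla_length": 15.0 + g, "flower_color": "red"}), c, cfg, 3.0
            )
            for g in gaps
        ]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_truth_matrix_matches_pairwise_kernel(self, small_eco):
        truth, res, con = small_eco.truth, small_eco.resource, small_eco.consumer
        rid, cid = res.species_ids[3], con.species_ids[5]
        expected = sd.true_link_prob(
            res.data.loc[rid], con.data.loc[cid], small_eco.config, truth.sigma[cid]
        )
        assert truth.p.loc[rid, cid] == pytest.approx(expected, rel=1e-12)

    def test_breadth_tracks_tolerance(self):
        # the recovery substrate: wider kernels admit more partners
        cfg = SynthConfig(seed=5, n_resource=60, n_consumer=40)
        res, con = sd.gen_traits(cfg)
        truth = sd.make_ground_truth(res, con, cfg)
        rho = spearmanr(truth.sigma, truth.niche_breadth().n_feasible).statistic
        assert rho > 0.5


class TestRanges:
    def test_every_species_occupies_a_cell(self, small_eco):
        for level in (RESOURCE, CONSUMER):
            assert (small_eco.grid.presence[level].sum(axis=1) >= 1).all()

    def test_zero_radius_keeps_centroid_cell_only(self):
        cfg = SynthConfig(seed=3, n_resource=5, n_consumer=5,
                          radius_log_mean_resource=-30, radius_log_sd_resource=1e-9,
                          radius_log_mean_consumer=-30, radius_log_sd_consumer=1e-9)
        res, con = sd.gen_traits(cfg)
        grid = sd.gen_ranges(cfg, res, con)
        assert (grid.presence[RESOURCE].sum(axis=1) == 1).all()

    def test_huge_radius_covers_all_cells(self):
        cfg = SynthConfig(seed=3, n_resource=4, n_consumer=4,
                          radius_log_mean_resource=10, radius_log_mean_consumer=10)
        res, con = sd.gen_traits(cfg)
        grid = sd.gen_ranges(cfg, res, con)
        assert grid.presence[RESOURCE].to_numpy().all()
        assert grid.presence[CONSUMER].to_numpy().all()

    def test_reproducible_presence_counts(self, small_config):
        r, c = sd.gen_traits(small_config)
        g1 = sd.gen_ranges(small_config, r, c)
        g2 = sd.gen_ranges(small_config, r, c)
        assert g1.presence[RESOURCE].equals(g2.presence[RESOURCE])


class TestSiteNetworks:
    def test_edges_local_to_site(self, small_eco):
        for net in small_eco.networks:
            for r, c in net.edges:
                assert r in net.resource_ids and c in net.consumer_ids

    def test_zero_detection_means_no_edges(self, small_config):
        cfg = sd.SynthConfig(**{**small_config.__dict__, "p_detect": 0.0})
        eco = sd.simulate(cfg)
        assert all(len(net.edges) == 0 for net in eco.networks)

    def test_certain_detection_of_certain_links_gives_full_graph(self, small_config):
        cfg = sd.SynthConfig(**{
            **small_config.__dict__,
            "p_detect": 1.0, "p_max": 1.0, "delta_cat": 0.0,
            "sigma_log_mean": 30.0, "sigma_log_sd": 1e-9,
        })
        eco = sd.simulate(cfg)
        for net in eco.networks:
            assert len(net.edges) == len(net.resource_ids) * len(net.consumer_ids)

    def test_observed_edge_fraction_binomial(self):
        # p_ij = 0.5 everywhere, p_detect = 0.8 -> edge fraction ~ 0.4
        cfg = SynthConfig(seed=9, n_resource=100, n_consumer=100, n_sites=1,
                          p_max=0.5, delta_cat=0.0, sigma_log_mean=30.0, sigma_log_sd=1e-9,
                          p_detect=0.8,
                          radius_log_mean_resource=10, radius_log_mean_consumer=10)
        eco = sd.simulate(cfg)
        net = eco.networks[0]
        n_pairs = len(net.resource_ids) * len(net.consumer_ids)
        assert n_pairs == 10_000
        frac = len(net.edges) / n_pairs
        se = math.sqrt(0.4 * 0.6 / n_pairs)
        assert abs(frac - 0.4) < 3 * se

    def test_too_many_sites_rejected(self, small_config):
        cfg = sd.SynthConfig(**{**small_config.__dict__, "n_sites": 10_000})
        res, con = sd.gen_traits(cfg)
        truth = sd.make_ground_truth(res, con, cfg)
        grid = sd.gen_ranges(cfg, res, con)
        with pytest.raises(sd.GenerationError):
            sd.gen_site_networks(grid, truth, cfg)


def test_simulation_bit_identical_across_runs(small_config, small_eco, tmp_path):
    eco2 = sd.simulate(small_config)
    assert eco2.resource.data.equals(small_eco.resource.data)
    assert eco2.truth.p.equals(small_eco.truth.p)
    assert [n.edges for n in eco2.networks] == [n.edges for n in small_eco.networks]
    sd.write_ecosystem(small_eco, tmp_path)
    assert (tmp_path / "ground_truth.csv").exists()
    assert (tmp_path / "resource_traits.csv.schema.json").exists()
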