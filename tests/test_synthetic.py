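import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from betascape import beta as beta_mod
from betascape import metrics, synthetic
from betascape.design import HexGrid
from betascape.errors import ConfigurationError, DesignError, DomainError
from betascape.synthetic import (
    LandscapeTruth,
    SimulationConfig,
    generate_communities,
    generate_habitat_raster,
    generate_species_pool,
    generate_study,
)


class TestConfig:
    def test_defaults_valid(self):
        SimulationConfig()

    def test_unordered_range_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(habitat_amount_range=(0.9, 0.1))

    def test_min_two_inventories(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(inventories_per_landscape_range=(1, 5))

    def test_mix_must_sum_to_one(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(endemism_mix=(0.5, 0.5, 0.5, 0, 0))

    def test_from_dict_rejects_unknown_keys(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig.from_dict({"bogus": 1})

    def test_yaml_roundtrip(self, tmp_path):
        p = tmp_path / "c.yaml"
        p.write_text("n_landscapes: 7\nhabitat_amount_range: [0.1, 0.8]\n")
        cfg = SimulationConfig.from_yaml(p)
        assert cfg.n_landscapes == 7
        assert cfg.habitat_amount_range == (0.1, 0.8)


class TestHabitatRaster:
    def test_saturation(self):
        r = generate_habitat_raster(9.0, 300.0, 1.0, 3, seed=0)
        assert (r.grid == 1).all()

    def test_empty(self):
        r = generate_habitat_raster(9.0, 300.0, 0.0, 3, seed=0)
        assert (r.grid == 0).all()

    def test_exact_count_and_determinism(self):
        r1 = generate_habitat_raster(9.0, 30.0, 0.3, 5, seed=17)
        r2 = generate_habitat_raster(9.0, 30.0, 0.3, 5, seed=17)
        assert r1.shape == (100, 100)
        assert int((r1.grid == 1).sum()) == 3000
        assert np.array_equal(r1.grid, r2.grid)

    def test_cover_within_one_cell(self, rng):
        for cover in rng.uniform(0, 1, 10):
            r = generate_habitat_raster(4.0, 200.0, float(cover), 4, seed=rng)
            n = r.grid.size
            assert abs((r.grid == 1).sum() / n - cover) <= 1.0 / n

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            generate_habitat_raster(9.0, 300.0, 1.5, 3, seed=0)
        with pytest.raises(ConfigurationError):
            generate_habitat_raster(1.0, 2000.0, 0.5, 3, seed=0)

    def test_nuclei_control_patch_count(self):
        # Spearman rho between nuclei and measured patches at fixed cover
        nuclei = []
        counts = []
        rng = np.random.default_rng(5)
        for i in range(60):
            k = int(rng.integers(1, 30))
            r = generate_habitat_raster(9.0, 150.0, 0.25, k, seed=rng)
            n, _, _ = metrics.patches(r)
            nuclei.append(k)
            counts.append(n)
        rho = sps.spearmanr(nuclei, counts).statistic
        assert rho > 0.5


class TestSpeciesPool:
    def test_degenerate_local_endemic(self):
        pool = generate_species_pool(20, (0, 0, 0, 0, 1), seed=0)
        assert all(s.category == "local_endemic" and s.score == 3 for s in pool)

    def test_degenerate_exotic(self):
        pool = generate_species_pool(20, (1, 0, 0, 0, 0), seed=0)
        assert all(s.score == -1 for s in pool)

    def test_reproducible(self):
        mix = (0.2, 0.2, 0.2, 0.2, 0.2)
        p1 = generate_species_pool(5, mix, seed=3)
        p2 = generate_species_pool(5, mix, seed=3)
        assert len(p1) == 5 and p1 == p2

    def test_frequencies_converge(self):
        mix = (0.1, 0.2, 0.3, 0.25, 0.15)
        pool = generate_species_pool(20000, mix, seed=1)
        cats = pd.Series([s.category for s in pool]).value_counts(normalize=True)
        from betascape.endemism import CATEGORIES

        for cat, p in zip(CATEGORIES, mix):
            assert cats.get(cat, 0.0) == pytest.approx(p, abs=0.02)

    def test_bad_mix_raises(self):
        with pytest.raises(DomainError):
            generate_species_pool(10, (0.3, 0.3, 0.3, 0.3, 0.3), seed=0)


def _truth(polygon, cover=0.5, nuclei=5, k=2):
    return LandscapeTruth(
        landscape_id="T",
        center=(polygon.centroid.x, polygon.centroid.y),
        polygon=polygon,
        target_cover=cover,
        n_nuclei=nuclei,
        n_inventories=k,
    )


class TestCommunities:
    def _polygon(self):
        return HexGrid(cell_area=100.0).polygon(0, 0)

    def test_too_few_sites_raises(self):
        cfg = SimulationConfig(pool_size=50)
        pool = generate_species_pool(50, cfg.endemism_mix, seed=0)
        with pytest.raises(DesignError):
            generate_communities(_truth(self._polygon(), k=1), pool, cfg, seed=0)

    def test_no_structure_means_flat_distance_slope(self):
        # distance_decay_rate = 0, homogenization 0: dissimilarity ~ distance
        # regression slope over 200 replicate pairs is ~ 0
        cfg = SimulationConfig(
            pool_size=80, distance_decay_rate=0.0, homogenization_strength=0.0,
            site_noise_sd=0.8, individuals_per_inventory=250, alpha_mean=30,
        )
        pool = generate_species_pool(80, cfg.endemism_mix, seed=1)
        rng = np.random.default_rng(11)
        dist, diss = [], []
        for _ in range(200):
            sites, counts = generate_communities(
                _truth(self._polygon()), pool, cfg, seed=rng
            )
            dist.append(np.linalg.norm(sites[0] - sites[1]))
            diss.append(beta_mod.pairwise_bray(counts[0], counts[1])[0])
        slope = sps.linregress(dist, diss).slope
        # dissimilarity spans ~[0.2, 0.5]; slope in 1/km must be tiny
        assert abs(slope) < 0.01

    def test_coincident_sites_hit_sampling_noise_floor(self):
        # decay-only model, two sites at the same point: dissimilarity should
        # match an independent oracle drawing two multinomials from one profile
        cfg = SimulationConfig(
            pool_size=60, distance_decay_rate=1.0, homogenization_strength=0.0,
            site_noise_sd=1.0, individuals_per_inventory=200, alpha_mean=25,
        )
        pool = generate_species_pool(60, cfg.endemism_mix, seed=2)
        rng = np.random.default_rng(21)

        # force coincident sites by shrinking the polygon to ~a point
        tiny = self._polygon().centroid.buffer(1e-6)
        vals = []
        for _ in range(150):
            _, counts = generate_communities(_truth(tiny), pool, cfg, seed=rng)
            vals.append(beta_mod.pairwise_bray(counts[0], counts[1])[0])
        observed = np.mean(vals)

        # oracle: replicate multinomial draws from a single noisy profile
        oracle_rng = np.random.default_rng(99)
        ratio = synthetic._geometric_ratio(60, 200, 25.0)
        base = ratio ** np.arange(60)
        floor_vals = []
        for _ in range(400):
            w = base * np.exp(oracle_rng.standard_normal(60) * 1.0)
            p = w / w.sum()
            a = oracle_rng.multinomial(200, p)
            b = oracle_rng.multinomial(200, p)
            floor_vals.append(beta_mod.pairwise_bray(a, b)[0])
        floor = np.mean(floor_vals)
        assert observed == pytest.approx(floor, abs=0.03)

    def test_endemism_cover_coupling_raises_cwm(self):
        from betascape.endemism import community_cwm

        cfg = SimulationConfig(
            pool_size=80, endemism_cover_coupling=2.0, alpha_mean=30,
            individuals_per_inventory=250,
        )
        pool = generate_species_pool(80, cfg.endemism_mix, seed=3)
        scores = {s.species_id: s.score for s in pool}
        ids = [s.species_id for s in pool]
        rng = np.random.default_rng(31)
        poly = self._polygon()

        def mean_cwm(cover):
            out = []
            for _ in range(100):
                _, counts = generate_communities(
                    _truth(poly, cover=cover), pool, cfg, seed=rng
                )
                out.append(community_cwm(dict(zip(ids, counts[0])), scores))
            return np.mean(out)

        assert mean_cwm(0.9) > mean_cwm(0.1)


class TestGenerateStudy:
    def test_inventory_count_range(self, small_config):
        study = generate_study(small_config)
        n = small_config.n_landscapes
        lo, hi = small_config.inventories_per_landscape_range
        assert n * lo <= len(study.inventories) <= n * hi
        sizes = study.inventories.groupby("landscape_id").size()
        assert (sizes >= 2).all()

    def test_determinism_byte_equal(self, small_config):
        s1 = generate_study(small_config)
        s2 = generate_study(small_config)
        assert s1.inventories.to_csv() == s2.inventories.to_csv()
        assert s1.abundances.to_csv() == s2.abundances.to_csv()
        assert s1.species.to_csv() == s2.species.to_csv()
        assert s1.climate.to_csv() == s2.climate.to_csv()
        assert s1.truth.to_csv() == s2.truth.to_csv()
        for lid in s1.rasters:
            assert np.array_equal(s1.rasters[lid].grid, s2.rasters[lid].grid)

    def test_full_cover_gradient_realized(self):
        cfg = SimulationConfig(
            n_landscapes=95, cell_size=500.0, habitat_amount_range=(0.0, 1.0),
            inventories_per_landscape_range=(2, 3), pool_size=30,
            individuals_per_inventory=50, alpha_mean=15, seed=4,
        )
        study = generate_study(cfg)
        covers = study.truth["target_cover"]
        assert covers.min() < 0.05
        assert covers.max() > 0.95

    def test_every_landscape_has_raster_and_truth(self, small_config):
        study = generate_study(small_config)
        lids = set(study.inventories["landscape_id"])
        assert lids == set(study.rasters)
        assert lids == set(study.truth["landscape_id"])

    def test_landscapes_match_hexagon_assignment(self, small_config):
        # design-stage tessellation must reproduce the generating memberships
        from betascape.design import HexGrid, assign_landscapes

        study = generate_study(small_config)
        grid = HexGrid(cell_area=small_config.landscape_area)
        units = assign_landscapes(study.inventories, grid)
        reconstructed = {
            frozenset(u.inventory_ids) for u in units
        }
        truth_groups = {
            frozenset(grp["inventory_id"])
            for _, grp in study.inventories.groupby("landscape_id")
        }
        assert reconstructed == truth_groups

    def test_homogenization_lowers_beta_in_fragmented_landscapes(self):
        # top patch-count tercile vs bottom tercile of total beta diversity
        cfg = SimulationConfig(
            n_landscapes=66, cell_size=500.0, habitat_amount_range=(0.3, 0.6),
            fragmentation_nuclei_range=(1, 40),
            inventories_per_landscape_range=(3, 4), pool_size=100,
            homogenization_strength=4.0, site_noise_sd=1.0,
            distance_decay_rate=0.3, alpha_mean=35,
            individuals_per_inventory=250, seed=8,
        )
        study = generate_study(cfg)
        rows = []
        for lid, grp in study.inventories.groupby("landscape_id"):
            M = study.abundances.loc[grp["inventory_id"]].to_numpy()
            total, _, _ = beta_mod.multi_site_partition(M)
            n_nuclei = int(study.truth.set_index("landscape_id").loc[lid, "n_nuclei"])
            rows.append((n_nuclei, total))
        df = pd.DataFrame(rows, columns=["nuclei", "beta"]).sort_values("nuclei")
        k = len(df) // 3
        bottom = df["beta"].iloc[:k].mean()
        top = df["beta"].iloc[-k:].mean()
        assert top < bottom
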