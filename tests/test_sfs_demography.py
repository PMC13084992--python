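import numpy as np
import pytest

from lousepop import simdata
from lousepop.genio import PopulationMap
from lousepop.sfs_demography import (
    LN10,
    SFSArray,
    SFSDemographicModel,
    build_sfs,
    composite_loglik,
    expected_sfs,
    fold_array,
    model_selection,
    thin_one_per_block,
    to_natural_units,
)

from conftest import make_gm


def two_pop_popmap():
    return PopulationMap({"ind0": "p1", "ind1": "p2"})


class TestBuildSfs:
    def test_single_het_site_lands_in_cell_10(self):
        gm = make_gm(np.array([[1], [0]], dtype=np.int8))
        arr = build_sfs(gm, two_pop_popmap())
        assert arr.counts[1, 0] == 1
        assert arr.total_snps == 1

    def test_cell_sum_equals_site_count(self, toy_gm, toy_popmap):
        arr = build_sfs(toy_gm, toy_popmap)
        # monomorphic-reference sites fall into the masked corner
        seg = arr.total_snps
        mono = arr.counts[tuple(0 for _ in arr.counts.shape)]
        assert seg + mono == toy_gm.n_sites

    def test_folding_matches_independent_enumeration(self):
        rng = np.random.default_rng(4)
        genotypes = rng.integers(0, 3, size=(4, 12)).astype(np.int8)
        gm = make_gm(genotypes)
        pm = PopulationMap({"ind0": "a", "ind1": "a", "ind2": "b", "ind3": "b"})
        arr = build_sfs(gm, pm, fold=True)
        # independent oracle: fold each site's count vector by hand
        shape = (5, 5)
        oracle = np.zeros(shape)
        for j in range(12):
            da = int(genotypes[0, j] + genotypes[1, j])
            db = int(genotypes[2, j] + genotypes[3, j])
            comp = (4 - da, 4 - db)
            total, ctotal = da + db, comp[0] + comp[1]
            if total < ctotal or (total == ctotal and (da, db) <= comp):
                oracle[da, db] += 1
            else:
                oracle[comp] += 1
        assert np.array_equal(arr.counts, oracle)

    def test_fold_array_conserves_mass(self):
        rng = np.random.default_rng(9)
        arr = rng.random((5, 7, 3))
        assert fold_array(arr).sum() == pytest.approx(arr.sum())


class TestThinning:
    def test_sparse_input_unchanged(self):
        gm = make_gm(np.array([[0, 1, 2]], dtype=np.int8), positions=[10, 1200, 2500])
        out = thin_one_per_block(gm, block_span=1000, seed=1)
        assert out.n_sites == 3

    def test_one_survivor_per_occupied_block(self):
        positions = [5, 200, 900, 1500, 1700, 2100]
        gm = make_gm(np.zeros((2, 6), dtype=np.int8), positions=positions)
        out = thin_one_per_block(gm, block_span=1000, seed=2)
        assert out.n_sites == 3  # blocks [0,1000), [1000,2000), [2000,3000)
        blocks = (out.sites["pos"] - 1) // 1000
        assert sorted(blocks.tolist()) == [0, 1, 2]

    def test_deterministic(self):
        rng = np.random.default_rng(7)
        gm = make_gm(rng.integers(0, 3, (3, 50)).astype(np.int8),
                     positions=np.sort(rng.choice(5000, 50, replace=False)) + 1)
        a = thin_one_per_block(gm, 1000, seed=3)
        b = thin_one_per_block(gm, 1000, seed=3)
        assert a.sites.equals(b.sites)


class TestExpectedSfs:
    def test_neutral_unfolded_spectrum_follows_one_over_i(self):
        model = simdata.DemographyModel(populations=[("p", 1e4)])
        cfg = simdata.SampleConfig({"p": 2}, num_loci=1, locus_length=1)
        probs = expected_sfs(model, cfg, n_rep=20_000, seed=5, fold=False)
        expected = np.array([0, 1, 1 / 2, 1 / 3, 0])
        expected /= expected.sum()
        assert np.allclose(probs, expected, atol=0.01)
        assert probs.sum() == pytest.approx(1.0)

    def test_symmetric_island_model_gives_symmetric_sfs(self):
        model = simdata.DemographyModel(
            populations=[("a", 5e3), ("b", 5e3)],
            migration_epochs=[(1e12, 0.0, [("a", "b", 5e-4), ("b", "a", 5e-4)])],
        )
        cfg = simdata.SampleConfig({"a": 2, "b": 2}, num_loci=1, locus_length=1)
        probs = expected_sfs(model, cfg, n_rep=8000, seed=6, fold=False)
        assert np.allclose(probs, probs.T, atol=0.01)

    def test_degenerate_model_rejected(self):
        model = simdata.DemographyModel(populations=[("p", 0.0)])
        cfg = simdata.SampleConfig({"p": 2}, num_loci=1, locus_length=1)
        with pytest.raises(ValueError, match="non-positive size"):
            expected_sfs(model, cfg, n_rep=10, seed=1)


class TestCompositeLoglik:
    def test_single_cell_arithmetic(self):
        counts = np.zeros((3, 3))
        counts[1, 0] = 100.0
        obs = SFSArray(counts, ["a", "b"], {"a": 1, "b": 1})
        probs = np.zeros((3, 3))
        probs[1, 0] = 0.1
        assert composite_loglik(obs, probs) == pytest.approx(-100.0)

    def test_three_cell_hand_computation(self):
        counts = np.zeros((3, 3))
        counts[1, 0], counts[0, 1], counts[1, 1] = 5, 3, 2
        obs = SFSArray(counts, ["a", "b"], {"a": 1, "b": 1})
        probs = np.zeros((3, 3))
        probs[1, 0], probs[0, 1], probs[1, 1] = 0.5, 0.3, 0.2
        hand = 5 * np.log10(0.5) + 3 * np.log10(0.3) + 2 * np.log10(0.2)
        assert composite_loglik(obs, probs) == pytest.approx(hand)

    def test_observed_proportions_maximize_likelihood(self):
        rng = np.random.default_rng(11)
        counts = np.zeros((5, 5))
        free = ~SFSArray.default_mask((5, 5), folded=True)
        counts[free] = rng.integers(1, 50, size=int(free.sum()))
        obs = SFSArray(counts, ["a", "b"], {"a": 2, "b": 2})
        best = np.zeros((5, 5))
        best[free] = counts[free] / counts[free].sum()
        ll_best = composite_loglik(obs, best)
        for _ in range(25):
            perturbed = np.zeros((5, 5))
            noise = rng.random(int(free.sum())) + 0.1
            weights = counts[free] * noise
            perturbed[free] = weights / weights.sum()
            assert composite_loglik(obs, perturbed) <= ll_best + 1e-9

    def test_shape_mismatch_rejected(self):
        obs = SFSArray(np.zeros((3, 3)), ["a", "b"], {"a": 1, "b": 1})
        with pytest.raises(ValueError, match="shape"):
            composite_loglik(obs, np.zeros((5, 5)))


class TestModelSelection:
    def test_reported_model_comparison_arithmetic(self):
        # log10-likelihood AIC convention reproduces the published
        # model-ranking table to its printed precision
        fits = [
            {"model": 1, "k": 12, "loglik10": -426_973.34},
            {"model": 2, "k": 12, "loglik10": -426_918.12},
            {"model": 3, "k": 12, "loglik10": -427_035.19},
            {"model": 4, "k": 11, "loglik10": -430_337.06},
            {"model": 5, "k": 13, "loglik10": -428_882.81},
            {"model": 6, "k": 14, "loglik10": -423_272.95},
            {"model": 7, "k": 15, "loglik10": -415_796.25},
            {"model": 8, "k": 16, "loglik10": -415_288.51},
        ]
        table = model_selection(fits).set_index("model")
        published = {1: 53_802.65, 2: 53_548.33, 3: 54_087.45, 4: 69_291.13,
                     5: 62_598.09, 6: 36_765.72, 7: 2_336.25, 8: 0.0}
        for model, daic in published.items():
            assert table.loc[model, "dAIC"] == pytest.approx(daic, abs=0.1)
        assert table.loc[8, "rel_likelihood"] == pytest.approx(1.0)

    def test_equal_models_tie(self):
        fits = [{"model": "x", "k": 3, "loglik10": -10.0},
                {"model": "y", "k": 3, "loglik10": -10.0}]
        table = model_selection(fits)
        assert (table["dAIC"] == 0).all()
        assert (table["rel_likelihood"] == 1.0).all()

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            model_selection([])


class TestFitMechanics:
    @staticmethod
    def two_pop_builder(params):
        return simdata.DemographyModel(
            populations=[("A", params["N"]), ("B", params["N"]), ("anc", params["N"])],
            splits=[(params["T"], ["A", "B"], "anc")],
            mutation_rate=3.5e-8,
        )

    def observed(self, seed=15):
        truth = {"N": 1e4, "T": 5000.0}
        cfg = simdata.SampleConfig({"A": 2, "B": 2}, num_loci=400, locus_length=1000)
        ds = simdata.simulate_dataset(self.two_pop_builder(truth), cfg, seed=seed)
        pm = ds.population_map()
        return build_sfs(ds.gm, pm), cfg

    def test_all_fixed_returns_point_likelihood(self):
        obs, cfg = self.observed()
        model = SFSDemographicModel(
            obs, self.two_pop_builder, {}, {"N": 1e4, "T": 5000.0},
            sample_config=cfg, n_rep=200,
        )
        res = model.fit(seed=3)
        assert res.k == 0
        assert res.loglik10 == pytest.approx(model.loglike(np.empty(0), seed=res.sim_seed))
        assert res.aic == pytest.approx(-2 * LN10 * res.loglik10)

    def test_same_seed_same_result(self):
        obs, cfg = self.observed()
        model = SFSDemographicModel(
            obs, self.two_pop_builder, {"T": (500.0, 5e4)}, {"N": 1e4},
            sample_config=cfg, n_rep=150,
        )
        a = model.fit(n_restarts=2, seed=7, maxiter=20)
        b = model.fit(n_restarts=2, seed=7, maxiter=20)
        assert np.array_equal(a.estimates, b.estimates)
        assert a.loglik10 == b.loglik10

    def test_monte_carlo_error_shrinks_with_replicates(self):
        # doubling n_rep roughly halves the variance of the cell estimates:
        # check the SE of repeated expected-SFS estimates scales ~1/sqrt(2)
        model = self.two_pop_builder({"N": 1e4, "T": 5000.0})
        cfg = simdata.SampleConfig({"A": 2, "B": 2}, num_loci=1, locus_length=1)
        def spread(n_rep, seeds):
            cells = np.stack([
                expected_sfs(model, cfg, n_rep=n_rep, seed=s)
                for s in seeds
            ])
            return cells.std(axis=0).mean()
        s_small = spread(250, range(40, 52))
        s_large = spread(500, range(60, 72))
        assert s_large / s_small == pytest.approx(1 / np.sqrt(2), rel=0.20)

    def test_summary_mentions_parameters(self):
        obs, cfg = self.observed()
        model = SFSDemographicModel(
            obs, self.two_pop_builder, {"T": (500.0, 5e4)}, {"N": 1e4},
            sample_config=cfg, n_rep=100,
        )
        res = model.fit(n_restarts=1, seed=1, maxiter=10)
        text = res.summary()
        assert "T" in text and "AIC" in text and "(fixed)" in text


class TestNaturalUnits:
    def test_generation_to_year_conversion(self):
        out = to_natural_units({"T_ARCTIC": 192_179.0})
        assert out["T_years_ARCTIC"] == 96_090  # two generations per year

    def test_zero_generations(self):
        assert to_natural_units({"T_X": 0.0})["T_years_X"] == 0

    def test_migrants_per_generation(self):
        out = to_natural_units({"M_BALTIC_GRAY": 1e-5, "N_GRAY": 50_000.0})
        assert out["Nm_BALTIC_GRAY"] == pytest.approx(0.5)


class TestBootstrap:
    @staticmethod
    def builder(params):
        return TestFitMechanics.two_pop_builder(params)

    def fit_small(self, gm, pm, cfg, n_rep=150):
        obs = build_sfs(gm, pm)
        model = SFSDemographicModel(
            obs, self.builder, {"T": (500.0, 5e4)}, {"N": 1e4},
            sample_config=cfg, n_rep=n_rep,
        )
        return model.fit(n_restarts=1, seed=3, maxiter=25)

    def test_zero_variance_blocks_give_zero_width_ci(self):
        from lousepop import sfs_demography as sfsd
        from lousepop.genio import PopulationMap
        import pandas as pd

        # four blocks with byte-identical site content: every resample
        # rebuilds the same SFS, so the CI collapses onto one point
        genotypes = np.tile(np.array([[0, 1, 2, 1], [1, 0, 1, 2],
                                      [2, 1, 0, 1], [1, 2, 1, 0]], dtype=np.int8), (1, 4))
        sites = pd.DataFrame({
            "scaffold": np.repeat([f"s{k}" for k in range(4)], 4),
            "pos": list(range(1, 5)) * 4,
            "ref": ["A"] * 16, "alt": ["C"] * 16, "qual": [60.0] * 16,
        })
        from lousepop.genio import GenotypeMatrix
        gm = GenotypeMatrix([f"ind{i}" for i in range(4)], sites, genotypes)
        pm = PopulationMap({"ind0": "A", "ind1": "A", "ind2": "B", "ind3": "B"})
        cfg = simdata.SampleConfig({"A": 2, "B": 2}, num_loci=4, locus_length=10)
        res = self.fit_small(gm, pm, cfg)
        ci = sfsd.bootstrap_ci(gm, pm, res, block_span=1000, n_boot=8, seed=5,
                               grid_points=9)
        assert ci.loc["T", "2.5%"] == ci.loc["T", "97.5%"]
        assert ci.loc["T", "norm_2.5%"] == ci.loc["T", "norm_97.5%"] == pytest.approx(res.estimates[0])

    def test_normal_interval_brackets_estimate(self):
        cfg = simdata.SampleConfig({"A": 3, "B": 3}, num_loci=60, locus_length=1000)
        ds = simdata.simulate_dataset(self.builder({"N": 1e4, "T": 5000.0}), cfg, seed=31)
        pm = ds.population_map()
        res = self.fit_small(ds.gm, pm, cfg)
        from lousepop import sfs_demography as sfsd
        ci = sfsd.bootstrap_ci(ds.gm, pm, res, block_span=1000, n_boot=10, seed=6,
                               grid_points=11)
        assert ci.loc["T", "norm_2.5%"] <= res.estimates[0] <= ci.loc["T", "norm_97.5%"]
        assert ci.loc["T", "2.5%"] <= ci.loc["T", "97.5%"]
        assert res.conf_int_ is not None and len(res.boot_replicates) == 10

    def test_too_few_blocks_rejected(self):
        cfg = simdata.SampleConfig({"A": 2, "B": 2}, num_loci=1, locus_length=1000)
        ds = simdata.simulate_dataset(self.builder({"N": 1e4, "T": 5000.0}), cfg, seed=33)
        pm = ds.population_map()
        res = self.fit_small(ds.gm, pm, cfg)
        from lousepop import sfs_demography as sfsd
        with pytest.raises(ValueError, match="two blocks"):
            sfsd.bootstrap_ci(ds.gm, pm, res, block_span=10**9, n_boot=4, seed=2)
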