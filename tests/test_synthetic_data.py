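import numpy as np
import pandas as pd
import pytest

from twigscale import multivariate
from twigscale.allometry import sma_fit
from twigscale.pipeline import derive_species_table
from twigscale.synthetic_data import (
    CORE_TRAITS,
    SimulationConfig,
    default_config,
    expand_to_measurements,
    generate_dataset,
    simulate_sma_dataset,
    simulate_species_traits,
    simulate_tree,
)
from twigscale.phylo import parse_newick
from twigscale.twig_architecture import TWIG_TRAIT_CODES, derive_twig_traits


def count_cherries(tree):
    return sum(
        1
        for n in tree.postorder()
        if n.children and all(c.is_leaf for c in n.children)
    )


class TestSimulateTree:
    def test_three_tips_forced_topology(self):
        tree = simulate_tree(3, seed=0)
        assert tree.n_tips == 3
        assert len([n for n in tree.postorder() if not n.is_leaf]) == 2
        depths = tree.tip_depths()
        assert np.allclose(list(depths.values()), 1.0)

    def test_determinism(self):
        assert simulate_tree(15, seed=42).to_newick() == simulate_tree(
            15, seed=42
        ).to_newick()
        assert simulate_tree(15, seed=42).to_newick() != simulate_tree(
            15, seed=43
        ).to_newick()

    def test_labels_and_positive_lengths(self):
        tree = simulate_tree(28, seed=1)
        assert sorted(tree.tip_labels) == [f"sp{i:02d}" for i in range(1, 29)]
        assert all(
            n.length > 0 for n in tree.postorder() if n is not tree.root
        )

    def test_too_few_species_rejected(self):
        with pytest.raises(ValueError):
            simulate_tree(2, seed=0)

    def test_yule_cherry_expectation(self):
        # Yule expectation for cherries is n/3; se over 200 trees ~ 0.08
        counts = [count_cherries(simulate_tree(28, seed=s)) for s in range(200)]
        assert abs(np.mean(counts) - 28.0 / 3.0) < 0.3


class TestSimulateSpeciesTraits:
    def test_zero_rate_returns_root_state(self):
        cfg = SimulationConfig(
            seed=0, traits=["u"], root_state={"u": 1.5}, bm_rates={"u": 0.0}
        )
        tab = simulate_species_traits(simulate_tree(6, seed=1), cfg)
        assert np.allclose(np.log10(tab["u"]), 1.5)

    def test_two_tip_bm_variance(self):
        # closed form: tip difference variance = 2 * t * sigma^2 = 2
        tree = parse_newick("(A:1,B:1);")
        diffs = []
        for seed in range(2000):
            cfg = SimulationConfig(
                seed=seed, traits=["u"], root_state={"u": 0.0},
                bm_rates={"u": 1.0},
            )
            tab = np.log10(simulate_species_traits(tree, cfg))
            diffs.append(tab["u"].loc["A"] - tab["u"].loc["B"])
        assert np.var(diffs) == pytest.approx(2.0, rel=0.1)

    def test_noise_free_exponent_exact(self):
        cfg = default_config(seed=2)
        cfg.allometric_exponents = {("TLA", "SA"): 1.0}
        cfg.allometric_r2 = {("TLA", "SA"): 1.0}
        cfg.tradeoff_correlations = {}
        tab = simulate_species_traits(simulate_tree(28, seed=2), cfg)
        fit = sma_fit(np.log10(tab["SA"]), np.log10(tab["TLA"]))
        assert fit.slope == pytest.approx(1.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_non_psd_matrix_rejected(self):
        with pytest.raises(ValueError, match="semi-definite"):
            SimulationConfig(
                traits=["u", "w"],
                root_state={"u": 0.0, "w": 0.0},
                bm_rate_matrix=np.array([[1.0, 2.0], [2.0, 1.0]]),
            )

    def test_exponent_recovered_within_ci(self):
        # requested SMA exponent inside the 95% CI in >= 90% of simulations
        hits = 0
        reps = 500
        for seed in range(reps):
            cfg = default_config(seed=seed)
            cfg.allometric_exponents = {("ILA", "SA"): 0.75}
            cfg.allometric_r2 = {("ILA", "SA"): 0.8}
            cfg.tradeoff_correlations = {}
            tab = simulate_species_traits(simulate_tree(28, seed=seed), cfg)
            fit = sma_fit(np.log10(tab["SA"]), np.log10(tab["ILA"]))
            hits += fit.ci_low <= 0.75 <= fit.ci_high
        assert hits / reps >= 0.90

    def test_derived_traits_consistent(self):
        cfg = default_config(seed=4)
        tab = simulate_species_traits(simulate_tree(10, seed=4), cfg)
        nbar = cfg.mean_leaf_count
        assert np.allclose(tab["TLA"], nbar * tab["ILA"], rtol=1e-9)
        assert np.allclose(tab["LeM"], nbar * tab["ILM"], rtol=1e-9)
        assert np.allclose(tab["SM"], nbar / tab["LI"], rtol=1e-9)
        assert np.allclose(tab["SLA"], 0.1 * tab["ILA"] / tab["ILM"], rtol=1e-9)


class TestExpandToMeasurements:
    def test_zero_noise_round_trip(self, noisefree_dataset):
        ds = noisefree_dataset
        table = derive_species_table(
            ds.twig_table, ds.vessel_table, ds.gravimetric_table, ds.bending_table
        )
        truth = ds.species_means[table.columns]
        assert np.allclose(table.values, truth.values, rtol=1e-9)

    def test_vessel_contract(self, small_dataset):
        counts = small_dataset.vessel_table.groupby("stem_id").size()
        assert (counts >= 30).all()
        assert (small_dataset.vessel_table["b_um"] > 0).all()
        assert (
            small_dataset.vessel_table["a_um"]
            >= small_dataset.vessel_table["b_um"]
        ).all()

    def test_twig_counts_in_range(self, small_dataset):
        per_ind = small_dataset.twig_table.groupby(
            ["species", "individual"]
        ).size()
        assert per_ind.between(3, 5).all()

    def test_missing_trait_rejected(self, small_dataset):
        cfg = default_config(seed=0, n_species=10)
        with pytest.raises(ValueError, match="missing required"):
            expand_to_measurements(
                small_dataset.species_means.drop(columns=["Dh"]), cfg
            )

    def test_species_match_tree_tips(self, small_dataset):
        tips = set(small_dataset.tree.tip_labels)
        for tbl in (
            small_dataset.twig_table,
            small_dataset.vessel_table,
            small_dataset.gravimetric_table,
            small_dataset.bending_table,
        ):
            assert set(tbl["species"]) <= tips

    def test_all_values_finite(self, small_dataset):
        for tbl in (
            small_dataset.species_means,
            small_dataset.twig_table.drop(
                columns=["species", "individual", "twig"]
            ),
        ):
            assert np.isfinite(tbl.values.astype(float)).all()

    def test_variance_mostly_among_species(self):
        ds = generate_dataset(default_config(seed=0))
        derived = derive_twig_traits(ds.twig_table)
        for trait in TWIG_TRAIT_CODES:
            vc = multivariate.nested_varcomp(derived, trait, log10=True)
            assert vc.pct_species > 70.0, trait


class TestDeterminism:
    def test_bit_identical_datasets(self):
        cfg1 = default_config(seed=123)
        cfg2 = default_config(seed=123)
        d1, d2 = generate_dataset(cfg1), generate_dataset(cfg2)
        assert d1.tree.to_newick() == d2.tree.to_newick()
        pd.testing.assert_frame_equal(d1.species_means, d2.species_means)
        pd.testing.assert_frame_equal(d1.twig_table, d2.twig_table)
        pd.testing.assert_frame_equal(d1.vessel_table, d2.vessel_table)
        pd.testing.assert_frame_equal(d1.gravimetric_table, d2.gravimetric_table)
        pd.testing.assert_frame_equal(d1.bending_table, d2.bending_table)

    def test_write_creates_text_files(self, tmp_path, small_dataset):
        small_dataset.write(tmp_path)
        for name in (
            "tree.nwk",
            "species_means_true.csv",
            "twig_table.csv",
            "vessel_table.csv",
            "gravimetric_table.csv",
            "bending_table.csv",
            "truth.json",
        ):
            assert (tmp_path / name).exists()

    def test_config_dict_round_trip(self):
        cfg = default_config(seed=9)
        clone = SimulationConfig.from_dict(cfg.to_dict())
        assert clone.allometric_exponents == cfg.allometric_exponents
        assert clone.tradeoff_correlations == cfg.tradeoff_correlations
        assert clone.seed == cfg.seed


class TestSmaDatasetGenerator:
    def test_population_moments(self, rng):
        x, y = simulate_sma_dataset(20000, -0.9, 0.7, rng, sd_x=0.4)
        assert np.std(y) / np.std(x) == pytest.approx(0.9, rel=0.02)
        assert np.corrcoef(x, y)[0, 1] == pytest.approx(-np.sqrt(0.7), abs=0.01)

    def test_r2_one_exact_line(self, rng):
        x, y = simulate_sma_dataset(50, 2.0, 1.0, rng)
        assert sma_fit(x, y).slope == pytest.approx(2.0, abs=1e-12)

    def test_invalid_args(self, rng):
        with pytest.raises(ValueError):
            simulate_sma_dataset(10, 0.0, 0.5, rng)
        with pytest.raises(ValueError):
            simulate_sma_dataset(10, 1.0, 0.0, rng)


class TestConfigValidation:
    def test_bad_counts(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_species=2)
        with pytest.raises(ValueError):
            SimulationConfig(n_twigs_min=5, n_twigs_max=3)
        with pytest.raises(ValueError):
            SimulationConfig(noise_sd_twig=-0.1)

    def test_missing_root_state(self):
        with pytest.raises(ValueError, match="root_state"):
            SimulationConfig(traits=["nonexistent"])
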