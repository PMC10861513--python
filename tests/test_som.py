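"""Toroidal SOM: scaling, grid sizing, training contracts, assignment."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_profile
from vernalign.som import (
    ClusterAssignment,
    assign_genes,
    grid_distance_sq,
    label_codebooks,
    quantization_error,
    scale_profiles,
    som_grid_shape,
    top_populated_clusters,
    train_som,
)


class TestScaleProfiles:
    def test_population_sd_closed_form(self):
        prof = make_profile({"g": [1, 2, 3], "h": [5, 5, 4]}, [1, 2, 3])
        scaled = scale_profiles(prof, ["g"])
        np.testing.assert_allclose(
            scaled.loc["g"], [-1.22474487, 0.0, 1.22474487], atol=1e-8
        )

    def test_constant_rows_dropped_and_counted(self):
        prof = make_profile({"g": [1, 2, 3], "c": [4, 4, 4]}, [1, 2, 3])
        scaled = scale_profiles(prof, ["g", "c"])
        assert list(scaled.index) == ["g"]
        assert scaled.attrs["n_dropped"] == 1

    def test_idempotent_on_scaled_rows(self):
        prof = make_profile({"g": [1, 2, 3, 10]}, [1, 2, 3, 4])
        once = scale_profiles(prof, ["g"])
        prof2 = make_profile({"g": once.loc["g"].tolist()}, [1, 2, 3, 4])
        twice = scale_profiles(prof2, ["g"])
        np.testing.assert_allclose(once.loc["g"], twice.loc["g"], atol=1e-12)

    def test_empty_gene_list_raises(self):
        prof = make_profile({"g": [1, 2]}, [1, 2])
        with pytest.raises(ValueError):
            scale_profiles(prof, [])


def data_with_eigenratio(ratio, n=400, seed=0):
    """Data whose sample covariance has exact leading eigenvalue ratio."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, 2))
    x -= x.mean(axis=0)
    u, _, vt = np.linalg.svd(x, full_matrices=False)
    sv = np.sqrt((n - 1) * np.array([ratio, 1.0]))
    return u * sv @ vt


class TestGridShape:
    def test_isotropic_square(self):
        assert som_grid_shape(data_with_eigenratio(1.0), target_units=100) == (10, 10)

    def test_ratio_two_rectangle(self):
        assert som_grid_shape(data_with_eigenratio(2.0), target_units=50) == (10, 5)

    def test_single_feature_rejected(self):
        with pytest.raises(ValueError):
            som_grid_shape(np.ones((10, 1)), target_units=9)

    def test_degenerate_second_eigenvalue_rejected(self):
        x = np.outer(np.linspace(-1, 1, 20), [1.0, 2.0])  # rank 1
        with pytest.raises(ValueError, match="explicit shape"):
            som_grid_shape(x, target_units=9)

    def test_elbow_scan_returns_valid_deterministic_shape(self):
        data = data_with_eigenratio(1.5, n=150, seed=3)
        s1 = som_grid_shape(data, seed=4)
        s2 = som_grid_shape(data, seed=4)
        assert s1 == s2
        assert s1[0] >= s1[1] >= 2


class TestTorusGeometry:
    def test_wraparound_distance(self):
        gd2 = grid_distance_sq(5, 10, toroidal=True)
        # units (0,0) and (0,9) on a 10-wide torus are adjacent
        assert gd2[0, 9] == 1.0

    def test_max_distance_bound(self):
        rows, cols = 7, 5
        gd2 = grid_distance_sq(rows, cols, toroidal=True)
        assert gd2.max() <= (rows / 2) ** 2 + (cols / 2) ** 2

    def test_bounded_grid_has_no_wraparound(self):
        gd2 = grid_distance_sq(5, 10, toroidal=False)
        assert gd2[0, 9] == 81.0
        # at radius 1 the opposite-edge neighbourhood weight is negligible
        assert np.exp(-gd2[0, 9] / 2.0) < 1e-6


class TestTrainSom:
    def test_four_distinct_points_claim_four_units(self):
        pts = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0], [10.0, 10.0]])
        model = train_som(pts, (2, 2), seed=0, epochs=300, radius=(1.0, 0.05))
        assert model.training_meta["qe_final"] < 1e-3
        units = np.argmin(
            ((pts[:, None, :] - model.codebooks[None, :, :]) ** 2).sum(-1), axis=1
        )
        assert len(set(units)) == 4

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        data = rng.normal(size=(50, 4))
        m1 = train_som(data, (3, 3), seed=7, epochs=5)
        m2 = train_som(data, (3, 3), seed=7, epochs=5)
        np.testing.assert_array_equal(m1.codebooks, m2.codebooks)

    @pytest.mark.parametrize("seed", range(5))
    def test_quantization_error_never_increases(self, seed, tiny_dataset):
        from vernalign.expression import collapse_replicates, som_prefilter

        prof = collapse_replicates(
            tiny_dataset.expression[("Tapidor", "apex")], "Tapidor", "apex"
        )
        survivors, _ = som_prefilter(prof, set(tiny_dataset.homology["crop_gene"]))
        scaled = scale_profiles(prof, survivors)
        model = train_som(scaled, (4, 4), seed=seed)
        assert model.training_meta["qe_final"] <= model.training_meta["qe_initial"]

    def test_fewer_genes_than_units_warns_but_trains(self):
        data = np.random.default_rng(0).normal(size=(5, 3))
        with pytest.warns(UserWarning, match="fewer profiles"):
            model = train_som(data, (3, 3), seed=0, epochs=2)
        assert model.codebooks.shape == (9, 3)


class TestAssignGenes:
    def _model_and_data(self, n=100, seed=4):
        rng = np.random.default_rng(seed)
        data = pd.DataFrame(rng.normal(size=(n, 4)),
                            index=[f"g{i}" for i in range(n)])
        model = train_som(data, (3, 4), seed=seed, epochs=5)
        return model, data

    def test_gene_equal_to_codebook_assigned_there(self):
        model, data = self._model_and_data()
        probe = pd.DataFrame([model.codebooks[7]], index=["probe"])
        assert assign_genes(model, probe).gene_unit["probe"] == 7

    def test_matches_brute_force_nearest_codebook(self):
        model, data = self._model_and_data()
        assign = assign_genes(model, data)
        for g in data.index:
            d = np.sqrt(((model.codebooks - data.loc[g].to_numpy()) ** 2).sum(axis=1))
            assert assign.gene_unit[g] == int(np.argmin(d))

    def test_empty_matrix_gives_empty_assignment(self):
        model, data = self._model_and_data()
        assign = assign_genes(model, data.iloc[:0])
        assert len(assign.gene_unit) == 0

    def test_dimension_mismatch_raises(self):
        model, data = self._model_and_data()
        with pytest.raises(ValueError, match="feature mismatch"):
            assign_genes(model, data.iloc[:, :3])

    def test_proportions_sum_to_one(self):
        model, data = self._model_and_data()
        assign = assign_genes(model, data)
        assert assign.proportions.sum() == pytest.approx(1.0, abs=1e-9)


class TestTopPopulated:
    def _assignment(self, units):
        return ClusterAssignment(
            gene_unit=pd.Series(units, index=[f"g{i}" for i in range(len(units))]),
            n_units=4,
        )

    def test_descending_with_proportions(self):
        a = self._assignment([0] * 5 + [1] * 3 + [2] * 2)
        assert top_populated_clusters(a, 1) == [(0, 5, 0.5)]

    def test_uniform_counts_tie_to_low_indices(self):
        a = self._assignment([0, 1, 2, 3])
        assert [u for u, _, _ in top_populated_clusters(a, 3)] == [0, 1, 2]

    def test_k_larger_than_units_returns_all(self):
        a = self._assignment([0, 1])
        assert len(top_populated_clusters(a, 99)) == 4

    def test_k_zero_rejected(self):
        with pytest.raises(ValueError):
            top_populated_clusters(self._assignment([0]), 0)


def test_codebook_labels_match_planted_archetypes():
    """Units of a map trained on pure archetype data are labelled with the
    archetype that generated their member genes."""
    from vernalign.expression import collapse_replicates
    from vernalign.simulate import SimulationConfig, generate_dataset

    cfg = SimulationConfig(
        n_families=120, archetype_mix=(0.25, 0.25, 0.25, 0.25, 0.0),
        frac_variety_specific=0.0, frac_tissue_preferential=0.0,
        frac_no_homologue=0.0, noise_sigma=0.1, seed=2,
    )
    ds = generate_dataset(cfg)
    prof = collapse_replicates(ds.expression[("Tapidor", "apex")], "Tapidor", "apex")
    scaled = scale_profiles(prof, list(prof.gene_ids))
    model = train_som(scaled, (6, 6), seed=1)
    assign = assign_genes(model, scaled)
    labels = label_codebooks(model, cfg.cold_window)
    truth = ds.truth
    agree = sum(
        labels[unit] == truth.loc[g, "archetype"] for g, unit in assign.gene_unit.items()
    )
    assert agree / len(assign.gene_unit) >= 0.9
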