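"""PCA, ASCA effect partitioning, and permutation validation."""

import numpy as np
import pandas as pd
import pytest

from protasca.decompose import (
    PermutationSpec,
    decompose_asca,
    permutation_test,
    run_pca,
    summarize_effects,
)
from protasca.io import AbundanceMatrix, ProtascaError, SampleDesign

from conftest import make_biological_design


def as_matrix(X, design, scale="log2"):
    """X is samples x proteins; stored as proteins x samples."""
    return AbundanceMatrix(
        values=pd.DataFrame(np.asarray(X, dtype=float).T,
                            index=[f"p{i}" for i in range(X.shape[1])],
                            columns=design.sample_ids),
        scale_tag=scale)


def brute_force_effects(X, time_lab, temp_lab):
    """Independent group-mean construction of the ASCA effect matrices."""
    Xc = X - X.mean(axis=0)
    n = X.shape[0]
    t_eff = np.zeros_like(Xc)
    g_eff = np.zeros_like(Xc)
    i_eff = np.zeros_like(Xc)
    for i in range(n):
        t_eff[i] = Xc[np.asarray(time_lab) == time_lab[i]].mean(axis=0)
        g_eff[i] = Xc[np.asarray(temp_lab) == temp_lab[i]].mean(axis=0)
        cell = (np.asarray(time_lab) == time_lab[i]) & \
               (np.asarray(temp_lab) == temp_lab[i])
        i_eff[i] = Xc[cell].mean(axis=0) - t_eff[i] - g_eff[i]
    return Xc, t_eff, g_eff, i_eff


class TestPca:
    def test_identical_samples_zero_variance_fractions(self, bio_design):
        X = np.ones((12, 5))
        pca = run_pca(as_matrix(X, bio_design))
        np.testing.assert_array_equal(pca.explained_variance_fraction, 0.0)

    def test_rank_one_matrix_pc1_explains_all(self, bio_design):
        design = bio_design
        X = np.zeros((12, 2))
        X[6:] = 2.0
        pca = run_pca(as_matrix(X, design))
        assert pca.explained_variance_fraction[0] == pytest.approx(1.0)

    def test_reconstruction_and_covariance_eigenvalue_oracle(self, rng,
                                                             bio_design):
        X = rng.standard_normal((12, 500))
        pca = run_pca(as_matrix(X, bio_design))
        Xc = X - X.mean(axis=0)
        recon = pca.scores.to_numpy() @ pca.loadings.to_numpy().T
        np.testing.assert_allclose(recon, Xc, atol=1e-8)
        # eigenvalues of the covariance matrix, computed independently
        eigvals = np.linalg.eigvalsh(Xc @ Xc.T)[::-1]
        sv2 = (pca.scores.to_numpy() ** 2).sum(axis=0)
        np.testing.assert_allclose(sv2[:11], eigvals[:11], rtol=1e-8,
                                   atol=1e-8)
        # loadings columns orthonormal
        L = pca.loadings.to_numpy()
        np.testing.assert_allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-8)

    def test_explained_fractions_non_increasing(self, rng, bio_design):
        pca = run_pca(as_matrix(rng.standard_normal((12, 40)), bio_design))
        frac = pca.explained_variance_fraction
        assert (np.diff(frac) <= 1e-12).all()

    def test_sign_convention_largest_loading_positive(self, rng, bio_design):
        pca = run_pca(as_matrix(rng.standard_normal((12, 30)), bio_design))
        L = pca.loadings.to_numpy()
        for j in range(L.shape[1]):
            assert L[np.abs(L[:, j]).argmax(), j] >= 0

    def test_too_few_samples(self):
        design = SampleDesign(pd.DataFrame(
            [{"sample_id": "a", "time_dpf": 21, "temperature_c": 23.0,
              "replicate_id": "A"}]))
        with pytest.raises(ProtascaError):
            run_pca(as_matrix(np.ones((1, 3)), design))


class TestAsca:
    def test_pure_time_signal_all_variation_in_time(self, bio_design):
        tvals = {21: 0.0, 23: 1.0, 25: 2.0, 27: 3.0, 29: 4.0, 31: 5.0}
        X = np.array([[tvals[t]] * 4
                      for t in bio_design.table["time_dpf"]])
        asca = decompose_asca(as_matrix(X, bio_design), bio_design)
        assert asca.percent_variation["time"] == pytest.approx(100.0)
        assert asca.percent_variation["temperature"] == pytest.approx(0.0,
                                                                      abs=1e-9)
        assert asca.percent_variation["interaction"] == pytest.approx(
            0.0, abs=1e-9)

    def test_saturated_design_percentages_sum_to_100(self, rng, bio_design):
        X = rng.standard_normal((12, 20))
        asca = decompose_asca(as_matrix(X, bio_design), bio_design)
        assert asca.saturated
        total = sum(asca.percent_variation.values())
        assert total == pytest.approx(100.0, abs=1e-8)
        assert asca.residual_percent == pytest.approx(0.0, abs=1e-8)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_effects_match_group_mean_oracle(self, seed):
        """2x2 design with 3 replicates per cell against brute force."""
        rng = np.random.default_rng(seed)
        rows = []
        for t in (21, 27):
            for g in (23.0, 29.0):
                for r in range(3):
                    rows.append({"sample_id": f"T{t}_{int(g)}_{r}",
                                 "time_dpf": t, "temperature_c": g,
                                 "replicate_id": str(r)})
        design = SampleDesign(pd.DataFrame(rows))
        X = rng.standard_normal((12, 15))
        asca = decompose_asca(as_matrix(X, design), design)
        Xc, t_eff, g_eff, i_eff = brute_force_effects(
            X, list(design.table["time_dpf"]),
            list(design.table["temperature_c"]))
        np.testing.assert_allclose(asca.effects["time"].to_numpy(), t_eff,
                                   atol=1e-10)
        np.testing.assert_allclose(asca.effects["temperature"].to_numpy(),
                                   g_eff, atol=1e-10)
        np.testing.assert_allclose(asca.effects["interaction"].to_numpy(),
                                   i_eff, atol=1e-10)
        # balanced design: mutual orthogonality + Pythagorean identity
        mats = [t_eff, g_eff, i_eff,
                Xc - t_eff - g_eff - i_eff]
        for a in range(4):
            for b in range(a + 1, 4):
                assert abs((mats[a] * mats[b]).sum()) < 1e-8
        assert (Xc ** 2).sum() == pytest.approx(
            sum((m ** 2).sum() for m in mats), rel=1e-8)

    def test_additive_decomposition_exact(self, rng, bio_design):
        X = rng.standard_normal((12, 25))
        asca = decompose_asca(as_matrix(X, bio_design), bio_design)
        recon = sum(E.to_numpy() for E in asca.effects.values()) \
            + asca.residual.to_numpy()
        np.testing.assert_allclose(recon, asca.centered.to_numpy(),
                                   atol=1e-12)

    def test_single_level_factor_rejected(self):
        rows = [{"sample_id": f"s{i}", "time_dpf": 21, "temperature_c": g,
                 "replicate_id": str(i)}
                for i, g in enumerate((23.0, 23.0, 29.0, 29.0))]
        design = SampleDesign(pd.DataFrame(rows))
        with pytest.raises(ProtascaError, match="time"):
            decompose_asca(as_matrix(np.random.default_rng(0)
                                     .standard_normal((4, 5)), design), design)

    def test_unbalanced_design_warns(self, rng):
        rows = []
        for t in (21, 23, 25, 27, 29, 31):
            for g in (23.0, 29.0):
                rows.append({"sample_id": f"T{t}_{int(g)}", "time_dpf": t,
                             "temperature_c": g, "replicate_id": "avg"})
        rows.append({"sample_id": "T19_16", "time_dpf": 19,
                     "temperature_c": 16.0, "replicate_id": "avg"})
        design = SampleDesign(pd.DataFrame(rows))
        with pytest.warns(UserWarning, match="unbalanced"):
            decompose_asca(as_matrix(rng.standard_normal((13, 6)), design),
                           design)


class TestPermutation:
    def test_constant_rows_p_equals_one(self, bio_design):
        X = np.ones((12, 8))
        X += np.arange(8)  # column offsets vanish after centering
        p = permutation_test(as_matrix(X, bio_design), bio_design, "time",
                             PermutationSpec(n_permutations=50, seed=0))
        assert p == 1.0

    def test_planted_strong_effect_minimum_p(self, rng, bio_design):
        level = {t: i * 50.0 for i, t in enumerate((21, 23, 25, 27, 29, 31))}
        X = np.array([[level[t]] * 10
                      for t in bio_design.table["time_dpf"]])
        X += rng.standard_normal(X.shape) * 0.01
        p = permutation_test(as_matrix(X, bio_design), bio_design, "time",
                             PermutationSpec(n_permutations=200, seed=1))
        assert p == pytest.approx(1 / 201)

    def test_deterministic_given_seed(self, rng, bio_design):
        m = as_matrix(rng.standard_normal((12, 30)), bio_design)
        spec = PermutationSpec(n_permutations=100, seed=42)
        assert permutation_test(m, bio_design, "time", spec) == \
            permutation_test(m, bio_design, "time", spec)

    def test_invariant_to_common_affine_rescaling(self, rng, bio_design):
        """A common positive rescaling and per-protein offsets leave every
        permutation p-value unchanged: offsets vanish with column centering
        and a common scale multiplies all sums of squares equally. (A
        protein-specific rescaling genuinely reweights the omnibus sum of
        squares and changes the test, so no such invariance is asserted.)"""
        X = rng.standard_normal((12, 20))
        a = 3.7
        b = rng.standard_normal(20) * 10
        spec = PermutationSpec(n_permutations=150, seed=7)
        for factor in ("time", "temperature", "interaction"):
            p1 = permutation_test(as_matrix(X, bio_design), bio_design,
                                  factor, spec)
            p2 = permutation_test(as_matrix(X * a + b, bio_design),
                                  bio_design, factor, spec)
            assert p1 == p2

    def test_raw_rule_and_validation(self, rng, bio_design):
        m = as_matrix(rng.standard_normal((12, 10)), bio_design)
        p_raw = permutation_test(m, bio_design, "time",
                                 PermutationSpec(n_permutations=100, seed=3,
                                                 p_value_rule="raw"))
        assert 0.0 <= p_raw <= 1.0
        with pytest.raises(ProtascaError):
            PermutationSpec(n_permutations=0)


def test_summarize_effects_formatting(rng, bio_design):
    X = rng.standard_normal((12, 10))
    asca = decompose_asca(as_matrix(X, bio_design), bio_design)
    asca.permutation_p = {f: 0.12345 for f in asca.effects}
    table = summarize_effects(asca)
    assert list(table.columns) == ["factor", "percent_variation", "p_value"]
    assert (table["p_value"] == 0.1234).all() or (table["p_value"] == 0.1235).all()
    for _, row in table.iterrows():
        assert row["percent_variation"] == pytest.approx(
            asca.percent_variation[row["factor"]], abs=0.005)
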