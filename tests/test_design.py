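import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tirtsim.design import (
    DesignError,
    TraitCorrelationMatrix,
    apply_keying,
    build_blocks,
    make_correlation,
    make_design,
    neo_like_matrix,
    sample_item_means,
    sample_loadings,
)


class TestSampleLoadings:
    def test_high_uniform_range_and_mean(self, rng):
        vals = sample_loadings(100_000, "high_uniform", rng)
        assert vals.min() >= 0.65 and vals.max() <= 0.95
        # uniform(.65,.95): mean .80, sd .30/sqrt(12); 4 MC sigmas
        assert abs(vals.mean() - 0.80) < 4 * (0.30 / np.sqrt(12)) / np.sqrt(vals.size)

    def test_truncnorm_range_and_mean(self, rng):
        vals = sample_loadings(100_000, "realistic_truncnorm", rng)
        assert vals.min() >= 0.1 and vals.max() <= 0.9
        # truncation interval is symmetric about the mode 0.5
        assert abs(vals.mean() - 0.5) < 0.003

    def test_unknown_dist(self, rng):
        with pytest.raises(DesignError):
            sample_loadings(6, "lognormal", rng)

    def test_too_few_items(self, rng):
        with pytest.raises(DesignError):
            sample_loadings(2, "high_uniform", rng)


class TestApplyKeying:
    def test_equal_is_identity(self, rng):
        mags = np.array([0.7, 0.8, 0.9, 0.6])
        np.testing.assert_array_equal(apply_keying(mags, "equal", rng), mags)

    @pytest.mark.parametrize("n", [4, 5, 9, 45])
    def test_mixed_negates_floor_half(self, rng, n):
        mags = rng.uniform(0.3, 0.9, size=n)
        signed = apply_keying(mags, "mixed", rng)
        assert int((signed < 0).sum()) == n // 2
        np.testing.assert_allclose(np.abs(signed), mags)

    def test_rejects_nonpositive(self, rng):
        with pytest.raises(DesignError):
            apply_keying(np.array([0.5, -0.2]), "mixed", rng)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(n=st.integers(min_value=3, max_value=120), seed=st.integers(0, 2**31 - 1))
    def test_mixed_keying_floor_rule_property(self, n, seed):
        rng = np.random.default_rng(seed)
        mags = rng.uniform(0.1, 0.95, size=n)
        signed = apply_keying(mags, "mixed", rng)
        assert int((signed < 0).sum()) == n // 2
        np.testing.assert_allclose(np.abs(signed), mags)


class TestBuildBlocks:
    @pytest.mark.parametrize(
        "n_traits,expected_blocks", [(30, 90), (5, 15), (3, 9)]
    )
    def test_block_counts_and_trait_quota(self, rng, n_traits, expected_blocks):
        blocks = build_blocks(n_traits, 9, rng)
        assert blocks.shape == (expected_blocks, 3)
        counts = np.bincount(blocks.ravel(), minlength=n_traits)
        assert (counts == 9).all()
        for row in blocks:
            assert len(set(row)) == 3

    def test_three_traits_forced_composition(self, rng):
        blocks = build_blocks(3, 9, rng)
        for row in blocks:
            assert set(row) == {0, 1, 2}

    def test_divisibility_error(self, rng):
        with pytest.raises(DesignError):
            build_blocks(5, 7, rng)


class TestItemMeans:
    def test_gamma_sign_convention(self):
        # gamma_ik = -(mu_i - mu_k)
        mu = np.array([0.2, -0.3])
        gamma_12 = -(mu[0] - mu[1])
        assert gamma_12 == pytest.approx(-0.5)

    def test_gamma_additive_and_bounded(self, small_design):
        g = small_design.gammas()
        assert np.all(np.abs(g) < 1.0)
        np.testing.assert_allclose(g[:, 1], g[:, 0] + g[:, 2], atol=1e-12)

    def test_means_range(self, rng):
        mu = sample_item_means(10_000, rng)
        assert mu.min() > -0.5 and mu.max() < 0.5


class TestMakeCorrelation:
    def test_zero_is_identity(self):
        phi = make_correlation("zero", 5)
        np.testing.assert_array_equal(phi.phi, np.eye(5))

    def test_matrix_file_full_dimension(self, rng, tmp_path):
        full = neo_like_matrix(rng)
        path = tmp_path / "phi.csv"
        np.savetxt(path, full, delimiter=",")
        phi = make_correlation("matrix_file", 30, replication=1, source_file=str(path))
        np.testing.assert_allclose(phi.phi, full, atol=1e-12)

    def test_neo_like_pd_and_heterogeneous(self, rng):
        phi = make_correlation("neo_like", 10, replication=3, rng=rng)
        assert np.linalg.eigvalsh(phi.phi).min() > 0
        off = phi.phi[np.triu_indices(10, k=1)]
        assert off.std() > 0.01  # off-diagonals are not all equal

    def test_submatrix_balances_domains(self, rng, tmp_path):
        full = neo_like_matrix(rng)
        path = tmp_path / "phi.csv"
        np.savetxt(path, full, delimiter=",")
        from tirtsim.design import _balanced_facets

        for n_traits in (5, 10, 20, 25):
            for rep in range(1, 7):
                idx = _balanced_facets(n_traits, rep, 30)
                counts = np.bincount(idx // 6, minlength=5)
                assert counts.max() - counts.min() <= 1
        # the six replicate selections differ
        sets = {tuple(_balanced_facets(10, r, 30)) for r in range(1, 7)}
        assert len(sets) > 1

    def test_rejects_non_pd(self, tmp_path):
        bad = np.array([[1.0, 0.99, -0.99], [0.99, 1.0, 0.99], [-0.99, 0.99, 1.0]])
        path = tmp_path / "bad.csv"
        np.savetxt(path, bad, delimiter=",")
        with pytest.raises(DesignError):
            make_correlation("matrix_file", 3, source_file=str(path))

    def test_dimension_too_small(self, rng, tmp_path):
        path = tmp_path / "phi.csv"
        np.savetxt(path, np.eye(4), delimiter=",")
        with pytest.raises(DesignError):
            make_correlation("matrix_file", 10, source_file=str(path))


class TestDesignAudit:
    @pytest.mark.parametrize("keying", ["equal", "mixed"])
    @pytest.mark.parametrize("loading_dist", ["high_uniform", "realistic_truncnorm"])
    def test_generated_designs_pass_audit(self, rng, keying, loading_dist):
        for n_traits in (3, 5, 10):
            design = make_design(n_traits, keying, loading_dist, rng)
            design.validate(blocks_per_trait=9)  # raises on violation
            psi2 = design.error_variances
            np.testing.assert_allclose(psi2, 1 - design.loadings**2)

    def test_seed_reproducibility(self):
        d1 = make_design(5, "mixed", "high_uniform", np.random.default_rng(7))
        d2 = make_design(5, "mixed", "high_uniform", np.random.default_rng(7))
        np.testing.assert_array_equal(d1.blocks, d2.blocks)
        np.testing.assert_array_equal(d1.loadings, d2.loadings)
        np.testing.assert_array_equal(d1.item_means, d2.item_means)

    def test_roundtrip_serialization(self, mixed_design):
        rebuilt = type(mixed_design).from_frame(mixed_design.to_frame())
        np.testing.assert_array_equal(rebuilt.blocks, mixed_design.blocks)
        np.testing.assert_allclose(rebuilt.loadings, mixed_design.loadings)
        assert rebuilt.keying == "mixed"


def test_correlation_matrix_validation():
    with pytest.raises(DesignError):
        TraitCorrelationMatrix(np.array([[1.0, 0.5], [0.4, 1.0]]))  # asymmetric
    with pytest.raises(DesignError):
        TraitCorrelationMatrix(np.array([[1.0, 1.2], [1.2, 1.0]]))  # not PD
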