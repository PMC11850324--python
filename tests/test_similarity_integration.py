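import numpy as np
import pytest
from scipy.linalg import orth, subspace_angles

from kgrdr.errors import InvalidInputError
from kgrdr.similarity_integration import (
    average_entropy,
    denoise,
    fit_joint_decomposition,
    gip_similarity,
    joint_loss,
    laplacian_quadratic,
    reconstruct,
    select_similarities,
)
from kgrdr.synthetic_fixtures import FixtureSpec, make_similarity_stack
from kgrdr.types import InteractionMatrix, SimilarityMatrix

from .conftest import random_similarity, tiny_interactions


# ---------------------------------------------------------------------------
# gip_similarity
# ---------------------------------------------------------------------------

def _gip_oracle(profiles, gamma_prime):
    """Scalar-loop evaluation of the profile kernel."""
    n = len(profiles)
    gamma = gamma_prime * n / sum(sum(x * x for x in p) for p in profiles)
    out = np.empty((n, n))
    for a in range(n):
        for b in range(n):
            d2 = sum((x - y) ** 2 for x, y in zip(profiles[a], profiles[b]))
            out[a, b] = np.exp(-gamma * d2)
    return out


class TestGipSimilarity:
    def test_identical_profiles_have_similarity_one(self):
        inter = tiny_interactions()  # drugs dA and dC share a profile
        sim = gip_similarity(inter, axis="drugs")
        assert sim.values[0, 2] == pytest.approx(1.0)

    def test_two_by_two_hand_value(self):
        # profiles (1,0) and (0,1): gamma_n = 2*2/2 = 2, similarity e^-4
        inter = InteractionMatrix(
            drug_ids=["a", "b"], disease_ids=["x", "y"], values=np.eye(2, dtype=int)
        )
        sim = gip_similarity(inter, axis="drugs", gamma_prime=2.0)
        assert sim.values[0, 1] == pytest.approx(np.exp(-4.0), abs=1e-15)
        oracle = _gip_oracle([(1, 0), (0, 1)], gamma_prime=2.0)
        np.testing.assert_allclose(sim.values, oracle, atol=1e-12)

    def test_matches_loop_oracle(self, rng):
        values = (rng.random((6, 5)) < 0.4).astype(int)
        values[0, 0] = 1  # ensure nonzero
        inter = InteractionMatrix(
            drug_ids=[f"d{i}" for i in range(6)],
            disease_ids=[f"s{j}" for j in range(5)],
            values=values,
        )
        for axis, profiles in (("drugs", values), ("diseases", values.T)):
            sim = gip_similarity(inter, axis=axis, gamma_prime=1.0)
            oracle = _gip_oracle([tuple(p) for p in profiles], 1.0)
            np.testing.assert_allclose(sim.values, oracle, atol=1e-12)

    def test_default_gamma_unit_self_similarity(self):
        sim = gip_similarity(tiny_interactions(), axis="diseases")
        np.testing.assert_allclose(np.diag(sim.values), 1.0)

    def test_symmetric_unit_diagonal_in_unit_interval(self):
        sim = gip_similarity(tiny_interactions(), axis="drugs")
        np.testing.assert_allclose(sim.values, sim.values.T)
        assert (sim.values > 0).all() and (sim.values <= 1).all()

    def test_permutation_equivariance(self, rng):
        values = (rng.random((5, 4)) < 0.5).astype(int)
        values[:, 0] = 1
        inter = InteractionMatrix(
            drug_ids=[f"d{i}" for i in range(5)],
            disease_ids=[f"s{j}" for j in range(4)],
            values=values,
        )
        perm = rng.permutation(5)
        inter_p = InteractionMatrix(
            drug_ids=[inter.drug_ids[i] for i in perm],
            disease_ids=inter.disease_ids,
            values=values[perm],
        )
        s = gip_similarity(inter, axis="drugs").values
        sp = gip_similarity(inter_p, axis="drugs").values
        np.testing.assert_allclose(sp, s[np.ix_(perm, perm)], atol=1e-12)

    def test_all_zero_matrix_rejected(self):
        inter = InteractionMatrix(
            drug_ids=["a", "b"], disease_ids=["x"], values=np.zeros((2, 1), dtype=int)
        )
        with pytest.raises(InvalidInputError):
            gip_similarity(inter, axis="drugs")

    def test_nonpositive_gamma_rejected(self):
        with pytest.raises(InvalidInputError):
            gip_similarity(tiny_interactions(), axis="drugs", gamma_prime=0.0)


# ---------------------------------------------------------------------------
# average_entropy
# ---------------------------------------------------------------------------

class TestAverageEntropy:
    def test_identity_matrix_zero(self):
        sim = SimilarityMatrix(ids=list("abcd"), values=np.eye(4), source_name="i")
        assert average_entropy(sim) == pytest.approx(0.0)

    def test_uniform_matrix_log_n(self):
        sim = SimilarityMatrix(ids=list("abcd"), values=np.ones((4, 4)), source_name="u")
        assert average_entropy(sim) == pytest.approx(np.log(4))

    def test_hand_two_by_two(self):
        sim = SimilarityMatrix(
            ids=["a", "b"], values=np.array([[1.0, 1.0], [1.0, 0.0]]), source_name="h"
        )
        assert average_entropy(sim) == pytest.approx(np.log(2) / 2)

    def test_zero_row_contributes_zero(self, caplog):
        sim = SimilarityMatrix(
            ids=["a", "b"], values=np.zeros((2, 2)), source_name="z"
        )
        assert average_entropy(sim) == pytest.approx(0.0)

    def test_single_entity_rejected(self):
        sim = SimilarityMatrix(ids=["a"], values=np.ones((1, 1)), source_name="s")
        with pytest.raises(InvalidInputError):
            average_entropy(sim)

    def test_bounded_by_log_n(self, rng):
        for _ in range(5):
            sim = random_similarity(rng, 7)
            h = average_entropy(sim)
            assert 0.0 <= h <= np.log(7) + 1e-12


# ---------------------------------------------------------------------------
# select_similarities
# ---------------------------------------------------------------------------

def _redundancy_oracle(a, b):
    iu = np.triu_indices(a.shape[0], k=1)
    return np.corrcoef(a[iu], b[iu])[0, 1]


class TestSelectSimilarities:
    def test_single_matrix_returned_unchanged(self, rng):
        sim = random_similarity(rng, 5)
        out = select_similarities([sim])
        assert out == [sim]

    def test_exact_duplicate_dropped(self, rng):
        sim = random_similarity(rng, 6, name="orig")
        dup = SimilarityMatrix(ids=sim.ids, values=sim.values.copy(), source_name="dup")
        out = select_similarities([sim, dup], redundancy_threshold=0.99)
        assert len(out) == 1

    def test_uniform_and_duplicate_removed(self, rng):
        # 2 noisy copies of a latent structure, 1 near-uniform, 1 duplicate
        base = random_similarity(rng, 12, name="base").values
        ids = [f"e{i}" for i in range(12)]

        def noisy(name, scale):
            noise = rng.standard_normal((12, 12)) * scale
            values = np.clip(base + (noise + noise.T) / 2, 0, 1)
            np.fill_diagonal(values, 1.0)
            return SimilarityMatrix(ids=ids, values=values, source_name=name)

        v1 = noisy("v1", 0.3)
        v2 = noisy("v2", 0.3)
        uniform = SimilarityMatrix(ids=ids, values=np.ones((12, 12)), source_name="uni")
        dup = SimilarityMatrix(ids=ids, values=v1.values.copy(), source_name="dup")
        stack = [v1, v2, uniform, dup]
        out = select_similarities(stack)
        names = [s.source_name for s in out]
        assert "uni" not in names and "dup" not in names
        assert "v1" in names
        # oracle: no surviving pair exceeds the redundancy threshold
        for i, a in enumerate(out):
            for b in out[i + 1:]:
                assert _redundancy_oracle(a.values, b.values) <= 0.8

    def test_never_empty_and_never_redundant(self, rng):
        for trial in range(5):
            stack = [random_similarity(rng, 8, name=f"m{j}") for j in range(4)]
            stack.append(
                SimilarityMatrix(
                    ids=stack[0].ids, values=stack[0].values.copy(), source_name="copy"
                )
            )
            out = select_similarities(stack, entropy_quantile=0.5, redundancy_threshold=0.9)
            assert len(out) >= 1
            for i, a in enumerate(out):
                for b in out[i + 1:]:
                    assert _redundancy_oracle(a.values, b.values) <= 0.9

    def test_mismatched_ids_rejected(self, rng):
        a = random_similarity(rng, 4, ids=list("abcd"))
        b = random_similarity(rng, 4, ids=list("abdc"))
        with pytest.raises(InvalidInputError):
            select_similarities([a, b])

    def test_preserves_input_order(self, rng):
        stack = [random_similarity(rng, 9, name=f"m{j}") for j in range(4)]
        out = select_similarities(stack, entropy_quantile=1.0, redundancy_threshold=1.0)
        names = [s.source_name for s in out]
        assert names == sorted(names, key=lambda n: int(n[1:]))


# ---------------------------------------------------------------------------
# denoise
# ---------------------------------------------------------------------------

class TestDenoise:
    def test_alpha_to_zero_limit_is_normalized_input(self, rng):
        sim = random_similarity(rng, 8)
        out = denoise(sim, alpha=1e-12)
        d = sim.values.sum(axis=1)
        normalized = sim.values / np.sqrt(np.outer(d, d))
        np.testing.assert_allclose(out.values, normalized, atol=1e-9)

    def test_identity_input_any_alpha(self):
        sim = SimilarityMatrix(ids=list("abcde"), values=np.eye(5), source_name="i")
        for alpha in (0.2, 0.5, 0.9):
            out = denoise(sim, alpha=alpha)
            np.testing.assert_allclose(out.values, np.eye(5), atol=1e-12)

    def test_matches_truncated_power_series(self, rng):
        # oracle: (1-a) sum_t a^t S_norm^(2t+1)
        sim = random_similarity(rng, 10)
        alpha = 0.5
        out = denoise(sim, alpha=alpha)
        d = sim.values.sum(axis=1)
        s_norm = sim.values / np.sqrt(np.outer(d, d))
        series = np.zeros_like(s_norm)
        power = s_norm.copy()
        s2 = s_norm @ s_norm
        for t in range(201):
            series += alpha ** t * power
            power = power @ s2
        series *= 1.0 - alpha
        np.testing.assert_allclose(out.values, series, atol=1e-6)

    def test_eigenvalue_mapping(self, rng):
        sim = random_similarity(rng, 9)
        alpha = 0.7
        out = denoise(sim, alpha=alpha)
        expected = np.sort((1 - alpha) * out.eigvals / (1 - alpha * out.eigvals ** 2))
        actual = np.sort(np.linalg.eigvalsh(out.values))
        np.testing.assert_allclose(actual, expected, atol=1e-8)

    def test_closed_form_reproduction(self, rng):
        sim = random_similarity(rng, 7)
        out = denoise(sim, alpha=0.8)
        U, S = out.eigvecs, np.diag(out.eigvals)
        closed = (1 - 0.8) * U @ S @ np.linalg.inv(np.eye(7) - 0.8 * S @ S) @ U.T
        np.testing.assert_allclose(out.values, closed, atol=1e-10)

    def test_preserves_symmetry(self, rng):
        out = denoise(random_similarity(rng, 11), alpha=0.8)
        np.testing.assert_allclose(out.values, out.values.T, atol=1e-12)

    def test_isolated_entity_gets_self_loop(self):
        values = np.eye(3)
        values[2, 2] = 0.0  # entity 2 fully isolated
        sim = SimilarityMatrix(ids=list("abc"), values=values, source_name="iso")
        out = denoise(sim, alpha=0.5)
        assert np.isfinite(out.values).all()

    @pytest.mark.parametrize("alpha", [0.0, 1.0, -0.5, 1.5])
    def test_invalid_alpha_rejected(self, rng, alpha):
        with pytest.raises(InvalidInputError):
            denoise(random_similarity(rng, 4), alpha=alpha)


# ---------------------------------------------------------------------------
# reconstruct / joint_loss
# ---------------------------------------------------------------------------

class TestReconstruct:
    def test_zero_features_give_uniform_rows(self):
        out = reconstruct(np.zeros((3, 2)), np.zeros((2, 5)))
        np.testing.assert_allclose(out, np.full((3, 5), 0.2))

    def test_rows_sum_to_one(self, rng):
        out = reconstruct(rng.standard_normal((6, 3)), rng.standard_normal((3, 6)))
        np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-12)

    def test_two_by_two_closed_form(self):
        # logits row (1, 0) -> (e/(e+1), 1/(e+1))
        X = np.array([[1.0]])
        W = np.array([[1.0, 0.0]])
        out = reconstruct(X, W)
        e = np.e
        np.testing.assert_allclose(out, [[e / (e + 1), 1 / (e + 1)]], atol=1e-15)

    def test_overflow_safe(self):
        out = reconstruct(np.array([[1000.0]]), np.array([[1.0, 0.0]]))
        assert np.isfinite(out).all()


class TestJointLoss:
    def test_laplacian_trace_identity(self, rng):
        # brute-force oracle: Tr(X^T L X) = 1/2 sum_ij ||x_i - x_j||^2 s_ij
        S = random_similarity(rng, 6).values
        X = rng.standard_normal((6, 3))
        brute = 0.0
        for i in range(6):
            for j in range(6):
                brute += ((X[i] - X[j]) ** 2).sum() * S[i, j]
        brute /= 2.0
        assert laplacian_quadratic(X, S) == pytest.approx(brute, abs=1e-9)

    def test_perfect_reconstruction_zero_kl(self, rng):
        sim = random_similarity(rng, 5)
        dn = denoise(sim, alpha=0.5)
        target = np.maximum(dn.values, 0)
        target /= target.sum(axis=1, keepdims=True)
        # choose logits = log(target) so softmax reproduces the target rows
        X = np.eye(5)
        W = np.log(np.maximum(target, 1e-300))
        _, l_appr, _ = joint_loss([dn], X, [W], lambda_reg=0.0)
        assert l_appr == pytest.approx(0.0, abs=1e-9)

    def test_identical_rows_zero_regularizer(self, rng):
        sim = random_similarity(rng, 5)
        dn = denoise(sim, alpha=0.5)
        X = np.tile(rng.standard_normal(3), (5, 1))  # all entity rows equal
        _, _, l_reg = joint_loss([dn], X, [rng.standard_normal((3, 5))], 1.0)
        assert l_reg == pytest.approx(0.0, abs=1e-9)

    def test_loss_composition(self, rng):
        sim = random_similarity(rng, 6)
        dn = denoise(sim, alpha=0.5)
        X = rng.standard_normal((6, 3))
        W = rng.standard_normal((3, 6))
        lam = 0.3
        total, l_appr, l_reg = joint_loss([dn], X, [W], lam)
        assert total == pytest.approx(l_appr + lam * l_reg)
        assert l_appr >= 0.0
        assert np.isfinite([total, l_appr, l_reg]).all()


# ---------------------------------------------------------------------------
# fit_joint_decomposition
# ---------------------------------------------------------------------------

def _recovery_views(seed, sigma=0.05, n=20):
    spec = FixtureSpec(
        n_drugs=n, n_diseases=10, latent_rank=3, density=0.1, n_views=2,
        noise_sigma=sigma, redundancy_copies=0, add_noise_view=False, seed=seed,
    )
    return [denoise(s, 0.8) for s in make_similarity_stack(spec, "drugs")]


def _planted_factors(seed, n=20):
    return np.random.default_rng(
        np.random.SeedSequence([seed % 2 ** 32, 0])
    ).standard_normal((n, 3))


def _mean_canonical_correlation(X, F):
    return float(np.cos(subspace_angles(orth(X), orth(F))).mean())


class TestFitJointDecomposition:
    def test_beats_uniform_baseline(self, rng):
        dn = [denoise(random_similarity(rng, 8), 0.5)]
        res = fit_joint_decomposition(dn, dim_D=8, lambda_reg=0.0, seed=0)
        uniform_baseline = joint_loss(dn, np.zeros((8, 8)), [np.zeros((8, 8))], 0.0)[1]
        assert res.loss_trace[-1][1] < uniform_baseline

    def test_loss_trace_non_increasing(self, rng):
        dn = [denoise(random_similarity(rng, 10), 0.8) for _ in range(2)]
        res = fit_joint_decomposition(dn, dim_D=4, lambda_reg=0.1, seed=1)
        losses = [t[0] for t in res.loss_trace]
        diffs = np.diff(losses)
        assert (diffs <= 1e-9).all()

    def test_deterministic_given_seed(self, rng):
        dn = [denoise(random_similarity(rng, 8), 0.8)]
        a = fit_joint_decomposition(dn, dim_D=3, lambda_reg=0.1, seed=7, max_iter=50)
        b = fit_joint_decomposition(dn, dim_D=3, lambda_reg=0.1, seed=7, max_iter=50)
        assert abs(a.loss_trace[-1][0] - b.loss_trace[-1][0]) <= 1e-12
        np.testing.assert_array_equal(a.X, b.X)

    def test_recovers_planted_factors(self):
        recoveries = []
        for seed in (0, 1, 2):
            res = fit_joint_decomposition(
                _recovery_views(seed), dim_D=6, lambda_reg=0.01, seed=seed
            )
            recoveries.append(
                _mean_canonical_correlation(res.X, _planted_factors(seed))
            )
        assert np.mean(recoveries) > 0.8

    def test_noise_degrades_recovery(self):
        means = []
        for sigma in (0.02, 0.3):
            vals = []
            for seed in (0, 1):  # 2-seed tolerance
                res = fit_joint_decomposition(
                    _recovery_views(seed, sigma=sigma), dim_D=6, lambda_reg=0.01, seed=seed
                )
                vals.append(_mean_canonical_correlation(res.X, _planted_factors(seed)))
            means.append(np.mean(vals))
        assert means[1] <= means[0] + 0.02

    def test_reconstruction_rows_stochastic(self, rng):
        dn = [denoise(random_similarity(rng, 7), 0.8)]
        res = fit_joint_decomposition(dn, dim_D=3, lambda_reg=0.1, seed=0, max_iter=50)
        recon = reconstruct(res.X, res.W_list[0])
        np.testing.assert_allclose(recon.sum(axis=1), 1.0, atol=1e-8)

    def test_invalid_dim_rejected(self, rng):
        dn = [denoise(random_similarity(rng, 5), 0.5)]
        with pytest.raises(InvalidInputError):
            fit_joint_decomposition(dn, dim_D=6, lambda_reg=0.0)
        with pytest.raises(InvalidInputError):
            fit_joint_decomposition(dn, dim_D=2, lambda_reg=-1.0)
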