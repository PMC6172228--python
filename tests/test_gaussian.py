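"""Gaussian/Student humanness model: prior moments, conjugate posterior,
scoring against an independent density oracle, deltas, ablations, I/O."""

import numpy as np
import pytest
from scipy import integrate
from scipy.stats import multivariate_normal, multivariate_t

from humab import (
    AlignedSequence,
    MultivariateGaussianScorer,
    SequenceDatabase,
    ablate_correlations,
    encode_onehot,
    fit_mg,
    mg_max,
    mg_score,
    mg_score_delta,
    uniform_prior_moments,
)
from conftest import random_database, random_residues


class TestUniformPrior:
    def test_closed_form_moments(self):
        p = uniform_prior_moments(1, 20)
        assert np.allclose(p.eta, 1 / 21)
        assert np.allclose(np.diag(p.U), 20 / 441)
        off = p.U[~np.eye(20, dtype=bool)]
        assert np.allclose(off, -1 / 441)

    def test_smallest_eigenvalue(self):
        p = uniform_prior_moments(1, 20)
        assert np.isclose(np.linalg.eigvalsh(p.U).min(), 1 / 441)

    def test_positions_independent(self):
        p = uniform_prior_moments(2, 20)
        assert np.all(p.U[:20, 20:] == 0.0)
        assert np.all(p.U[20:, :20] == 0.0)

    def test_matches_empirical_uniform_sample(self, rng):
        # oracle: literal moments of a huge uniform categorical sample
        Q, n = 3, 200_000
        states = rng.integers(0, Q + 1, size=n)
        X = np.zeros((n, Q))
        hot = states < Q
        X[np.arange(n)[hot], states[hot]] = 1.0
        p = uniform_prior_moments(1, Q)
        assert np.allclose(X.mean(0), p.eta, atol=5e-3)
        assert np.allclose(np.cov(X.T, bias=True), p.U, atol=5e-3)


class TestFit:
    def test_identical_sequences_zero_covariance(self):
        db = SequenceDatabase.from_residues(["ACDE"] * 7, label="same")
        m = MultivariateGaussianScorer(lam=0.4).fit(db)
        assert np.all(m.Cbar_ == 0.0)
        d = m.xbar_ - m.eta_
        expected = 0.4 * m.U_ + 0.4 * 0.6 * np.outer(d, d)
        assert np.allclose(m.Sigma_post_, expected)

    def test_permutation_invariance(self, rng):
        db = random_database(rng, L=5, M=20)
        m1 = MultivariateGaussianScorer(lam=0.3).fit(db)
        perm = list(rng.permutation(db.M))
        db2 = SequenceDatabase([db.sequences[i] for i in perm], label="perm")
        m2 = MultivariateGaussianScorer(lam=0.3).fit(db2)
        assert np.array_equal(m1.mu_post_, m2.mu_post_)
        assert np.array_equal(m1.Sigma_post_, m2.Sigma_post_)
        s = random_residues(rng, 5)
        assert m1.score_sequence(s) == m2.score_sequence(s)

    def test_streaming_equals_batch(self, rng):
        db = random_database(rng, L=4, M=30)
        m = MultivariateGaussianScorer(lam=0.2).fit(db)
        # streaming oracle: accumulate sum and sum-of-outer one sequence at
        # a time, then finalize
        s1 = np.zeros(m.N_)
        s2 = np.zeros((m.N_, m.N_))
        for seq in db:
            x = encode_onehot(seq.residues)
            s1 += x
            s2 += np.outer(x, x)
        xbar = s1 / db.M
        Cbar = s2 / db.M - np.outer(xbar, xbar)
        assert np.allclose(m.xbar_, xbar, atol=1e-12)
        assert np.allclose(m.Cbar_, Cbar, atol=1e-12)

    def test_dof_and_scale(self, small_model):
        m = small_model
        assert m.dof_ == m.M_ / (1 - m.lam) + 2
        assert np.allclose(m.scale_, (1 + (1 - m.lam) / m.M_) * m.Sigma_post_)
        assert m.dof_ > 2

    @pytest.mark.parametrize("lam", [0.0, -0.1, 1.5])
    def test_invalid_lambda(self, lam, small_db):
        with pytest.raises(ValueError):
            MultivariateGaussianScorer(lam=lam).fit(small_db)

    def test_empty_database_rejected(self):
        with pytest.raises(ValueError):
            SequenceDatabase([])


class TestScore:
    def test_matches_independent_multivariate_t(self, rng):
        """The implemented closed form equals scipy's multivariate-t
        log-density on small random models."""
        for _ in range(25):
            Q = int(rng.integers(2, 4))
            L = int(rng.integers(1, 12 // Q + 1))
            alphabet = "ABCDEFGHIJ"[:Q]
            M = int(rng.integers(3, 25))
            lam = float(rng.uniform(0.05, 0.95))
            db = random_database(rng, L, M, alphabet=alphabet, gap_prob=0.1)
            m = MultivariateGaussianScorer(lam=lam, alphabet=alphabet).fit(db)
            oracle = multivariate_t(loc=m.mu_post_, shape=m.scale_, df=m.dof_)
            for _ in range(4):
                s = random_residues(rng, L, alphabet, gap_prob=0.1)
                assert m.score_sequence(s) == pytest.approx(
                    float(oracle.logpdf(encode_onehot(s, alphabet))), abs=1e-8
                )

    def test_mode_bounds_all_scores(self, small_model, rng):
        top = mg_max(small_model)
        assert top == small_model.log_norm_
        assert small_model.score_vector(small_model.mu_post_) == pytest.approx(top)
        for _ in range(200):
            s = random_residues(rng, 8)
            assert mg_score(small_model, s) <= top

    def test_identical_inputs_identical_scores(self, small_model):
        assert small_model.score_sequence("ACDEFGHI") == small_model.score_sequence(
            "ACDEFGHI"
        )

    def test_batch_matches_single(self, small_model, rng):
        seqs = [random_residues(rng, 8) for _ in range(10)]
        batch = small_model.score_samples(seqs)
        singles = [small_model.score_sequence(s) for s in seqs]
        assert np.allclose(batch, singles, atol=1e-10)

    def test_length_mismatch_rejected(self, small_model):
        with pytest.raises(ValueError, match="length"):
            small_model.score_sequence("ACD")

    def test_chain_mismatch_rejected(self, rng):
        db = SequenceDatabase.from_residues(
            [random_residues(rng, 149, gap_prob=0) for _ in range(5)], chain="VH"
        )
        m = MultivariateGaussianScorer(lam=0.5).fit(db)
        query = AlignedSequence("q", "A" * 149, chain="VL")
        with pytest.raises(ValueError, match="chain"):
            m.score_sequence(query)


class TestNormalizationAndLimits:
    def test_toy_density_integrates_to_one(self, rng):
        """For L=1, Q=2 (N=2) the exponentiated score is a proper density."""
        db = random_database(rng, L=1, M=12, alphabet="AB", gap_prob=0.2)
        m = MultivariateGaussianScorer(lam=0.5, alphabet="AB").fit(db)
        sd = np.sqrt(np.diag(m.scale_).max())
        lo, hi = -40 * sd, 1 + 40 * sd
        val, err = integrate.dblquad(
            lambda y2, y1: np.exp(m.score_vector(np.array([y1, y2]))),
            lo, hi, lo, hi,
        )
        assert val == pytest.approx(1.0, abs=1e-3)

    def test_lambda_one_returns_prior_exactly(self, small_db):
        m = MultivariateGaussianScorer(lam=1.0).fit(small_db)
        assert np.array_equal(m.mu_post_, m.eta_)
        assert np.array_equal(m.Sigma_post_, m.U_)
        assert np.isinf(m.dof_)

    def test_gaussian_limit(self, rng):
        db = random_database(rng, L=2, M=15, alphabet="ABC", gap_prob=0.1)
        m = MultivariateGaussianScorer(lam=1 - 1e-6, alphabet="ABC").fit(db)
        normal = multivariate_normal(mean=m.eta_, cov=m.U_)
        for _ in range(10):
            s = random_residues(rng, 2, "ABC", gap_prob=0.1)
            assert m.score_sequence(s) == pytest.approx(
                float(normal.logpdf(encode_onehot(s, "ABC"))), abs=1e-3
            )

    def test_posterior_moments_interpolate(self, small_db):
        lo = MultivariateGaussianScorer(lam=1e-3).fit(small_db)
        hi = MultivariateGaussianScorer(lam=1.0).fit(small_db)
        assert np.allclose(lo.mu_post_, lo.xbar_, atol=1e-3)
        assert np.array_equal(hi.mu_post_, hi.eta_)


class TestDelta:
    def test_noop_is_exact_zero(self, small_model, rng):
        s = random_residues(rng, 8)
        ctx = small_model.delta_context(s)
        assert ctx.delta(3, s[2]) == 0.0

    def test_matches_full_rescoring(self, small_model, rng):
        symbols = small_model.alphabet + "-"
        for _ in range(50):
            s = random_residues(rng, 8)
            ctx = small_model.delta_context(s)
            pos = int(rng.integers(1, 9))
            aa = symbols[rng.integers(len(symbols))]
            d = mg_score_delta(small_model, ctx, pos, aa)
            mutated = s[: pos - 1] + aa + s[pos:]
            full = small_model.score_sequence(mutated) - small_model.score_sequence(s)
            assert d == pytest.approx(full, abs=1e-9)

    def test_apply_then_reverse_restores_score(self, small_model, rng):
        s = random_residues(rng, 8)
        ctx = small_model.delta_context(s)
        start = ctx.score
        for _ in range(30):
            pos = int(rng.integers(1, 9))
            old = ctx.current_residues()[pos - 1]
            aa = (small_model.alphabet + "-")[rng.integers(21)]
            ctx.apply(pos, aa)
            ctx.apply(pos, old)
        assert ctx.score == pytest.approx(start, abs=1e-9)
        assert ctx.current_residues() == s

    def test_context_score_agrees_with_cholesky_path(self, small_model, rng):
        s = random_residues(rng, 8)
        ctx = small_model.delta_context(s)
        assert ctx.score == pytest.approx(small_model.score_sequence(s), abs=1e-9)
        ctx.apply(1, "W")
        assert ctx.score == pytest.approx(ctx.recompute(), abs=1e-9)

    def test_position_out_of_range(self, small_model, rng):
        ctx = small_model.delta_context(random_residues(rng, 8))
        with pytest.raises(ValueError):
            ctx.delta(9, "A")


class TestAblation:
    def test_all_off_is_block_diagonal(self, small_model):
        ab = ablate_correlations(small_model, "all_off")
        S = ab.Sigma_post_.reshape(8, 20, 8, 20)
        for i in range(8):
            for j in range(8):
                if i != j:
                    assert np.all(S[i, :, j, :] == 0.0)
                else:
                    assert np.array_equal(
                        S[i, :, i, :],
                        small_model.Sigma_post_.reshape(8, 20, 8, 20)[i, :, i, :],
                    )

    def test_interchain_off_zeroes_cross_blocks_only(self, small_model):
        ab = small_model.ablated("interchain_off", boundary=4)
        S = ab.Sigma_post_.reshape(8, 20, 8, 20)
        full = small_model.Sigma_post_.reshape(8, 20, 8, 20)
        for i in range(8):
            for j in range(8):
                cross = (i < 4) != (j < 4)
                if cross:
                    assert np.all(S[i, :, j, :] == 0.0)
                else:
                    assert np.array_equal(S[i, :, j, :], full[i, :, j, :])

    def test_all_off_then_interchain_is_all_off(self, small_model):
        once = small_model.ablated("all_off")
        twice = once.ablated("interchain_off", boundary=4)
        assert np.array_equal(once.Sigma_post_, twice.Sigma_post_)
        assert twice.ablation_ == "all_off"

    def test_interchain_requires_paired_chain_or_boundary(self, small_model):
        with pytest.raises(ValueError, match="paired-chain"):
            small_model.ablated("interchain_off")

    def test_lambda_unchanged(self, small_model):
        assert small_model.ablated("all_off").lam == small_model.lam


class TestSerialization:
    def test_roundtrip_scores_bit_identical(self, small_model, tmp_path, rng):
        path = tmp_path / "model.h5"
        small_model.save(path)
        back = MultivariateGaussianScorer.load(path)
        for _ in range(10):
            s = random_residues(rng, 8)
            assert back.score_sequence(s) == small_model.score_sequence(s)

    def test_roundtrip_preserves_ablation(self, small_model, tmp_path):
        ab = small_model.ablated("interchain_off", boundary=4)
        path = tmp_path / "ab.h5"
        ab.save(path)
        back = MultivariateGaussianScorer.load(path)
        assert back.ablation_ == "interchain_off"
        assert np.array_equal(back.Sigma_post_, ab.Sigma_post_)


def test_functional_surface_matches_estimator(small_db, rng):
    m1 = fit_mg(small_db, lam=0.2)
    m2 = MultivariateGaussianScorer(lam=0.2).fit(small_db)
    s = random_residues(rng, 8)
    assert mg_score(m1, s) == m2.score_sequence(s)
    assert mg_max(m1) == m2.mode_score_
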