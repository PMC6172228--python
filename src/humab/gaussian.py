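"""Bayesian multivariate-Gaussian humanness model ("MG score").

Each aligned sequence is one-hot encoded into a real vector of N = Q·L bits
and treated as a draw from a multivariate normal with unknown mean μ and
covariance Σ.  Under a Normal-Inverse-Wishart prior the posterior is again
NIW, and the posterior predictive density of a new sequence y is a
multivariate Student-t:

    p(y | X) = t_N(ν, ⟨μ⟩, S),     ν = M/(1−λ) + 2,
    ⟨μ⟩ = λη + (1−λ)x̄,
    ⟨Σ⟩ = λU + (1−λ)C̄ + λ(1−λ)(x̄−η)(x̄−η)ᵀ,
    S   = (1 + (1−λ)/M)·⟨Σ⟩,

where x̄ and C̄ are the empirical mean and (1/M-normalized) covariance of the
M one-hot encoded learning sequences, and (η, U) are the moments of a
uniformly distributed sample over the Q+1 per-position states (Q amino acids
plus the gap).  λ ∈ (0, 1] is the single regularization knob mixing the data
moments with the uninformative prior; the log of p(y|X) is the humanness
score (a log-*density*, so it is not bounded by 0).

Including the gap as a 21st uniform state makes U strictly positive definite
(smallest eigenvalue 1/(Q+1)², i.e. 1/441 for Q = 20), so the score is well
defined for any λ > 0 even when the empirical covariance is rank deficient.

The module also provides O(1)-per-candidate score deltas for single
mutations (the workhorse of the humanization optimizers) and correlation
ablations that zero cross-position or cross-chain covariance blocks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import h5py
import numpy as np
from scipy import linalg
from scipy.special import gammaln
from sklearn.base import BaseEstimator

from .alignment import (
    AA_ALPHABET,
    GAP,
    AlignedSequence,
    SequenceDatabase,
    encode_database,
    encode_onehot,
    indices_to_seq,
    seq_to_indices,
)

_FORMAT_VERSION = 1


@dataclass
class PriorSpec:
    """NIW prior moments: mean η, covariance scale U, and optionally the
    regularization weight λ they are to be mixed in with."""

    eta: np.ndarray
    U: np.ndarray
    lam: float | None = None
    kind: str = "custom"

    def __post_init__(self) -> None:
        self.eta = np.asarray(self.eta, dtype=np.float64)
        self.U = np.asarray(self.U, dtype=np.float64)
        n = self.eta.shape[0]
        if self.U.shape != (n, n):
            raise ValueError(f"U shape {self.U.shape} incompatible with eta ({n},)")
        if self.lam is not None and not (0.0 < self.lam <= 1.0):
            raise ValueError(f"lam must be in (0, 1], got {self.lam}")


def uniform_prior_moments(L: int, Q: int = 20) -> PriorSpec:
    """Exact first and second central moments of the one-hot encoding of a
    sequence uniform over the Q+1 states (Q letters + gap) at every position.

    η_i = 1/(Q+1); U is block diagonal with Q×Q blocks
    (1/s)·I − (1/s²)·J, s = Q+1 (zero between positions).
    """
    if L < 1 or Q < 1:
        raise ValueError("L and Q must be >= 1")
    s = Q + 1
    eta = np.full(L * Q, 1.0 / s)
    block = np.eye(Q) / s - 1.0 / s**2
    U = np.kron(np.eye(L), block)
    return PriorSpec(eta, U, kind="uniform")


class MultivariateGaussianScorer(BaseEstimator):
    """Posterior-predictive Student-t humanness scorer.

    Parameters
    ----------
    lam : float in (0, 1]
        Regularization weight mixing the uniform-sample prior moments with
        the empirical moments of the learning ensemble.  λ → 0 trusts the
        data; λ = 1 returns the prior exactly.
    prior : PriorSpec, optional
        Custom prior moments; defaults to :func:`uniform_prior_moments`.
    alphabet : str
        Ordered residue alphabet defining the one-hot block layout.

    Fitted attributes (trailing underscore) include the empirical moments
    ``xbar_``/``Cbar_``, the posterior moments ``mu_post_``/``Sigma_post_``,
    the Student-t parameters ``dof_``/``scale_`` with Cholesky factor
    ``chol_``, and the log normalizing constant ``log_norm_`` (which equals
    the score at the mode, the "MG_max" upper bound).
    """

    def __init__(
        self,
        lam: float = 0.05,
        prior: PriorSpec | None = None,
        alphabet: str = AA_ALPHABET,
    ):
        self.lam = lam
        self.prior = prior
        self.alphabet = alphabet

    # -- fitting ----------------------------------------------------------

    def fit(self, db: SequenceDatabase, y=None) -> "MultivariateGaussianScorer":
        if not (0.0 < self.lam <= 1.0):
            raise ValueError(f"lam must be in (0, 1], got {self.lam}")
        if not isinstance(db, SequenceDatabase):
            db = SequenceDatabase.from_residues(list(db), alphabet=self.alphabet)
        if db.alphabet != self.alphabet:
            raise ValueError(
                f"database alphabet {db.alphabet!r} != scorer alphabet "
                f"{self.alphabet!r}"
            )
        X = encode_database(db)
        # canonical row order: moments become bit-identical under any
        # permutation of the learning set
        X = X[np.lexsort(X.T[::-1])]
        M, N = X.shape
        L, Q = db.L, len(self.alphabet)
        prior = self.prior if self.prior is not None else uniform_prior_moments(L, Q)
        if prior.eta.shape[0] != N:
            raise ValueError(
                f"prior dimension {prior.eta.shape[0]} != N = {N}"
            )
        self.M_ = M
        self.N_ = N
        self.L_ = L
        self.Q_ = Q
        self.chain_ = db.chain
        self.label_ = db.label
        self.xbar_ = X.mean(axis=0)
        Xc = X - self.xbar_
        self.Cbar_ = (Xc.T @ Xc) / M  # biased 1/M normalizer, moment-matching
        self.eta_ = prior.eta.copy()
        self.U_ = prior.U.copy()
        self.prior_kind_ = prior.kind
        self.ablation_ = None
        self.boundary_ = None
        self._compute_posterior()
        return self

    def _compute_posterior(self) -> None:
        lam, M, N, L, Q = self.lam, self.M_, self.N_, self.L_, self.Q_
        d = self.xbar_ - self.eta_
        self.mu_post_ = lam * self.eta_ + (1.0 - lam) * self.xbar_
        Sigma = (
            lam * self.U_
            + (1.0 - lam) * self.Cbar_
            + lam * (1.0 - lam) * np.outer(d, d)
        )
        Sigma = (Sigma + Sigma.T) / 2.0
        if self.ablation_ == "all_off":
            B = Sigma.reshape(L, Q, L, Q)
            out = np.zeros_like(Sigma).reshape(L, Q, L, Q)
            for i in range(L):
                out[i, :, i, :] = B[i, :, i, :]
            Sigma = out.reshape(N, N)
        elif self.ablation_ == "interchain_off":
            b = self.boundary_
            B = Sigma.reshape(L, Q, L, Q)
            B[:b, :, b:, :] = 0.0
            B[b:, :, :b, :] = 0.0
            Sigma = B.reshape(N, N)
        self.Sigma_post_ = Sigma
        if lam == 1.0:
            self.dof_ = np.inf
            self.scale_ = Sigma.copy()
        else:
            self.dof_ = M / (1.0 - lam) + 2.0
            self.scale_ = (1.0 + (1.0 - lam) / M) * Sigma
        try:
            self.chol_ = linalg.cholesky(self.scale_, lower=True)
        except linalg.LinAlgError as exc:
            eigmin = float(linalg.eigvalsh(self.scale_, subset_by_index=[0, 0])[0])
            raise ValueError(
                f"scale matrix factorization failed (smallest pivot/eigenvalue "
                f"~ {eigmin:.3e}); increase lam"
            ) from exc
        self.logdet_ = 2.0 * float(np.sum(np.log(np.diag(self.chol_))))
        if np.isinf(self.dof_):
            self.log_norm_ = -0.5 * N * np.log(2.0 * np.pi) - 0.5 * self.logdet_
        else:
            nu = self.dof_
            self.log_norm_ = float(
                gammaln((nu + N) / 2.0)
                - gammaln(nu / 2.0)
                - 0.5 * N * np.log(nu * np.pi)
                - 0.5 * self.logdet_
            )
        self._precision: np.ndarray | None = None

    # -- scoring ----------------------------------------------------------

    def _check_fitted(self) -> None:
        if not hasattr(self, "chol_"):
            raise ValueError("scorer is not fitted")

    def _log_kernel(self, q: np.ndarray | float):
        """Log-density minus log_norm as a function of the Mahalanobis form q."""
        if np.isinf(self.dof_):
            return -0.5 * q
        return -0.5 * (self.dof_ + self.N_) * np.log1p(q / self.dof_)

    def score_vector(self, y: np.ndarray) -> float:
        """Score an arbitrary real vector of length N (the encoding space)."""
        self._check_fitted()
        y = np.asarray(y, dtype=np.float64)
        if y.shape != (self.N_,):
            raise ValueError(f"expected vector of length {self.N_}, got {y.shape}")
        z = y - self.mu_post_
        w = linalg.solve_triangular(self.chol_, z, lower=True, check_finite=False)
        q = float(w @ w)
        return float(self.log_norm_ + self._log_kernel(q))

    def _validate_sequence(self, seq: AlignedSequence | str) -> str:
        residues = seq.residues if isinstance(seq, AlignedSequence) else seq
        if len(residues) != self.L_:
            raise ValueError(
                f"sequence length {len(residues)} != model length {self.L_}"
            )
        if (
            isinstance(seq, AlignedSequence)
            and seq.chain is not None
            and self.chain_ is not None
            and seq.chain != self.chain_
        ):
            raise ValueError(
                f"sequence chain {seq.chain} != model chain {self.chain_}"
            )
        return residues

    def score_sequence(self, seq: AlignedSequence | str) -> float:
        residues = self._validate_sequence(seq)
        return self.score_vector(encode_onehot(residues, self.alphabet))

    def score_samples(self, seqs) -> np.ndarray:
        """Score a database or iterable of sequences; returns an array."""
        self._check_fitted()
        if isinstance(seqs, SequenceDatabase):
            seqs = list(seqs)
        Y = np.stack(
            [
                encode_onehot(self._validate_sequence(s), self.alphabet)
                for s in seqs
            ]
        )
        Z = (Y - self.mu_post_).T
        W = linalg.solve_triangular(self.chol_, Z, lower=True, check_finite=False)
        q = np.einsum("ij,ij->j", W, W)
        return self.log_norm_ + self._log_kernel(q)

    @property
    def mode_score_(self) -> float:
        """Score at the distribution mode y = ⟨μ⟩ (q = 0): an upper bound on
        the score of any input."""
        self._check_fitted()
        return float(self.log_norm_)

    @property
    def precision_(self) -> np.ndarray:
        """Dense inverse of the scale matrix; materialized lazily, needed
        only for single-mutation delta scoring."""
        self._check_fitted()
        if self._precision is None:
            P = linalg.cho_solve((self.chol_, True), np.eye(self.N_))
            self._precision = (P + P.T) / 2.0
        return self._precision

    def _aa_index(self, aa: str) -> int:
        if aa == GAP:
            return -1
        idx = self.alphabet.find(aa)
        if idx < 0:
            raise ValueError(f"residue {aa!r} not in alphabet")
        return idx

    def delta_context(self, seq: AlignedSequence | str) -> "DeltaContext":
        residues = self._validate_sequence(seq)
        return DeltaContext(self, residues)

    # -- ablations --------------------------------------------------------

    def ablated(
        self, mode: str, boundary: int | None = None
    ) -> "MultivariateGaussianScorer":
        """Return a new scorer with covariance blocks zeroed.

        ``all_off`` keeps only the within-position Q×Q diagonal blocks (an
        independent-sites model); ``interchain_off`` zeroes only blocks
        coupling positions 1..boundary with boundary+1..L (by default the
        149-position heavy/light split of a VHVL model).  λ is unchanged.
        """
        self._check_fitted()
        if mode not in ("all_off", "interchain_off"):
            raise ValueError(f"unknown ablation mode {mode!r}")
        if mode == "interchain_off":
            if boundary is None:
                if self.chain_ == "VHVL":
                    boundary = 149
                else:
                    raise ValueError(
                        "interchain_off requires a paired-chain (VHVL) model "
                        "or an explicit boundary"
                    )
            if not (1 <= boundary < self.L_):
                raise ValueError(f"boundary {boundary} out of range 1..{self.L_ - 1}")
        new = MultivariateGaussianScorer(
            lam=self.lam, prior=self.prior, alphabet=self.alphabet
        )
        for name in (
            "M_", "N_", "L_", "Q_", "chain_", "label_", "prior_kind_",
        ):
            setattr(new, name, getattr(self, name))
        for name in ("xbar_", "Cbar_", "eta_", "U_"):
            setattr(new, name, getattr(self, name).copy())
        # Ablations compose; all_off dominates interchain_off.
        if mode == "all_off" or self.ablation_ == "all_off":
            new.ablation_, new.boundary_ = "all_off", None
        else:
            new.ablation_, new.boundary_ = "interchain_off", boundary
        new._compute_posterior()
        return new

    # -- serialization ----------------------------------------------------

    def save(self, path) -> None:
        """Write the fitted model to a single HDF5 container."""
        self._check_fitted()
        meta = {
            "format_version": _FORMAT_VERSION,
            "lam": self.lam,
            "M": self.M_,
            "L": self.L_,
            "Q": self.Q_,
            "chain": self.chain_,
            "label": self.label_,
            "alphabet": self.alphabet,
            "prior_kind": self.prior_kind_,
            "ablation": self.ablation_,
            "boundary": self.boundary_,
        }
        with h5py.File(path, "w") as f:
            f.create_dataset("meta", data=json.dumps(meta))
            f.create_dataset("xbar", data=self.xbar_)
            f.create_dataset("Cbar", data=self.Cbar_)
            f.create_dataset("eta", data=self.eta_)
            f.create_dataset("lambda", data=self.lam)
            if self.prior_kind_ != "uniform":
                f.create_dataset("U", data=self.U_)

    @classmethod
    def load(cls, path) -> "MultivariateGaussianScorer":
        with h5py.File(path, "r") as f:
            meta = json.loads(f["meta"][()].decode())
            xbar = f["xbar"][()]
            Cbar = f["Cbar"][()]
            eta = f["eta"][()]
            U = f["U"][()] if "U" in f else None
        if meta["format_version"] > _FORMAT_VERSION:
            raise ValueError("model file written by a newer format version")
        model = cls(lam=meta["lam"], alphabet=meta["alphabet"])
        model.M_ = meta["M"]
        model.L_ = meta["L"]
        model.Q_ = meta["Q"]
        model.N_ = meta["L"] * meta["Q"]
        model.chain_ = meta["chain"]
        model.label_ = meta.get("label", "")
        model.prior_kind_ = meta["prior_kind"]
        model.ablation_ = meta["ablation"]
        model.boundary_ = meta["boundary"]
        model.xbar_ = xbar
        model.Cbar_ = Cbar
        model.eta_ = eta
        if U is None:
            U = uniform_prior_moments(model.L_, model.Q_).U
        model.U_ = U
        model._compute_posterior()
        return model


class DeltaContext:
    """Cached residual state enabling O(1) single-mutation score deltas.

    A point mutation flips at most two bits of the one-hot vector, so with
    the precision matrix P = S⁻¹ and the cached products z = y − ⟨μ⟩ and
    P·z, the new Mahalanobis form is a rank-≤2 update:

        q' = q + 2·eᵀPz + eᵀPe

    with e the (sparse) encoding change.  Accepted mutations update the
    cache in O(N).
    """

    def __init__(self, model: MultivariateGaussianScorer, residues: str):
        self.model = model
        self.ints = seq_to_indices(residues, model.alphabet)
        y = encode_onehot(residues, model.alphabet)
        self.z = y - model.mu_post_
        P = model.precision_
        self.Pz = P @ self.z
        self.q = float(self.z @ self.Pz)
        self.score = float(model.log_norm_ + model._log_kernel(self.q))

    def current_residues(self) -> str:
        return indices_to_seq(self.ints, self.model.alphabet)

    def _changes(self, pos: int, new_idx: int):
        model = self.model
        if not (1 <= pos <= model.L_):
            raise ValueError(f"position {pos} out of range 1..{model.L_}")
        cur = int(self.ints[pos - 1])
        if new_idx == cur:
            return cur, []
        base = (pos - 1) * model.Q_
        changes = []
        if cur >= 0:
            changes.append((base + cur, -1.0))
        if new_idx >= 0:
            changes.append((base + new_idx, 1.0))
        return cur, changes

    def _delta_q(self, changes) -> float:
        P = self.model.precision_
        dq = 0.0
        for k, c in changes:
            dq += 2.0 * c * float(self.Pz[k])
        for k1, c1 in changes:
            for k2, c2 in changes:
                dq += c1 * c2 * float(P[k1, k2])
        return dq

    def delta_idx(self, pos: int, new_idx: int) -> float:
        """Score change of mutating ``pos`` to alphabet index ``new_idx``
        (-1 for gap), without applying it."""
        _, changes = self._changes(pos, new_idx)
        if not changes:
            return 0.0
        qnew = self.q + self._delta_q(changes)
        m = self.model
        return float(m._log_kernel(qnew) - m._log_kernel(self.q))

    def delta(self, pos: int, new_aa: str) -> float:
        return self.delta_idx(pos, self.model._aa_index(new_aa))

    def apply_idx(self, pos: int, new_idx: int) -> float:
        """Apply the mutation, updating the cache; returns the score delta."""
        _, changes = self._changes(pos, new_idx)
        if not changes:
            return 0.0
        qnew = self.q + self._delta_q(changes)
        m = self.model
        d = float(m._log_kernel(qnew) - m._log_kernel(self.q))
        P = m.precision_
        for k, c in changes:
            self.Pz += c * P[:, k]
            self.z[k] += c
        self.q = qnew
        self.score += d
        self.ints[pos - 1] = new_idx
        return d

    def apply(self, pos: int, new_aa: str) -> float:
        return self.apply_idx(pos, self.model._aa_index(new_aa))

    def recompute(self) -> float:
        """Full-path score of the current sequence (drift check)."""
        return self.model.score_sequence(self.current_residues())


# ---------------------------------------------------------------------------
# Thin functional surface


def fit_mg(
    db: SequenceDatabase, lam: float = 0.05, prior: PriorSpec | None = None
) -> MultivariateGaussianScorer:
    """Fit the posterior-predictive Student-t model on a learning ensemble."""
    if prior is not None and prior.lam is not None:
        lam = prior.lam
    return MultivariateGaussianScorer(
        lam=lam, prior=prior, alphabet=db.alphabet
    ).fit(db)


def mg_score(model: MultivariateGaussianScorer, seq: AlignedSequence | str) -> float:
    return model.score_sequence(seq)


def mg_max(model: MultivariateGaussianScorer) -> float:
    return model.mode_score_


def mg_score_delta(
    model: MultivariateGaussianScorer,
    ctx: DeltaContext,
    pos: int,
    new_aa: str,
) -> float:
    if ctx.model is not model:
        raise ValueError("context was built for a different model")
    return ctx.delta(pos, new_aa)


def ablate_correlations(
    model: MultivariateGaussianScorer, mode: str, boundary: int | None = None
) -> MultivariateGaussianScorer:
    return model.ablated(mode, boundary=boundary)
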