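"""Synthetic aligned-sequence ensembles with controlled statistics.

Two generative families make every statistical claim in the package
testable without external antibody databases:

* :class:`ProfileModel` — independent per-position categorical profiles
  over 21 states (20 amino acids + gap); i.i.d. sampling.
* :class:`CoupledModel` — per-position fields plus pairwise log-coupling
  tables, sampled by single-site Gibbs sweeps from the corresponding
  Boltzmann distribution.  This emulates the pair correlations (within and
  across chains) that the covariance-aware humanness model is designed to
  capture, and whose removal degrades classification.

:func:`make_species_pair` builds two coupled models sharing a base profile
but diverging in a fraction of site preferences and in their coupling
tables — a stand-in for the human/murine ensemble pair used in the
classification experiments.  All generators are bit-reproducible for a
fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import AA_ALPHABET, GAP, SequenceDatabase

N_STATES = 21  # 20 amino acids + gap; state index 20 is the gap
_SYMBOLS = AA_ALPHABET + GAP


def _ints_to_residues(states: np.ndarray) -> str:
    return "".join(_SYMBOLS[int(s)] for s in states)


def _db_from_states(states: np.ndarray, label: str) -> SequenceDatabase:
    M = states.shape[0]
    width = max(4, len(str(M)))
    residues = [_ints_to_residues(row) for row in states]
    ids = [f"{label}_{i:0{width}d}" for i in range(M)]
    return SequenceDatabase.from_residues(
        residues, chain=None, label=label, ids=ids
    )


@dataclass
class ProfileModel:
    """Independent-sites categorical sequence model."""

    L: int
    probs: np.ndarray  # (L, 21), rows sum to 1
    seed: int = 0

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.shape != (self.L, N_STATES):
            raise ValueError(
                f"probs must have shape ({self.L}, {N_STATES}), got {self.probs.shape}"
            )
        if (self.probs < 0).any():
            raise ValueError("probabilities must be non-negative")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("each per-position probability row must sum to 1")

    @classmethod
    def uniform(cls, L: int, seed: int = 0) -> "ProfileModel":
        return cls(L, np.full((L, N_STATES), 1.0 / N_STATES), seed=seed)

    @classmethod
    def random(
        cls,
        L: int,
        seed: int = 0,
        gap_prob: float = 0.02,
        concentration: float = 0.5,
    ) -> "ProfileModel":
        """Dirichlet-distributed amino-acid profiles with a fixed small gap
        probability per site (default 2%, so gap code paths are exercised).

        The default concentration 0.5 yields sparse, moderately conserved
        columns with a few dominant residues, as framework alignment
        columns show."""
        rng = np.random.default_rng(seed)
        aa = rng.dirichlet(np.full(20, concentration), size=L) * (1.0 - gap_prob)
        probs = np.hstack([aa, np.full((L, 1), gap_prob)])
        return cls(L, probs, seed=seed)


def sample_profile_db(
    model: ProfileModel, M: int, label: str = "profile", seed: int | None = None
) -> SequenceDatabase:
    """Draw M i.i.d. sequences, each position from its own profile."""
    if M < 1:
        raise ValueError("M must be >= 1")
    rng = np.random.default_rng(model.seed if seed is None else seed)
    cum = np.cumsum(model.probs, axis=1)
    cum[:, -1] = 1.0
    u = rng.random((M, model.L))
    states = np.empty((M, model.L), dtype=np.int64)
    for j in range(model.L):
        states[:, j] = np.searchsorted(cum[j], u[:, j], side="right")
    return _db_from_states(states, label)


@dataclass
class CoupledModel:
    """Fields-plus-pairwise-couplings (Potts-like) sequence model.

    Energy of a state vector s: −Σ_i fields[i][s_i] − Σ_(i,j) J_ij[s_i, s_j]
    over the listed couplings (1-based positions, i < j); sampling is by
    single-site Gibbs sweeps with ``gibbs_burnin`` sweeps of burn-in and
    ``gibbs_thin`` sweeps between recorded samples.
    """

    L: int
    fields: np.ndarray  # (L, 21) log-preferences
    couplings: list = field(default_factory=list)  # [(i, j, (21, 21) table)]
    gibbs_burnin: int = 100
    gibbs_thin: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        self.fields = np.asarray(self.fields, dtype=np.float64)
        if self.fields.shape != (self.L, N_STATES):
            raise ValueError(
                f"fields must have shape ({self.L}, {N_STATES}), got {self.fields.shape}"
            )
        if not np.isfinite(self.fields).all():
            raise ValueError("fields must be finite")
        norm = []
        for i, j, tab in self.couplings:
            tab = np.asarray(tab, dtype=np.float64)
            if not (1 <= i < j <= self.L):
                raise ValueError(f"coupling positions ({i}, {j}) invalid for L={self.L}")
            if tab.shape != (N_STATES, N_STATES) or not np.isfinite(tab).all():
                raise ValueError(f"coupling table ({i}, {j}) malformed")
            norm.append((int(i), int(j), tab))
        self.couplings = norm

    def log_weight(self, states: np.ndarray) -> float:
        """Unnormalized Boltzmann log-weight of a state vector (0-based states)."""
        lw = float(self.fields[np.arange(self.L), states].sum())
        for i, j, tab in self.couplings:
            lw += float(tab[states[i - 1], states[j - 1]])
        return lw


def _gibbs_neighbors(model: CoupledModel):
    nb: list[list[tuple[int, np.ndarray, int]]] = [[] for _ in range(model.L)]
    for i, j, tab in model.couplings:
        nb[i - 1].append((j - 1, tab, 0))  # tab[s_i, s_j]: axis 0 is site i
        nb[j - 1].append((i - 1, tab, 1))
    return nb


def sample_coupled_db(
    model: CoupledModel, M: int, label: str = "coupled", seed: int | None = None
) -> SequenceDatabase:
    """Gibbs-sample M sequences from the Boltzmann distribution of the model."""
    if M < 1:
        raise ValueError("M must be >= 1")
    rng = np.random.default_rng(model.seed if seed is None else seed)
    nb = _gibbs_neighbors(model)
    L = model.L

    # init from the fields-only conditional
    def _softmax_sample(logits: np.ndarray) -> int:
        p = np.exp(logits - logits.max())
        p /= p.sum()
        return int(np.searchsorted(np.cumsum(p), rng.random(), side="right"))

    state = np.array([_softmax_sample(model.fields[i]) for i in range(L)])

    def _sweep() -> None:
        for i in range(L):
            logits = model.fields[i].copy()
            for other, tab, axis in nb[i]:
                if axis == 0:
                    logits += tab[:, state[other]]
                else:
                    logits += tab[state[other], :]
            state[i] = _softmax_sample(logits)

    for _ in range(model.gibbs_burnin):
        _sweep()
    out = np.empty((M, L), dtype=np.int64)
    for m in range(M):
        for _ in range(model.gibbs_thin):
            _sweep()
        out[m] = state
    return _db_from_states(out, label)


def _gap_column(aa_fields: np.ndarray, gap_prob: float) -> np.ndarray:
    """Gap log-field making the fields-only gap marginal equal gap_prob."""
    total = np.log(np.exp(aa_fields).sum(axis=1))
    return np.log(gap_prob / (1.0 - gap_prob)) + total


def make_species_pair(
    L: int,
    divergence: float,
    coupling_strength: float,
    cross_chain: bool = True,
    seed: int = 0,
    gap_prob: float = 0.02,
) -> tuple[CoupledModel, CoupledModel]:
    """Build a "human-like" / "murine-like" pair of coupled models.

    The two models share a random base profile; a fraction ``divergence``
    of positions gets independently shifted preferences in the murine
    model.  Couplings of the given strength are placed within positions
    1..L/2 and L/2+1..L (the two "chains"), plus cross-chain pairs when
    ``cross_chain``.  The two species share coupling positions and
    magnitude but prefer inverted pair combinations (the murine tables are
    the negated human ones), so species identity is carried substantially
    by the pair correlations rather than by single-site composition — the
    regime where covariance-aware scoring should dominate.  Deterministic
    per seed.
    """
    if not (0.0 <= divergence <= 1.0):
        raise ValueError("divergence must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    # Base fields concentrate each site on a handful of preferred letters
    # (as real alignment columns do) and are shared between species, so at
    # divergence 0 composition alone carries no species signal.
    base = rng.normal(0.0, 1.5, size=(L, 20))
    n_div = int(round(divergence * L))
    div_pos = rng.choice(L, size=n_div, replace=False) if n_div else np.array([], int)
    murine_aa = base.copy()
    if n_div:
        murine_aa[div_pos] += rng.normal(0.0, 0.5, size=(n_div, 20))

    def _with_gap(aa: np.ndarray) -> np.ndarray:
        return np.hstack([aa, _gap_column(aa, gap_prob)[:, None]])

    # Couplings form a matching (every site in at most one pair): the
    # coupled system factorizes into independent two-site subsystems, so
    # single-site Gibbs provably mixes even at strong coupling.  About a
    # third of each chain's sites pair within the chain; leftovers pair
    # across the chain boundary when cross_chain.
    half = L // 2
    pool_a = list(rng.permutation(np.arange(half)))
    pool_b = list(rng.permutation(np.arange(half, L)))
    n_within = max(1, half // 3)
    pairs: list[tuple[int, int]] = []
    for pool in (pool_a, pool_b):
        for _ in range(n_within):
            if len(pool) >= 2:
                i, j = pool.pop(), pool.pop()
                pairs.append((min(i, j) + 1, max(i, j) + 1))
    if cross_chain:
        while pool_a and pool_b:
            i, j = pool_a.pop(), pool_b.pop()
            pairs.append((i + 1, j + 1))
    pairs.sort()

    # Each site gets a random balanced +-1 class assignment of its 20
    # letters (gaps are class 0); a coupling table is the rank-one spin
    # product strength * s_i s_j^T.  The human model favours same-class
    # pairs along each coupled edge, the murine model the inverted
    # combinations: correlation structure flips while letter classes and
    # magnitudes are shared.
    spins = np.zeros((L, N_STATES))
    for i in range(L):
        half_states = rng.permutation(20)
        spins[i, half_states[:10]] = 1.0
        spins[i, half_states[10:]] = -1.0
    tables_h = []
    tables_m = []
    for a, b in pairs:
        J = coupling_strength * np.outer(spins[a - 1], spins[b - 1])
        tables_h.append((a, b, J))
        tables_m.append((a, b, -J))

    human = CoupledModel(L, _with_gap(base), tables_h, seed=seed + 1)
    murine = CoupledModel(L, _with_gap(murine_aa), tables_m, seed=seed + 1)
    return human, murine
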