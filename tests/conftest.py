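"""Shared fixtures: small random aligned ensembles and tiny fitted models."""

import numpy as np
import pytest

from humab import (
    AA_ALPHABET,
    GAP,
    AlignedSequence,
    MultivariateGaussianScorer,
    SequenceDatabase,
)


def random_residues(rng, L, alphabet=AA_ALPHABET, gap_prob=0.05):
    symbols = list(alphabet) + [GAP]
    probs = np.full(len(symbols), (1.0 - gap_prob) / len(alphabet))
    probs[-1] = gap_prob
    return "".join(rng.choice(symbols, size=L, p=probs))


def random_database(rng, L, M, alphabet=AA_ALPHABET, gap_prob=0.05, label="toy"):
    return SequenceDatabase.from_residues(
        [random_residues(rng, L, alphabet, gap_prob) for _ in range(M)],
        label=label,
        alphabet=alphabet,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_db(rng):
    """40 random 8-mers over the full amino-acid alphabet with some gaps."""
    return random_database(rng, L=8, M=40)


@pytest.fixture
def small_model(small_db):
    return MultivariateGaussianScorer(lam=0.2).fit(small_db)


@pytest.fixture
def tiny_model(rng):
    """Model over a 4-letter alphabet, L=3: landscapes small enough to
    enumerate exhaustively."""
    db = random_database(rng, L=3, M=25, alphabet="ACDE", gap_prob=0.0)
    return MultivariateGaussianScorer(lam=0.3, alphabet="ACDE").fit(db)


@pytest.fixture
def tiny_origin(tiny_model, rng):
    return AlignedSequence(
        "origin", random_residues(rng, 3, "ACDE", 0.0), alphabet="ACDE"
    )
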