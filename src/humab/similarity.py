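"""Distance-based humanness scores.

T_k(A) is the mean Hamming distance from a query A to its k nearest
sequences in a reference ensemble (T_1 = nearest neighbour, T_all = mean
over the whole ensemble); lower means more human-like when the reference is
human.  Nearest-k selection is by the k smallest distance *values*, so ties
at the k-th distance never make the score depend on reference ordering.

The two-reference score contrasts the mean distance to a murine ensemble
with the mean distance to a human one; it is oriented so that positive
values indicate a more human-like query.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .alignment import AlignedSequence, CDRMask, SequenceDatabase, seq_to_indices


@dataclass
class DistanceProfile:
    query_id: str
    k: int | str
    score: float
    reference_label: str


def _query_indices(query: AlignedSequence | str, db: SequenceDatabase) -> np.ndarray:
    if isinstance(query, AlignedSequence):
        if (
            query.chain is not None
            and db.chain is not None
            and query.chain != db.chain
        ):
            raise ValueError(
                f"query chain {query.chain} != reference chain {db.chain}"
            )
        residues = query.residues
    else:
        residues = query
    if len(residues) != db.L:
        raise ValueError(f"query length {len(residues)} != reference L {db.L}")
    return seq_to_indices(residues, db.alphabet)


class NearestReferenceScorer(BaseEstimator):
    """Mean Hamming distance to the k nearest reference sequences.

    ``k`` may be an integer or ``"all"``; ``exclude`` is an optional
    :class:`CDRMask` of positions dropped from the distance (the
    framework-only variant).
    """

    def __init__(self, k: int | str = 1, exclude: CDRMask | None = None):
        self.k = k
        self.exclude = exclude

    def fit(self, ref_db: SequenceDatabase, y=None) -> "NearestReferenceScorer":
        self.ref_ = ref_db
        self.ref_indices_ = ref_db.indices_matrix()
        self.keep_ = np.ones(ref_db.L, dtype=bool)
        if self.exclude is not None:
            self.keep_ &= ~self.exclude.membership(ref_db.L)
        k = self.k
        if k != "all" and not (1 <= int(k) <= ref_db.M):
            raise ValueError(f"k must be in 1..{ref_db.M} or 'all', got {k}")
        return self

    def _distances(self, query: AlignedSequence | str) -> np.ndarray:
        q = _query_indices(query, self.ref_)
        diff = self.ref_indices_[:, self.keep_] != q[self.keep_]
        return diff.sum(axis=1)

    def score_one(self, query: AlignedSequence | str) -> float:
        d = self._distances(query)
        if self.k == "all":
            return float(d.mean())
        k = int(self.k)
        return float(np.sort(np.partition(d, k - 1)[:k]).mean())

    def score_samples(self, queries) -> np.ndarray:
        if isinstance(queries, SequenceDatabase):
            queries = list(queries)
        return np.array([self.score_one(q) for q in queries])


def t_k_score(
    ref: SequenceDatabase,
    query: AlignedSequence | str,
    k: int | str = 1,
    mask: CDRMask | None = None,
) -> DistanceProfile:
    """T_k score of a query against a reference ensemble."""
    scorer = NearestReferenceScorer(k=k, exclude=mask).fit(ref)
    qid = query.id if isinstance(query, AlignedSequence) else "query"
    return DistanceProfile(qid, k, scorer.score_one(query), ref.label)


def two_reference_score(
    ref_h: SequenceDatabase,
    ref_m: SequenceDatabase,
    query: AlignedSequence | str,
    mask: CDRMask | None = None,
) -> float:
    """Mean-distance contrast d̄_m(A) − d̄_h(A); positive ⇒ closer to the
    human ensemble (human-like)."""
    if ref_h.L != ref_m.L:
        raise ValueError("reference ensembles have different lengths")
    dh = NearestReferenceScorer(k="all", exclude=mask).fit(ref_h).score_one(query)
    dm = NearestReferenceScorer(k="all", exclude=mask).fit(ref_m).score_one(query)
    return float(dm - dh)
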