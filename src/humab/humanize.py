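"""CDR-preserving humanization by score optimization.

The negative humanness score E(y) = −log p(y|X) is treated as an energy
over sequence space.  Starting from a murine sequence, the CDR positions
are frozen (they carry the antigen-binding function) and framework
positions are mutated to lower E:

* steepest descent (SD): at every step all single mutations at all free
  positions are evaluated and the best strictly-improving one is applied;
  the walk stops at a local optimum.  The trajectory is the ordered list of
  "best humanizing mutations", useful when few mutations are wanted.
* simulated-annealing Monte Carlo (SAMC): random single mutations accepted
  by the Metropolis rule min(1, exp(−ΔE/T)) under a decreasing temperature
  schedule; better at escaping local optima, returns the best-ever visited
  sequence.

Gap proposals are excluded by default (``allow_gaps=True`` permits them):
introducing indels into a fixed framework is rarely wanted.  ``residues``
restricts the proposal alphabet (e.g. to exclude cysteines).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import (
    GAP,
    AlignedSequence,
    CDRMask,
    hamming_distance,
)
from .gaussian import DeltaContext, MultivariateGaussianScorer


@dataclass(frozen=True)
class AnnealSchedule:
    """Linear cooling schedule: T from ``t_init`` down to ``t_final`` in
    steps of ``dt``, with ``steps_per_t`` Metropolis proposals per stage."""

    t_init: float = 25.1
    t_final: float = 0.1
    dt: float = 0.5
    steps_per_t: int = 20_000

    def __post_init__(self) -> None:
        if not (self.t_init >= self.t_final > 0):
            raise ValueError("need t_init >= t_final > 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.steps_per_t < 1:
            raise ValueError("steps_per_t must be >= 1")

    def temperatures(self) -> np.ndarray:
        n_stages = int(np.floor((self.t_init - self.t_final) / self.dt + 1e-9)) + 1
        return self.t_init - self.dt * np.arange(n_stages)

    @classmethod
    def paper_preset(cls) -> "AnnealSchedule":
        """Cluster-scale preset: 3.74e6 proposals per temperature stage."""
        return cls(t_init=25.1, t_final=0.1, dt=0.5, steps_per_t=3_740_000)

    @classmethod
    def desk_preset(cls) -> "AnnealSchedule":
        return cls()


@dataclass
class TrajectoryStep:
    step: int
    temperature: float | None
    position: int
    from_aa: str
    to_aa: str
    score_after: float
    hd_to_origin: int


@dataclass
class HumanizationTrajectory:
    origin: AlignedSequence
    method: str  # "SD" | "SAMC"
    mask: CDRMask | None
    seed: int | None
    steps: list[TrajectoryStep]
    final: AlignedSequence
    best: AlignedSequence
    best_score: float
    origin_score: float
    n_proposals: int = 0

    def scores(self) -> np.ndarray:
        return np.array([s.score_after for s in self.steps])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "step": s.step,
                    "temperature": s.temperature,
                    "position": s.position,
                    "from": s.from_aa,
                    "to": s.to_aa,
                    "score": s.score_after,
                    "hd_to_origin": s.hd_to_origin,
                }
                for s in self.steps
            ]
        )


def _free_positions(L: int, mask: CDRMask | None) -> list[int]:
    fixed = set(mask.positions) if mask is not None else set()
    free = [p for p in range(1, L + 1) if p not in fixed]
    if not free:
        raise ValueError("mask freezes every position; nothing to optimize")
    return free


def _candidate_indices(
    model: MultivariateGaussianScorer,
    residues: str | None,
    allow_gaps: bool,
) -> list[int]:
    alphabet = model.alphabet if residues is None else residues
    idx = [model._aa_index(a) for a in sorted(set(alphabet) - {GAP})]
    if allow_gaps:
        idx.append(-1)
    return idx


def _result_sequence(
    origin: AlignedSequence, ints: np.ndarray, model, suffix: str
) -> AlignedSequence:
    from .alignment import indices_to_seq

    return AlignedSequence(
        f"{origin.id}|{suffix}",
        indices_to_seq(ints, model.alphabet),
        chain=origin.chain,
        species=origin.species,
        alphabet=origin.alphabet,
    )


def steepest_descent(
    model: MultivariateGaussianScorer,
    origin: AlignedSequence,
    mask: CDRMask | None = None,
    allow_gaps: bool = False,
    residues: str | None = None,
) -> HumanizationTrajectory:
    """Greedy best-single-mutation ascent of the humanness score.

    At each step every candidate mutation at every free position is scored
    via the O(1) delta machinery and the strictly best-improving one is
    applied; equal improvements break ties toward the lowest position, then
    the alphabetically first residue.  Terminates at a local optimum (all
    deltas <= 0).  Deterministic.
    """
    ctx = model.delta_context(origin)
    free = _free_positions(model.L_, mask)
    cands = _candidate_indices(model, residues, allow_gaps)
    origin_score = ctx.score
    steps: list[TrajectoryStep] = []
    hd = 0
    symbols = model.alphabet + GAP
    while True:
        best_d, best_pos, best_idx = 0.0, None, None
        for pos in free:
            cur = int(ctx.ints[pos - 1])
            for j in cands:
                if j == cur:
                    continue
                d = ctx.delta_idx(pos, j)
                if d > best_d:
                    best_d, best_pos, best_idx = d, pos, j
        if best_pos is None:
            break
        from_aa = symbols[int(ctx.ints[best_pos - 1])]
        origin_aa = origin.residues[best_pos - 1]
        was_match = from_aa == origin_aa
        ctx.apply_idx(best_pos, best_idx)
        to_aa = symbols[best_idx]
        hd += (to_aa != origin_aa) - (not was_match)
        steps.append(
            TrajectoryStep(
                len(steps) + 1, None, best_pos, from_aa, to_aa, ctx.score, hd
            )
        )
    final = _result_sequence(origin, ctx.ints, model, "sd")
    return HumanizationTrajectory(
        origin=origin,
        method="SD",
        mask=mask,
        seed=None,
        steps=steps,
        final=final,
        best=final,
        best_score=ctx.score,
        origin_score=origin_score,
        n_proposals=0,
    )


def samc(
    model: MultivariateGaussianScorer,
    origin: AlignedSequence,
    mask: CDRMask | None = None,
    schedule: AnnealSchedule | None = None,
    seed: int | None = None,
    allow_gaps: bool = False,
    residues: str | None = None,
) -> HumanizationTrajectory:
    """Simulated-annealing Metropolis optimization of the humanness score.

    Each proposal draws a uniform free position, then a uniform alternative
    residue at that position, and accepts with min(1, exp(ΔS/T)) where ΔS
    is the score change (= −ΔE).  After ``steps_per_t`` proposals the
    temperature drops by ``dt`` until it falls below ``t_final``.  The
    best-ever sequence is recorded; identical seeds give identical
    trajectories.
    """
    if seed is None:
        raise ValueError("samc requires an explicit seed")
    if schedule is None:
        schedule = AnnealSchedule()
    rng = np.random.default_rng(seed)
    ctx = model.delta_context(origin)
    free = _free_positions(model.L_, mask)
    cands = _candidate_indices(model, residues, allow_gaps)
    symbols = model.alphabet + GAP
    origin_ints = ctx.ints.copy()
    origin_score = ctx.score
    best_ints = ctx.ints.copy()
    best_score = ctx.score
    steps: list[TrajectoryStep] = []
    hd = 0
    proposal = 0
    for T in schedule.temperatures():
        for _ in range(schedule.steps_per_t):
            proposal += 1
            pos = free[rng.integers(len(free))]
            cur = int(ctx.ints[pos - 1])
            alts = [j for j in cands if j != cur]
            if not alts:
                continue
            j = alts[rng.integers(len(alts))]
            d = ctx.delta_idx(pos, j)
            if d < 0 and rng.random() >= np.exp(d / T):
                continue
            from_aa = symbols[cur]
            origin_aa = symbols[int(origin_ints[pos - 1])]
            ctx.apply_idx(pos, j)
            to_aa = symbols[j]
            hd += (to_aa != origin_aa) - (from_aa != origin_aa)
            steps.append(
                TrajectoryStep(proposal, float(T), pos, from_aa, to_aa, ctx.score, hd)
            )
            if ctx.score > best_score:
                best_score = ctx.score
                best_ints = ctx.ints.copy()
    final = _result_sequence(origin, ctx.ints, model, "samc")
    best = _result_sequence(origin, best_ints, model, "samc_best")
    return HumanizationTrajectory(
        origin=origin,
        method="SAMC",
        mask=mask,
        seed=seed,
        steps=steps,
        final=final,
        best=best,
        best_score=float(best_score),
        origin_score=origin_score,
        n_proposals=proposal,
    )


@dataclass
class TripleComparison:
    """Per-position agreement of a predicted humanization with an
    experimental one, relative to the original murine sequence.

    Over compared (non-CDR) positions with residues (o, h, p):
    o==h==p → TN; o==h≠p → FP; o≠h, p==o → FN; o≠h, p==h → TP;
    o≠h, p∉{o,h} → FP.  Hence HD(p,o) = TP+FP and HD(p,h) = FP+FN.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    tpr: float
    fpr: float
    youden: float
    hd_po: int
    hd_ho: int


def compare_to_reference(
    original: AlignedSequence | str,
    humanized: AlignedSequence | str,
    predicted: AlignedSequence | str,
    mask: CDRMask | None = None,
) -> TripleComparison:
    """Classify every compared position of the (original, humanized,
    predicted) triple and report TPR/FPR/Youden of the prediction."""
    ro = original.residues if isinstance(original, AlignedSequence) else original
    rh = humanized.residues if isinstance(humanized, AlignedSequence) else humanized
    rp = predicted.residues if isinstance(predicted, AlignedSequence) else predicted
    if not (len(ro) == len(rh) == len(rp)):
        raise ValueError("the three sequences must have equal length")
    fixed = set(mask.positions) if mask is not None else set()
    tp = fp = tn = fn = 0
    for i, (o, h, p) in enumerate(zip(ro, rh, rp), start=1):
        if i in fixed:
            continue
        if o == h:
            if p == o:
                tn += 1
            else:
                fp += 1
        else:
            if p == h:
                tp += 1
            elif p == o:
                fn += 1
            else:
                fp += 1
    tpr = tp / (tp + fn) if (tp + fn) > 0 else float("nan")
    fpr = fp / (tn + fp) if (tn + fp) > 0 else float("nan")
    return TripleComparison(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        tpr=tpr,
        fpr=fpr,
        youden=tpr - fpr,
        hd_po=tp + fp,
        hd_ho=tp + fn,
    )
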