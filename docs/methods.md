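# Methods

## Sequence representation

Sequences are pre-aligned, fixed-length strings over the 20 amino acids
plus `-` (gap).  Coordinates are 1-based AHo positions: a single variable
domain occupies 149 positions, a combined VH+VL pair 298 with the light
chain at 150–298.  The one-hot encoding maps position i, residue a to bit
Q(i−1)+index(a) of an N = QL vector; the residue ordering is the
alphabetical one-letter ordering `ACDEFGHIKLMNPQRSTVWY`, fixed and
serialized with every model.  A gap is an all-zero block: it is
representable but carries no bit, preserving N = 20L.  The Hamming
distance treats the gap as an ordinary 21st symbol (any gap/non-gap pair
is one mismatch).

CDR definitions (IMGT boundaries in AHo coordinates): VH 27–40, 58–68,
107–138; combined VHVL additionally 176–189, 207–217, 257–287; a
standalone VL uses the combined VL ranges shifted down by 149 (27–40,
58–68, 108–138).  These ranges total 57 positions for VH and 113 for VHVL.
A count of 111 fixed CDR positions (hence 187 mutable positions out of
298) also circulates for the same ranges; the discrepancy cannot be
resolved from the published boundaries, so the package implements the
printed ranges and documents both numbers.  The alphabet and the chain/L
pairing are configurable so that small-alphabet toy models (used by the
exactness oracles) run through exactly the same code paths.

## The humanness model

The one-hot encodings x of the M learning sequences are treated as draws
from a multivariate normal N(μ, Σ) with a Normal-Inverse-Wishart prior.
The model targets the posterior-predictive density directly:

    p(y|X) = t_N(ν, ⟨μ⟩, S)
    ν   = M/(1−λ) + 2
    ⟨μ⟩ = λη + (1−λ)x̄
    ⟨Σ⟩ = λU + (1−λ)C̄ + λ(1−λ)(x̄−η)(x̄−η)ᵀ
    S   = (1 + (1−λ)/M)⟨Σ⟩

with x̄ the empirical mean and C̄ the biased (1/M) empirical covariance —
the normalizer that makes the λ-mixture above an exact moment match.  The
underlying NIW hyperparameters κ, ν are not exposed separately: λ is the
single regularization knob.  The score is log p(y|X), a log-*density*
(routinely ≫ 0 in high dimension); its value at the mode y = ⟨μ⟩ is the
upper bound reported by `mode_score_`.

Prior moments (η, U) are the exact first and second central moments of a
sequence uniform over the **21** per-position states (20 amino acids + the
gap): η_i = 1/21; U is block diagonal with per-position blocks
(1/21)I − (1/441)J.  Including the gap state is what makes U strictly
positive definite (smallest eigenvalue 1/441): a uniform distribution over
the 20 amino acids alone has constant block sums and a singular
covariance, which would leave the density undefined.  Consequently the
scale matrix S is positive definite for every λ > 0 even when columns of
the alignment are perfectly conserved; λ = 0 is rejected rather than
pseudo-inverted.  λ = 1 is the exact prior endpoint and is scored as the
Gaussian N(η, U) (the ν → ∞ limit).

Numerics: S is Cholesky-factorized once per fit; scoring uses triangular
solves.  A dense inverse S⁻¹ is materialized only when single-mutation
deltas are requested (humanization): a point mutation changes at most two
bits of y, so with cached z = y − ⟨μ⟩ and S⁻¹z each candidate delta is a
rank-≤2 update of the Mahalanobis form, O(1) per candidate and O(N) per
accepted move.  Both paths agree to ≤1e−9 and are cross-checked in the
tests.  Learning sequences are brought into a canonical (lexicographic)
order before moment accumulation, so fits are bit-identical under any
permutation of the input ensemble.

Correlation ablations operate on the final ⟨Σ⟩: `all_off` zeroes every
cross-position block (leaving an independent-sites model — for one-hot
data the retained diagonal blocks encode exactly the site frequencies);
`interchain_off` zeroes only blocks coupling the two chains, splitting at
position 149 for VHVL models or at a caller-supplied boundary for
synthetic paired ensembles.  λ is deliberately left unchanged —
re-selection after ablation is the caller's decision (`select_lambda`
accepts an `ablation` argument).

## Classification and calibration

ROC curves sweep all distinct score values (higher-is-positive for the MG
score, lower-is-positive for distances); AUC is the trapezoid area.
Youden's index is implemented as sensitivity + specificity − 1 = TPR −
FPR.  A variant with TN/(TN+FN) as the second term appears in print; it
is available behind `youden_variant="printed"` but is not the default,
because the published worked examples are consistent with TPR − FPR and
not with the variant.  MCC with a zero denominator is defined as 0.
Threshold ties are broken toward classifying fewer positives
(conservative); λ-selection AUC ties toward the smaller λ (stronger
regularization).  λ selection requires an explicit validation split; the
test set is never reused silently.  The default grid (21 log-spaced values
in [0.005, 0.5]) brackets the weakly regularized optima typical when the
ensemble is an order of magnitude smaller than N.

The two-reference distance score is implemented as s(A) = d̄_m(A) −
d̄_h(A), so that positive values mean "closer to the human ensemble".
(The opposite algebraic sign is sometimes quoted together with the same
verbal interpretation; the interpretation wins here, and the convention is
recorded in output metadata.)  Exact two-reference ties are labeled
non-human — the conservative choice for humanization use.

## Humanization

E(y) = −log p(y|X) is minimized over the framework positions with CDR
positions frozen.

* **Steepest descent** evaluates all 19 (or 20 with `allow_gaps`)
  alternatives at every free position via the delta machinery and applies
  the strictly best improving mutation; it stops when no mutation
  improves.  Ties break to the lowest position, then the alphabetically
  first residue, making the walk fully deterministic.  The trajectory is
  itself the deliverable: a sequence of locally optimal humanizations at
  every mutation count.
* **SAMC** proposes a uniform free position and a uniform alternative
  residue, accepts with min(1, e^(ΔS/T)) (ΔS the score change), and cools
  linearly.  The shipped presets are `paper_preset` (T: 25.1 → 0.1,
  ΔT = 0.5, 3.74e6 proposals per stage — a cluster-scale budget of ~1.9e8
  proposals) and the default desk preset with 20 000 proposals per stage.
  One seeded generator drives the run; identical seeds give byte-identical
  trajectories, and the best-ever sequence is reported alongside the final
  one because low-temperature trapping can end off-optimum.

Gap proposals are off by default: introducing indels into a fixed
numbering frame is rarely wanted; `allow_gaps=True` enables them.  The
`residues` argument restricts the proposal alphabet (e.g. to exclude
unpaired cysteines).

The triple comparison classifies every non-CDR position of
(original, humanized, predicted) as TN (A,A,A), FP (A,A,B or A,B,C), FN
(A,B,A) or TP (A,B,B), with TPR = TP/(TP+FN), FPR = FP/(TN+FP) and
Youden = TPR − FPR; HD(p,o) = TP+FP and HD(p,h) = FP+FN by construction.

## Synthetic data

The generators exist so that every statistical claim is testable without
external antibody databases; they emulate alignment-column statistics, not
immunoglobulin biology (no germline structure, V(D)J recombination or
somatic hypermutation).

* `ProfileModel` — independent per-position categoricals over 21 states.
  `ProfileModel.random` draws Dirichlet(0.5) amino-acid profiles (sparse,
  moderately conserved columns, as framework positions show) with a fixed
  2% gap probability so gap code paths are exercised.
* `CoupledModel` — per-position fields plus pairwise log-coupling tables,
  sampled by single-site Gibbs sweeps (defaults: 100 sweeps burn-in, 10
  sweeps thinning).  Exactness is certified by enumeration at L = 2
  (chi-square against the closed-form Boltzmann distribution) and
  against closed-form marginals when no couplings are present.
* `make_species_pair` — the human/murine stand-in.  Both species share
  base fields N(0, 1.5) (a handful of preferred residues per column); a
  `divergence` fraction of positions gets N(0, 0.5) shifts in the murine
  model.  Couplings form a **matching** — each position participates in at
  most one pair, placed within each chain half and across the boundary
  when `cross_chain` — because a matching factorizes the coupled system
  into independent two-site subsystems, which single-site Gibbs samples
  correctly even at strong coupling (dense random coupling graphs at
  comparable strength are glassy: the chain cannot cross parity barriers,
  and what looks like species signal is then chain-initialization
  artifact).  Tables are rank-one spin products: each site assigns a
  random balanced ±1 class to its 20 letters, a coupled pair (i, j) gets
  J = strength·s_i s_jᵀ for the human model and −J for the murine model.
  Species identity therefore lives in *which letter-class combinations
  co-occur*, while site marginals coincide at divergence 0 — the regime in
  which covariance-aware scoring should, and does, dominate both its
  correlation-ablated variant and mean-distance baselines.

## Benchmark and test problem sizes

The classification benchmark (`humab.benchmarks`) uses L = 30 with 400
training, 200 validation and 200 test sequences per species, divergence
0.3 and coupling strength 3.0, λ selected on the validation split from
{0.02, 0.05, 0.1, 0.2}; each species' ensemble is one Gibbs chain split
into train/validation/test so all splits see the same stationary
distribution.  Optimizer oracles run on exhaustively enumerable landscapes
(4-letter alphabet, L = 3, one masked position: 16 free sequences), where
steepest descent is compared step-by-step with an independent
full-rescoring greedy walk and SAMC against the enumerated global optimum
and, at fixed temperature, against exact Boltzmann occupancies.  Density
exactness is checked against an independently implemented multivariate-t
log-pdf on models with N ≤ 12, and normalization by quadrature on an
L = 1, Q = 2 toy.  These sizes are chosen so the whole suite and the
acceptance script each complete in well under a minute while every check
retains its statistical power.

## Known limitations

* Scoring a full VHVL model (N = 5960) materializes dense N×N matrices
  (~280 MB each); fitting and scoring are fine on a workstation, but the
  delta machinery additionally materializes S⁻¹, so humanization at full
  scale wants ~1 GB of memory.
* The model is a density over relaxed (real-valued) encodings; scores of
  discrete sequences are comparable with each other but are not
  probabilities, and the normalization constant depends on λ and M, so
  scores from differently fitted models are not directly comparable.
* Whether the published score ceiling refers to the density at the mode or
  to a maximum over valid one-hot vectors is ambiguous; `mode_score_`
  implements the mode bound, which dominates both.
* The synthetic species pair makes correlation structure the dominant
  species signal by construction; real human/murine ensembles mix marginal
  and correlation signal in unknown proportion, so benchmark AUCs
  characterize the implementation, not biology.
* Humanization optimizes sequence statistics only: stability, solubility,
  expression and immunogenicity of proposals are explicitly out of scope.
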