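"""Synthetic ground truths, the maximum-entropy noise model, and edge metrics.

Evaluation uses symmetric ground-truth networks G (tractography cannot see
fiber polarity) whose observed streamline fractions are corrupted by two
independent noise sources with support [0, 1]:

    T(i,j) = 1 − Z1   if i and j are connected      (miss-direction noise)
    T(i,j) = Z2       otherwise                      (spurious signal)

Z1 and Z2 follow the maximum-entropy distribution with a mean constraint on
[0, 1] — the truncated exponential f(ζ) = α e^{−αζ} / (1 − e^{−α}) — whose
mean is

    μ(α) = [1 − (1+α) e^{−α}] / [α (1 − e^{−α})],   μ ∈ (0, 1/2) for α > 0.

Noise intensity is parameterized by the means μ1, μ2 rather than by α.  Each
simulated ROI is a single voxel, so the corrupted T is itself a strength
matrix.  The module also provides the binary-classification metrics (Jaccard
similarity, false-positive/negative rates) and the oracle that knows the
Jaccard-optimal threshold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .errors import ValidationError
from .inference import StrengthMatrix, _candidate_taus
from .network import DirectedNetwork

__all__ = [
    "NoiseModel",
    "OptimalThresholdResult",
    "generate_ground_truth",
    "random_directed_network",
    "mu_from_alpha",
    "alpha_from_mu",
    "sample_noise",
    "corrupt",
    "jaccard",
    "error_rates",
    "optimal_threshold",
]


def mu_from_alpha(alpha: float) -> float:
    """Mean of the truncated exponential on [0, 1] with rate α > 0.

    Decreases from 1/2 (α→0, uniform limit) to 0 (α→∞).  Evaluated with
    ``expm1`` to stay accurate for small α.
    """
    if alpha <= 0:
        raise ValidationError(f"alpha must be positive, got {alpha}")
    if alpha < 1e-6:
        # series expansion: mu = 1/2 - alpha/12 + O(alpha^3)
        return 0.5 - alpha / 12.0
    em = -math.expm1(-alpha)  # 1 - e^{-alpha}
    numerator = em - alpha * math.exp(-alpha)
    return numerator / (alpha * em)


def alpha_from_mu(mu: float) -> float:
    """Invert μ(α) by bracketed root finding; residual below 1e−10.

    Only μ ∈ (0, 1/2) is reachable: μ→1/2 as α→0 and μ→0 as α→∞.
    """
    if not 0.0 < mu < 0.5:
        raise ValidationError(
            f"mu must lie in (0, 0.5); no finite alpha gives {mu}"
        )
    lo, hi = 1e-9, max(10.0, 4.0 / mu)
    while mu_from_alpha(hi) > mu:  # pragma: no cover - tiny mu safety net
        hi *= 4.0
    alpha = brentq(lambda a: mu_from_alpha(a) - mu, lo, hi, xtol=1e-13, rtol=1e-15)
    return float(alpha)


@dataclass(frozen=True)
class NoiseModel:
    """Truncated-exponential corruption with means μ1 (misses), μ2 (spurious).

    μ1 governs how much signal is lost on true connections (T = 1 − Z1);
    μ2 how much spurious signal appears on non-connections (T = Z2).
    Both must lie in (0, 1/2); beyond ~0.3 the distribution is nearly uniform
    and inference is hopeless.
    """

    mu1: float
    mu2: float
    alpha1: float = field(init=False)
    alpha2: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "alpha1", alpha_from_mu(self.mu1))
        object.__setattr__(self, "alpha2", alpha_from_mu(self.mu2))


def sample_noise(
    model: NoiseModel, which: int, count: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw i.i.d. truncated-exponential noise (which=1 → Z1, 2 → Z2).

    Inverse-CDF sampling: ζ = −ln(1 − u(1 − e^{−α})) / α for u ~ U(0,1).
    """
    if which not in (1, 2):
        raise ValidationError(f"which must be 1 or 2, got {which}")
    if count < 1:
        raise ValidationError("count must be positive")
    alpha = model.alpha1 if which == 1 else model.alpha2
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    u = rng.random(count)
    return -np.log1p(-u * -np.expm1(-alpha)) / alpha


def generate_ground_truth(n: int, rho: float, seed: int | np.random.Generator) -> DirectedNetwork:
    """Symmetric ground truth with round(ρ·n(n−1)/2) undirected edges.

    Edges are placed on distinct unordered pairs sampled uniformly without
    replacement; half-integer edge counts round up.
    """
    if n < 2:
        raise ValidationError("need at least 2 nodes")
    if not 0.0 < rho < 1.0:
        raise ValidationError(f"rho must lie in (0, 1), got {rho}")
    total_pairs = n * (n - 1) // 2
    n_edges = math.floor(rho * total_pairs + 0.5)
    if n_edges > total_pairs:
        raise ValidationError(
            f"{n_edges} edges requested but only {total_pairs} pairs exist"
        )
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    chosen = rng.choice(total_pairs, size=n_edges, replace=False)
    iu = np.triu_indices(n, k=1)
    adj = np.zeros((n, n), dtype=np.int8)
    adj[iu[0][chosen], iu[1][chosen]] = 1
    adj |= adj.T
    return DirectedNetwork(adj)


def random_directed_network(
    n: int, rho: float, seed: int | np.random.Generator
) -> DirectedNetwork:
    """Random directed network with exactly ⌊n(n−1)ρ⌋ distinct ordered pairs.

    This is the construction under which the expected asymmetry is 1−ρ.
    """
    if n < 2:
        raise ValidationError("need at least 2 nodes")
    if not 0.0 < rho < 1.0:
        raise ValidationError(f"rho must lie in (0, 1), got {rho}")
    total = n * (n - 1)
    k = int(math.floor(total * rho))
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    chosen = rng.choice(total, size=k, replace=False)
    off = np.nonzero(~np.eye(n, dtype=bool))
    adj = np.zeros((n, n), dtype=np.int8)
    adj[off[0][chosen], off[1][chosen]] = 1
    return DirectedNetwork(adj)


def corrupt(
    g: DirectedNetwork, model: NoiseModel, seed: int | np.random.Generator
) -> StrengthMatrix:
    """Corrupt a symmetric ground truth into noisy streamline fractions.

    Every ordered pair receives an independent draw, so T(i,j) and T(j,i)
    generally differ even though G is symmetric.  Each simulated ROI is a
    single voxel, so the result is directly a strength matrix.
    """
    if not g.is_symmetric:
        raise ValidationError("ground truth must be symmetric")
    n = g.n_nodes
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    off = ~np.eye(n, dtype=bool)
    connected = g.adjacency.astype(bool)
    t = np.zeros((n, n))
    n_conn = int((connected & off).sum())
    n_abs = int((~connected & off).sum())
    if n_conn:
        t[connected & off] = 1.0 - sample_noise(model, 1, n_conn, rng)
    if n_abs:
        t[~connected & off] = sample_noise(model, 2, n_abs, rng)
    return StrengthMatrix(t, provenance="synthetic")


def jaccard(g: DirectedNetwork, g_hat: DirectedNetwork) -> float:
    """Edge-set Jaccard similarity over directed edges.

    Undirected networks participate through their reciprocal directed pairs.
    Two empty networks return 1 by convention, with a warning.
    """
    if g.n_nodes != g_hat.n_nodes:
        raise ValidationError("networks must share the node set")
    a, b = g.adjacency.astype(bool), g_hat.adjacency.astype(bool)
    union = int((a | b).sum())
    if union == 0:
        warnings.warn("Jaccard of two empty networks; returning 1 by convention")
        return 1.0
    return float((a & b).sum() / union)


def error_rates(g: DirectedNetwork, g_hat: DirectedNetwork) -> tuple[float, float]:
    """(false-positive rate, false-negative rate) over ordered node pairs.

    p_f = FP / (pairs absent in G); p_m = FN / (pairs present in G).  NaN when
    the corresponding denominator is zero (G complete resp. empty).
    """
    if g.n_nodes != g_hat.n_nodes:
        raise ValidationError("networks must share the node set")
    n = g.n_nodes
    off = ~np.eye(n, dtype=bool)
    truth = g.adjacency.astype(bool)
    pred = g_hat.adjacency.astype(bool)
    present = int((truth & off).sum())
    absent = int((~truth & off).sum())
    fp = int((pred & ~truth & off).sum())
    fn = int((~pred & truth & off).sum())
    p_f = fp / absent if absent else math.nan
    p_m = fn / present if present else math.nan
    return p_f, p_m


@dataclass(frozen=True)
class OptimalThresholdResult:
    """Jaccard-maximizing threshold(s) for a known ground truth.

    ``intervals`` lists every maximal open τ interval achieving the optimum;
    ``tau`` is the midpoint of the widest such interval.
    """

    tau: float
    jaccard: float
    intervals: tuple[tuple[float, float], ...]


def _pair_cutoffs(s: StrengthMatrix) -> np.ndarray:
    """Per unordered pair, the τ below which the post-symmetrized edge exists.

    With a = max(S_ij, S_ji) and b = min: the pair is reciprocated for τ < b;
    for b < τ < a it survives the confidence-ratio rule iff
    τ (1 + b − a) < b; for τ > a it is absent.  Presence is therefore
    monotone in τ with cutoff min(a, b / (1 + b − a)) (which is ≥ b), the
    degenerate a = 1, b = 0 tie resolving to absent.
    Returns the n×n symmetric cutoff matrix.
    """
    a = np.maximum(s.values, s.values.T)
    b = np.minimum(s.values, s.values.T)
    denom = 1.0 + b - a
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(denom > 0, b / np.where(denom > 0, denom, 1.0), b)
    cut = np.minimum(a, ratio)
    np.fill_diagonal(cut, 0.0)
    return cut


def optimal_threshold(
    s: StrengthMatrix,
    g: DirectedNetwork,
    post_symmetrize_result: bool = False,
) -> OptimalThresholdResult:
    """Oracle: maximize Jaccard similarity to a known ground truth over τ.

    Synthetic-evaluation use only.  With ``post_symmetrize_result`` the
    Jaccard is that of the post-symmetrized network at each τ (the network
    then changes at the per-pair confidence cutoffs, not only at strength
    values).  All maximal optimal intervals are reported.
    """
    if g.n_nodes != s.n_rois:
        raise ValidationError("strength matrix and ground truth disagree on size")
    n = s.n_rois
    truth = g.adjacency.astype(bool)
    n_true = int(truth.sum())

    if post_symmetrize_result:
        # the post-symmetrized network at τ contains pair {i,j} iff
        # cutoff(i,j) > τ; breakpoints are the distinct cutoffs
        iu = np.triu_indices(n, k=1)
        cut = _pair_cutoffs(s)[iu]
        true_pair = (truth | truth.T)[iu]  # g symmetric; defensive union
        distinct = np.unique(cut[cut > 0.0])
        bounds = np.concatenate([[0.0], distinct, [1.0]])
        widths = np.diff(bounds)
        keep = widths > 0
        taus = ((bounds[:-1] + bounds[1:]) / 2.0)[keep]
        lows, highs = bounds[:-1][keep], bounds[1:][keep]
        cut_sorted = np.sort(cut)
        cut_true_sorted = np.sort(cut[true_pair])
        pairs_in = cut_sorted.size - np.searchsorted(cut_sorted, taus, "right")
        tp_pairs = cut_true_sorted.size - np.searchsorted(cut_true_sorted, taus, "right")
        tp = 2 * tp_pairs
        k = 2 * pairs_in
    else:
        taus = _candidate_taus(s)
        off = ~np.eye(n, dtype=bool)
        vals_sorted = np.sort(s.values[off])
        true_sorted = np.sort(s.values[truth & off])
        k = vals_sorted.size - np.searchsorted(vals_sorted, taus, "right")
        tp = true_sorted.size - np.searchsorted(true_sorted, taus, "right")
        # interval bounds around each candidate tau
        positive = np.unique(s.values[off][s.values[off] > 0.0])
        bounds = np.concatenate([[0.0], positive, [1.0]])
        widths = np.diff(bounds)
        lows, highs = bounds[:-1][widths > 0], bounds[1:][widths > 0]

    union = n_true + k - tp
    with np.errstate(divide="ignore", invalid="ignore"):
        j = np.where(union > 0, tp / np.where(union > 0, union, 1), 1.0)

    j_best = float(j.max())
    best = np.nonzero(j >= j_best - 1e-15)[0]
    # merge adjacent optimal intervals
    intervals: list[tuple[float, float]] = []
    for idx in best:
        lo, hi = float(lows[idx]), float(highs[idx])
        if intervals and math.isclose(intervals[-1][1], lo):
            intervals[-1] = (intervals[-1][0], hi)
        else:
            intervals.append((lo, hi))
    widest = max(intervals, key=lambda ab: ab[1] - ab[0])
    return OptimalThresholdResult(
        tau=(widest[0] + widest[1]) / 2.0,
        jaccard=j_best,
        intervals=tuple(intervals),
    )
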