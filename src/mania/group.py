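"""Group-level inference by Kemeny rank aggregation of per-subject edge ranks.

Each subject m contributes a total order R_m over the same universe of
N(N−1) directed edges, ranked by first-appearance density (most confident
first).  The consensus ordering R̂ approximately minimizes the cumulative
Kemeny distance — the number of pairwise disagreements — to all R_m, using
the randomized QuickSort heuristic: at each recursive step a random pivot
edge splits the remainder into those ranked before it by a strict majority
of subjects and the rest.

The consensus network is then selected exactly as in single-subject MANIA,
but over edge counts instead of thresholds: the top-K prefix of R̂ is scored
by normalized asymmetry for every K, and the K minimizing Φ wins (largest K
on ties).  No strengths exist at group level, so post-symmetrization is not
applicable and asymmetric optima are returned as-is.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .confidence import rank_edges
from .errors import ValidationError
from .inference import StrengthMatrix
from .network import DirectedNetwork, ScanCurve, ScanRecord

__all__ = [
    "RankProfile",
    "GroupResult",
    "edge_universe",
    "rank_vector_from_strengths",
    "kemeny_distance",
    "quicksort_aggregate",
    "group_infer",
    "edge_frequency",
]


def edge_universe(n: int) -> list[tuple[int, int]]:
    """Canonical enumeration of all N(N−1) directed edges."""
    return [(i, j) for i in range(n) for j in range(n) if i != j]


@dataclass(frozen=True)
class RankProfile:
    """M subject rank vectors over a shared directed-edge universe.

    ``rankings[m]`` lists edge ids (indices into :func:`edge_universe`) from
    most to least confident for subject m.
    """

    n_nodes: int
    rankings: tuple[np.ndarray, ...]
    subject_ids: tuple[str, ...] | None = None
    roi_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.rankings) < 1:
            raise ValidationError("need at least one subject")
        e = self.n_nodes * (self.n_nodes - 1)
        universe = np.arange(e)
        cleaned = []
        for m, r in enumerate(self.rankings):
            r = np.asarray(r, dtype=np.int64)
            if r.shape != (e,) or not np.array_equal(np.sort(r), universe):
                raise ValidationError(
                    f"subject {m}: ranking is not a permutation of the "
                    f"{e}-edge universe"
                )
            cleaned.append(r)
        object.__setattr__(self, "rankings", tuple(cleaned))

    @property
    def n_subjects(self) -> int:
        return len(self.rankings)

    @property
    def n_edges(self) -> int:
        return self.n_nodes * (self.n_nodes - 1)


@dataclass(frozen=True)
class GroupResult:
    """Consensus network, its selected edge count K*, and the Φ(K) scan."""

    network: DirectedNetwork
    aggregate_ranking: np.ndarray
    k_star: int
    rho_star: float
    phi_min: float
    scan: ScanCurve


def rank_vector_from_strengths(s: StrengthMatrix) -> np.ndarray:
    """One subject's edge rank vector from a strength matrix.

    Edges are ordered by first-appearance density; ties within a ρ_α class
    are broken by ROI-label lexicographic order (index order when unlabeled)
    so the result is a strict permutation, as Kemeny comparison requires.
    """
    n = s.n_rois
    universe = edge_universe(n)
    index_of = {e: k for k, e in enumerate(universe)}
    labels = s.roi_labels

    def key(pair: tuple[int, int]):
        i, j = pair
        if labels is not None:
            return (-s.values[i, j], labels[i], labels[j])
        return (-s.values[i, j], i, j)

    ordered = sorted(universe, key=key)
    return np.array([index_of[e] for e in ordered], dtype=np.int64)


def _count_inversions(seq: np.ndarray) -> int:
    """Merge-sort inversion count."""
    seq = np.asarray(seq, dtype=np.int64)

    def rec(a: np.ndarray) -> tuple[np.ndarray, int]:
        if a.size <= 1:
            return a, 0
        mid = a.size // 2
        left, nl = rec(a[:mid])
        right, nr = rec(a[mid:])
        # inversions across the split: for each right element, how many
        # left elements exceed it
        cross = int(np.sum(left.size - np.searchsorted(left, right, side="right")))
        merged = np.sort(np.concatenate([left, right]))  # already sorted halves
        return merged, nl + nr + cross

    return rec(seq)[1]


def kemeny_distance(r1: np.ndarray, r2: np.ndarray) -> int:
    """Number of edge pairs the two rankings order oppositely."""
    r1 = np.asarray(r1, dtype=np.int64)
    r2 = np.asarray(r2, dtype=np.int64)
    if r1.shape != r2.shape or not np.array_equal(np.sort(r1), np.sort(r2)):
        raise ValidationError("rank vectors must permute the same edge universe")
    pos2 = np.empty(r2.size, dtype=np.int64)
    pos2[r2] = np.arange(r2.size)
    return _count_inversions(pos2[r1])


def quicksort_aggregate(profile: RankProfile, seed: int = 0) -> np.ndarray:
    """Randomized-pivot QuickSort consensus of the subjects' rankings.

    At each step a random pivot edge is drawn; an edge goes to the left list
    when a *strict* majority of subjects rank it before the pivot, otherwise
    (including exact ties) to the right list.  Recursion proceeds until all
    edges are ordered.  The pivot sequence is fully determined by ``seed``.
    """
    m = profile.n_subjects
    e = profile.n_edges
    pos = np.empty((m, e), dtype=np.int64)
    for s_idx, r in enumerate(profile.rankings):
        pos[s_idx, r] = np.arange(e)

    rng = np.random.default_rng(seed)
    out: list[np.ndarray] = []
    stack: list[np.ndarray] = [np.arange(e, dtype=np.int64)]
    while stack:
        seg = stack.pop()
        if seg.size <= 1:
            if seg.size:
                out.append(seg)
            continue
        pivot = seg[rng.integers(seg.size)]
        rest = seg[seg != pivot]
        before = (pos[:, rest] < pos[:, pivot][:, None]).sum(axis=0)
        left_mask = 2 * before > m
        # push right, pivot, left so they pop in left→pivot→right order
        stack.append(rest[~left_mask])
        stack.append(np.array([pivot], dtype=np.int64))
        stack.append(rest[left_mask])
    return np.concatenate(out)


def group_infer(profile: RankProfile, seed: int = 0) -> GroupResult:
    """Select the minimum-normalized-asymmetry prefix of the consensus ranking.

    For K = 1 … N(N−1)−1 the network of the top-K aggregated edges is scored
    by Φ; the smallest Φ wins, with the largest K on ties (mirroring the
    largest-density tie-breaker of single-subject inference).
    """
    agg = quicksort_aggregate(profile, seed)
    n = profile.n_nodes
    e = profile.n_edges
    universe = edge_universe(n)

    # position of each edge and of its reverse in the aggregate order
    pos = np.empty(e, dtype=np.int64)
    pos[agg] = np.arange(e)
    def eid_of(i: int, j: int) -> int:
        return i * (n - 1) + (j if j < i else j - 1)

    rev = np.array([eid_of(j, i) for (i, j) in universe], dtype=np.int64)
    # an unordered pair becomes reciprocated once both directions are in the
    # prefix, i.e. at K = max(pos, pos[rev]) + 1; count each pair once
    pair_done = np.maximum(pos, pos[rev])
    first_dir = pos < pos[rev]
    done_at = np.sort(pair_done[first_dir] + 1)

    ks = np.arange(1, e)  # K = e has density 1, ineligible
    reciprocated_pairs = np.searchsorted(done_at, ks, side="right")
    unrec = ks - 2 * reciprocated_pairs
    rho = ks / e
    phi = unrec / ks
    phi_norm = phi / (1.0 - rho)

    records = tuple(
        ScanRecord(
            tau=float("nan"),
            rho=float(r),
            phi=float(p),
            phi_norm=float(pn),
            edge_count=int(k),
            eligible=True,
        )
        for k, r, p, pn in zip(ks, rho, phi, phi_norm)
    )
    scan = ScanCurve(records, provenance="group-aggregate")

    phi_min = phi_norm.min()
    from .inference import PHI_TIE_TOL

    tied = np.nonzero(phi_norm - phi_min <= PHI_TIE_TOL)[0]
    k_star = int(ks[tied[-1]])  # ties → largest K (ks is increasing)

    adj = np.zeros((n, n), dtype=np.int8)
    for eid in agg[:k_star]:
        i, j = universe[eid]
        adj[i, j] = 1
    net = DirectedNetwork(adj, profile.roi_labels)
    return GroupResult(
        network=net,
        aggregate_ranking=agg,
        k_star=k_star,
        rho_star=float(k_star / e),
        phi_min=float(phi_norm[tied[-1]]),
        scan=scan,
    )


def edge_frequency(per_subject_networks: Sequence[DirectedNetwork]) -> np.ndarray:
    """Fraction of subjects whose individual network contains each edge."""
    if not per_subject_networks:
        raise ValidationError("need at least one network")
    n = per_subject_networks[0].n_nodes
    labels = per_subject_networks[0].node_labels
    acc = np.zeros((n, n))
    for net in per_subject_networks:
        if net.n_nodes != n or net.node_labels != labels:
            raise ValidationError("all networks must share the same node set")
        acc += net.adjacency
    return acc / len(per_subject_networks)
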