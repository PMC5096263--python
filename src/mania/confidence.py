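"""Edge ranking by first-appearance density and the derived confidence metric.

As the connectivity threshold is lowered, each directed edge α first enters
the network at a specific density ρ_α (its rank among all strengths divided by
the number of ordered pairs).  Edges that appear earlier — at lower ρ_α — are
more confidently present.  Relative to the density ρ* selected by MANIA:

* present edges (ρ_α < ρ*):  C(α) = (ρ* − ρ_α) / ρ*        ∈ (0, 1]
* absent edges  (ρ_α > ρ*):  C(α) = (ρ* − ρ_α) / (1 − ρ*)  ∈ [−1, 0)
* marginal edges (ρ_α = ρ*): C(α) = 0

and a node pair's confidence is the arithmetic mean of its two directed
edges' confidences.  C is a confidence of presence/absence, not a connection
strength.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .inference import StrengthMatrix

__all__ = ["EdgeRanking", "ConfidenceReport", "rank_edges", "edge_confidence"]


@dataclass(frozen=True)
class EdgeRanking:
    """All N(N−1) directed edges ordered by decreasing strength.

    ``edges[r]`` is the (source, target) index pair at rank r (best first),
    ``strengths[r]`` its strength and ``rho_alpha[r]`` its first-appearance
    density.  Equal-strength edges enter the network together, so every member
    of a tie class shares the density at which the whole class has appeared.
    """

    edges: tuple[tuple[int, int], ...]
    strengths: np.ndarray
    rho_alpha: np.ndarray
    roi_labels: tuple[str, ...] | None = None

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def rho_of(self, source: int, target: int) -> float:
        for e, r in zip(self.edges, self.rho_alpha):
            if e == (source, target):
                return float(r)
        raise KeyError((source, target))


@dataclass(frozen=True)
class ConfidenceReport:
    """Per-edge and per-pair confidences at a given MANIA density ρ*."""

    ranking: EdgeRanking
    rho_star: float
    edge_conf: np.ndarray          # aligned with ranking.edges
    pair_conf: dict[tuple[int, int], float]  # keyed by (min, max) node index

    def confidence_of(self, source: int, target: int) -> float:
        for e, c in zip(self.ranking.edges, self.edge_conf):
            if e == (source, target):
                return float(c)
        raise KeyError((source, target))

    def to_edge_csv(self, path: str | Path) -> None:
        """`source,target,strength,rho_alpha,confidence` rows, rank order."""
        labels = self.ranking.roi_labels
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["source", "target", "strength", "rho_alpha", "confidence"])
            for (i, j), s, r, c in zip(
                self.ranking.edges,
                self.ranking.strengths,
                self.ranking.rho_alpha,
                self.edge_conf,
            ):
                src = labels[i] if labels else str(i)
                tgt = labels[j] if labels else str(j)
                w.writerow([src, tgt, f"{s:.12g}", f"{r:.12g}", f"{c:.12g}"])

    def to_pair_csv(self, path: str | Path) -> None:
        """`roi_a,roi_b,pair_confidence` rows sorted by descending confidence."""
        labels = self.ranking.roi_labels
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["roi_a", "roi_b", "pair_confidence"])
            for (i, j), c in sorted(
                self.pair_conf.items(), key=lambda kv: -kv[1]
            ):
                a = labels[i] if labels else str(i)
                b = labels[j] if labels else str(j)
                w.writerow([a, b, f"{c:.12g}"])


def rank_edges(s: StrengthMatrix) -> EdgeRanking:
    """Order all directed edges by descending strength and assign ρ_α.

    ρ_α = (number of edges with strength ≥ strength(α)) / N(N−1); tied edges
    all receive the density at which their whole tie class has entered.
    Zero-strength edges never truly appear and sit at ρ_α = 1 in the last tie
    class.  Deterministic within ties: sorted by (source, target) index.
    """
    n = s.n_rois
    total = n * (n - 1)
    pairs = [(i, j) for i in range(n) for j in range(n) if i != j]
    pairs.sort(key=lambda p: (-s.values[p[0], p[1]], p[0], p[1]))
    strengths = np.array([s.values[i, j] for i, j in pairs])
    # tie class shares the rank of its last member
    rho = np.empty(total)
    r = 0
    while r < total:
        q = r
        while q + 1 < total and strengths[q + 1] == strengths[r]:
            q += 1
        rho[r : q + 1] = (q + 1) / total
        r = q + 1
    return EdgeRanking(tuple(pairs), strengths, rho, s.roi_labels)


def edge_confidence(ranking: EdgeRanking, rho_star: float) -> ConfidenceReport:
    """Score every directed edge and node pair against the MANIA density ρ*."""
    if not 0.0 < rho_star < 1.0:
        raise ValidationError(f"rho_star must lie in (0, 1), got {rho_star}")
    rho = ranking.rho_alpha
    conf = np.where(
        rho < rho_star,
        (rho_star - rho) / rho_star,
        (rho_star - rho) / (1.0 - rho_star),
    )
    conf[rho == rho_star] = 0.0
    by_edge = {e: c for e, c in zip(ranking.edges, conf)}
    pair_conf: dict[tuple[int, int], float] = {}
    for (i, j), c in by_edge.items():
        key = (min(i, j), max(i, j))
        if key not in pair_conf:
            pair_conf[key] = (c + by_edge[(j, i)]) / 2.0
    return ConfidenceReport(ranking, rho_star, conf, pair_conf)
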