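"""Binary directed networks and their asymmetry/density metrics.

A tractography-derived network between ``N`` regions of interest (ROIs) is an
unweighted directed graph without self-loops.  Because diffusion imaging cannot
resolve fiber polarity, a perfectly reconstructed network must be symmetric:
every true anatomical connection should be traceable in both directions.  The
*asymmetry* of a directed network — the fraction of its edges present in only
one direction — therefore measures reconstruction error, once it is normalized
by the asymmetry expected by chance at the same edge density.

This module provides the :class:`DirectedNetwork` container, the three metrics

* ``density``              ρ(G)  = K / [N(N−1)]
* ``asymmetry``            ϕ(G)  = (# unreciprocated edges) / K
* ``normalized_asymmetry`` Φ(G)  = ϕ(G) / (1 − ρ(G))

and the :class:`ScanCurve` record of how these metrics evolve as the
connectivity threshold is swept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .errors import UndefinedMetricError, ValidationError

__all__ = [
    "DirectedNetwork",
    "ScanCurve",
    "ScanRecord",
    "density",
    "asymmetry",
    "expected_random_asymmetry",
    "normalized_asymmetry",
    "write_edge_list",
    "write_adjacency",
]


@dataclass(frozen=True)
class DirectedNetwork:
    """An unweighted directed graph over ROIs, stored as a dense 0/1 matrix.

    Self-loops are structurally forbidden: the diagonal is forced to zero at
    construction.  ``node_labels`` optionally names the ROIs.
    """

    adjacency: np.ndarray
    node_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency)
        if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
            raise ValidationError(f"adjacency must be square, got shape {adj.shape}")
        if adj.shape[0] < 2:
            raise ValidationError("a network needs at least 2 nodes")
        vals = np.unique(adj)
        if not np.isin(vals, (0, 1)).all():
            raise ValidationError("adjacency entries must be 0 or 1")
        adj = adj.astype(np.int8, copy=True)
        np.fill_diagonal(adj, 0)
        adj.setflags(write=False)
        object.__setattr__(self, "adjacency", adj)
        if self.node_labels is not None:
            labels = tuple(str(x) for x in self.node_labels)
            if len(labels) != adj.shape[0]:
                raise ValidationError(
                    f"{len(labels)} labels for {adj.shape[0]} nodes"
                )
            object.__setattr__(self, "node_labels", labels)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum())

    @property
    def density(self) -> float:
        return density(self)

    @property
    def asymmetry(self) -> float:
        return asymmetry(self)

    @property
    def normalized_asymmetry(self) -> float:
        return normalized_asymmetry(self)

    @property
    def is_symmetric(self) -> bool:
        return bool((self.adjacency == self.adjacency.T).all())

    def edges(self) -> list[tuple[int, int]]:
        """Directed edges as (source, target) index pairs."""
        rows, cols = np.nonzero(self.adjacency)
        return list(zip(rows.tolist(), cols.tolist()))

    def label_of(self, i: int) -> str:
        if self.node_labels is not None:
            return self.node_labels[i]
        return str(i)

    def symmetrized_union(self) -> "DirectedNetwork":
        """Undirected closure: connect i~j when either direction is present."""
        adj = self.adjacency | self.adjacency.T
        return DirectedNetwork(adj, self.node_labels)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DirectedNetwork):
            return NotImplemented
        return bool((self.adjacency == other.adjacency).all())

    def __hash__(self) -> int:
        return hash(self.adjacency.tobytes())


def density(net: DirectedNetwork) -> float:
    """Fraction of ordered node pairs that are connected, K / [N(N−1)]."""
    n = net.n_nodes
    if n < 2:
        raise ValidationError("density undefined for fewer than 2 nodes")
    return net.n_edges / (n * (n - 1))


def asymmetry(net: DirectedNetwork) -> float:
    """Fraction of edges present in only one direction.

    Undefined (0/0) for an edgeless network; callers scanning thresholds must
    exclude the empty network before evaluating this.
    """
    a = net.adjacency
    k = a.sum()
    if k == 0:
        raise UndefinedMetricError("asymmetry undefined for an edgeless network")
    unreciprocated = (a & (1 - a.T)).sum()
    return float(unreciprocated / k)


def expected_random_asymmetry(rho: float) -> float:
    """Expected asymmetry 1−ρ of a random directed network of density ρ.

    A random network with K = N(N−1)ρ directed edges placed on distinct
    ordered pairs has on average K(1−ρ) unreciprocated edges.
    """
    if not 0.0 < rho < 1.0:
        raise ValidationError(f"rho must lie in (0, 1), got {rho}")
    return 1.0 - rho


def normalized_asymmetry(net: DirectedNetwork) -> float:
    """Observed asymmetry divided by the chance level at the same density."""
    rho = density(net)
    if rho == 0.0 or rho == 1.0:
        raise UndefinedMetricError(
            f"normalized asymmetry undefined at density {rho}"
        )
    return asymmetry(net) / (1.0 - rho)


@dataclass(frozen=True)
class ScanRecord:
    """Metrics of the network obtained at one representative threshold.

    ``phi`` and ``phi_norm`` are NaN for ineligible records (density 0 or 1),
    which are kept in the curve but excluded from optimization.
    """

    tau: float
    rho: float
    phi: float
    phi_norm: float
    edge_count: int
    eligible: bool


@dataclass(frozen=True)
class ScanCurve:
    """The (τ, ρ, ϕ, Φ) trajectory over every threshold where the network changes.

    Records are ordered by increasing τ, so density is non-increasing along
    the curve.  ``provenance`` names the strength matrix that produced it.
    """

    records: tuple[ScanRecord, ...]
    provenance: str = ""

    def __iter__(self) -> Iterator[ScanRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def eligible(self) -> tuple[ScanRecord, ...]:
        return tuple(r for r in self.records if r.eligible)

    def as_arrays(self) -> dict[str, np.ndarray]:
        return {
            "tau": np.array([r.tau for r in self.records]),
            "rho": np.array([r.rho for r in self.records]),
            "phi": np.array([r.phi for r in self.records]),
            "phi_norm": np.array([r.phi_norm for r in self.records]),
            "edge_count": np.array([r.edge_count for r in self.records]),
            "eligible": np.array([r.eligible for r in self.records]),
        }


def write_edge_list(net: DirectedNetwork, path: str | Path) -> None:
    """Write directed edges as a two-column CSV with header ``source,target``."""
    lines = ["source,target"]
    for i, k in net.edges():
        lines.append(f"{net.label_of(i)},{net.label_of(k)}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_adjacency(net: DirectedNetwork, path: str | Path) -> None:
    """Write the adjacency matrix as TSV with labeled rows and columns."""
    labels = [net.label_of(i) for i in range(net.n_nodes)]
    lines = ["\t".join([""] + labels)]
    for i, row in enumerate(net.adjacency):
        lines.append("\t".join([labels[i]] + [str(int(v)) for v in row]))
    Path(path).write_text("\n".join(lines) + "\n")
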