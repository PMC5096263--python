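"""MANIA: minimum-asymmetry network inference from tractography strengths.

The input is either a set of per-ROI voxel-to-ROI streamline-fraction matrices
(:class:`TractogramSet`) or the :class:`StrengthMatrix` they reduce to, where
the strength of the directed pair (i, k) is the *maximum* streamline fraction
over the seed voxels of ROI i — a directed edge exists at threshold τ exactly
when at least one seed voxel exceeds τ.

Given the strength matrix S, sweeping τ across (0, 1) produces a finite family
of nested directed networks (the network only changes when τ crosses a
distinct strength value).  MANIA selects

    τ* = argmin over τ of Φ(G_τ),   Φ = ϕ / (1 − ρ),

the threshold whose network has the smallest density-normalized asymmetry;
ties are broken toward the *largest* density, which avoids trivially sparse
solutions.  If the winning network is not fully symmetric it can be
post-symmetrized: each one-directional pair keeps an undirected edge only when
the confidence that the edge exists, (S_ij − τ)/(1 − τ), exceeds the
confidence that it does not, (τ − S_ji)/τ.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DegenerateInputError, NoSignalError, ValidationError
from .network import DirectedNetwork, ScanCurve, ScanRecord

__all__ = [
    "TractogramSet",
    "StrengthMatrix",
    "ManiaResult",
    "PHI_TIE_TOL",
    "strengths_from_tractogram",
    "binarize",
    "scan_thresholds",
    "infer",
    "post_symmetrize",
    "infer_threshold",
]

logger = logging.getLogger(__name__)

#: Two normalized-asymmetry values closer than this are considered tied and
#: resolved by the largest-density rule.  Φ along a scan is a ratio of small
#: integers, so exact ties are the norm and 1e-12 separates genuine ties from
#: floating-point noise.
PHI_TIE_TOL = 1e-12


@dataclass(frozen=True)
class TractogramSet:
    """Per-ROI seed-voxel-by-target-ROI streamline-fraction matrices.

    ``matrices[i]`` has shape (v_i, N): entry (j, k) is the fraction of
    streamlines seeded at voxel j of ROI i that reach any voxel of ROI k.
    Column i of matrix i is identically zero (no self-connections).
    """

    matrices: tuple[np.ndarray, ...]
    roi_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        mats = tuple(np.asarray(m, dtype=float) for m in self.matrices)
        n = len(mats)
        if n < 2:
            raise ValidationError("need at least 2 ROIs")
        for i, m in enumerate(mats):
            if m.ndim != 2 or m.shape[1] != n:
                raise ValidationError(
                    f"matrix {i} has shape {m.shape}, expected (v_{i}, {n})"
                )
            if m.shape[0] < 1:
                raise ValidationError(f"ROI {i} has no seed voxels")
            if np.any(m < 0) or np.any(m > 1):
                raise ValidationError(
                    f"matrix {i} has entries outside [0, 1]"
                )
            if np.any(m[:, i] != 0):
                raise ValidationError(
                    f"matrix {i}, column {i} (self-connections) must be zero"
                )
            m.setflags(write=False)
        object.__setattr__(self, "matrices", mats)
        if self.roi_labels is not None:
            labels = tuple(str(x) for x in self.roi_labels)
            if len(labels) != n:
                raise ValidationError(f"{len(labels)} labels for {n} ROIs")
            if len(set(labels)) != n:
                raise ValidationError("ROI labels must be unique")
            object.__setattr__(self, "roi_labels", labels)

    @property
    def n_rois(self) -> int:
        return len(self.matrices)

    @property
    def voxel_counts(self) -> tuple[int, ...]:
        return tuple(m.shape[0] for m in self.matrices)


@dataclass(frozen=True)
class StrengthMatrix:
    """N×N directed connection strengths in [0, 1]; diagonal forced to zero.

    Binarizing at any τ reproduces the at-least-one-voxel rule of the full
    tractogram: ``G_τ(i,k) = 1 ⇔ S(i,k) > τ``.
    """

    values: np.ndarray
    roi_labels: tuple[str, ...] | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float).copy()
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValidationError(f"strength matrix must be square, got {v.shape}")
        if v.shape[0] < 2:
            raise ValidationError("need at least 2 ROIs")
        if np.any(v < 0) or np.any(v > 1):
            raise ValidationError("strengths must lie in [0, 1]")
        np.fill_diagonal(v, 0.0)
        v.setflags(write=False)
        object.__setattr__(self, "values", v)
        if self.roi_labels is not None:
            labels = tuple(str(x) for x in self.roi_labels)
            if len(labels) != v.shape[0]:
                raise ValidationError(
                    f"{len(labels)} labels for {v.shape[0]} ROIs"
                )
            object.__setattr__(self, "roi_labels", labels)

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class ManiaResult:
    """Outcome of minimum-asymmetry inference.

    ``network`` is the directed network at the selected threshold τ*;
    ``phi_min`` its normalized asymmetry before any post-symmetrization.
    When post-symmetrization was applied, ``symmetrized`` holds the resulting
    undirected network (``None`` otherwise).
    """

    network: DirectedNetwork
    tau_star: float
    rho_star: float
    phi_min: float
    scan: ScanCurve
    post_symmetrized: bool = False
    symmetrized: DirectedNetwork | None = None

    @property
    def final_network(self) -> DirectedNetwork:
        """The symmetrized network when available, else the directed one."""
        return self.symmetrized if self.symmetrized is not None else self.network


def strengths_from_tractogram(t: TractogramSet) -> StrengthMatrix:
    """Reduce voxel-level fractions to one strength per directed ROI pair.

    S(i, k) = max over seed voxels j of T_i(j, k).  The maximum realizes the
    at-least-one-voxel connectivity rule under thresholding.
    """
    n = t.n_rois
    s = np.zeros((n, n))
    for i, m in enumerate(t.matrices):
        s[i, :] = m.max(axis=0)
    np.fill_diagonal(s, 0.0)
    return StrengthMatrix(s, t.roi_labels, provenance="tractogram")


def binarize(s: StrengthMatrix, tau: float) -> DirectedNetwork:
    """Threshold strengths: edge i→k present iff S(i,k) > τ (strictly)."""
    if not 0.0 < tau < 1.0:
        raise ValidationError(f"tau must lie in (0, 1), got {tau}")
    return DirectedNetwork((s.values > tau).astype(np.int8), s.roi_labels)


def _candidate_taus(s: StrengthMatrix) -> np.ndarray:
    """One representative τ per interval between consecutive distinct strengths.

    The thresholded network only changes when τ crosses a strength value, so
    evaluating interval midpoints enumerates every achievable network exactly
    once (including the empty network above the maximum strength, when the
    maximum is below 1).
    """
    off = ~np.eye(s.n_rois, dtype=bool)
    vals = s.values[off]
    positive = np.unique(vals[vals > 0.0])
    if positive.size == 0:
        raise NoSignalError("all connection strengths are zero")
    bounds = np.concatenate([[0.0], positive, [1.0]])
    widths = np.diff(bounds)
    mids = (bounds[:-1] + bounds[1:]) / 2.0
    return mids[widths > 0.0]


def _scan_arrays(s: StrengthMatrix) -> dict[str, np.ndarray]:
    """Vectorized scan: metric arrays over all candidate thresholds.

    For every candidate τ (ascending), counts edges (strengths > τ), pairs
    connected in at least one direction, and reciprocated pairs, from which
    ρ, ϕ and Φ follow.  Shared by the record-building scan and the fast
    selection path used in simulation loops.
    """
    taus = _candidate_taus(s)
    n = s.n_rois
    npairs_ordered = n * (n - 1)

    off = ~np.eye(n, dtype=bool)
    vals_sorted = np.sort(s.values[off])
    iu = np.triu_indices(n, k=1)
    hi = np.sort(np.maximum(s.values, s.values.T)[iu])   # per unordered pair
    lo = np.sort(np.minimum(s.values, s.values.T)[iu])

    # counts of entries strictly greater than each tau
    k = vals_sorted.size - np.searchsorted(vals_sorted, taus, side="right")
    pairs_any = hi.size - np.searchsorted(hi, taus, side="right")
    pairs_both = lo.size - np.searchsorted(lo, taus, side="right")
    unreciprocated = pairs_any - pairs_both

    rho = k / npairs_ordered
    eligible = (k > 0) & (k < npairs_ordered)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where(k > 0, unreciprocated / np.maximum(k, 1), np.nan)
        phi_norm = np.where(eligible, phi / (1.0 - rho), np.nan)
    return {
        "tau": taus,
        "edge_count": k,
        "rho": rho,
        "phi": phi,
        "phi_norm": phi_norm,
        "eligible": eligible,
    }


def scan_thresholds(s: StrengthMatrix) -> ScanCurve:
    """Evaluate ρ, ϕ and Φ at every threshold where the network changes.

    Returns records ordered by increasing τ.  Records whose network is empty
    or complete are kept but flagged ineligible (Φ is undefined there).
    """
    arrs = _scan_arrays(s)
    records = tuple(
        ScanRecord(
            tau=float(t),
            rho=float(r),
            phi=float(p),
            phi_norm=float(pn),
            edge_count=int(kk),
            eligible=bool(el),
        )
        for t, r, p, pn, kk, el in zip(
            arrs["tau"], arrs["rho"], arrs["phi"], arrs["phi_norm"],
            arrs["edge_count"], arrs["eligible"],
        )
    )
    return ScanCurve(records, provenance=s.provenance)


def _select_from_arrays(arrs: dict[str, np.ndarray]) -> tuple[float, float, float]:
    """(τ*, ρ*, Φ_min) of the minimum-Φ eligible record, largest ρ on ties."""
    eligible = arrs["eligible"]
    if not eligible.any():
        cause = "all-complete" if (arrs["rho"] == 1.0).any() else "all-empty"
        raise DegenerateInputError(
            f"no eligible threshold: every achievable network is {cause}"
        )
    phi = arrs["phi_norm"]
    phi_min = np.nanmin(phi[eligible])
    tied = eligible & (phi - phi_min <= PHI_TIE_TOL)
    idx = int(np.nonzero(tied)[0][np.argmax(arrs["rho"][tied])])
    return float(arrs["tau"][idx]), float(arrs["rho"][idx]), float(phi[idx])


def _select_record(scan: ScanCurve) -> ScanRecord:
    eligible = scan.eligible
    if not eligible:
        rhos = {r.rho for r in scan.records}
        cause = "all-complete" if 1.0 in rhos else "all-empty"
        raise DegenerateInputError(
            f"no eligible threshold: every achievable network is {cause}"
        )
    phi_min = min(r.phi_norm for r in eligible)
    tied = [r for r in eligible if r.phi_norm - phi_min <= PHI_TIE_TOL]
    return max(tied, key=lambda r: r.rho)


def infer(s: StrengthMatrix, post_symmetrize_result: bool = True) -> ManiaResult:
    """Run MANIA on a strength matrix.

    Scans every achievable threshold, picks the eligible record minimizing the
    normalized asymmetry Φ (largest density on ties), and — when the optimum
    is not perfectly symmetric (Φ_min > 0) and ``post_symmetrize_result`` is
    set — resolves the remaining one-directional pairs with the confidence
    ratio rule.
    """
    scan = scan_thresholds(s)
    best = _select_record(scan)
    net = binarize(s, best.tau)
    result = ManiaResult(
        network=net,
        tau_star=best.tau,
        rho_star=best.rho,
        phi_min=best.phi_norm,
        scan=scan,
    )
    if post_symmetrize_result and best.phi_norm > 0.0:
        sym = post_symmetrize(net, s, best.tau)
        result = ManiaResult(
            network=net,
            tau_star=best.tau,
            rho_star=best.rho,
            phi_min=best.phi_norm,
            scan=scan,
            post_symmetrized=True,
            symmetrized=sym,
        )
    return result


def _infer_fast(
    s: StrengthMatrix, post_symmetrize_result: bool = True
) -> tuple[DirectedNetwork, float, float, float]:
    """Minimum-asymmetry selection without materializing a ScanCurve.

    Returns (final network, τ*, ρ*, Φ_min); same decision rule as
    :func:`infer`, used inside large simulation loops.
    """
    tau, rho, phi_min = _select_from_arrays(_scan_arrays(s))
    net = binarize(s, tau)
    if post_symmetrize_result and phi_min > 0.0:
        net = post_symmetrize(net, s, tau)
    return net, tau, rho, phi_min


def post_symmetrize(
    net: DirectedNetwork, s: StrengthMatrix, tau: float
) -> DirectedNetwork:
    """Resolve one-directional pairs by comparing presence vs absence confidence.

    For a pair connected in exactly one direction, with S(i,j) > τ ≥ S(j,i),
    the undirected edge is kept iff (S(i,j) − τ)/(1 − τ) > (τ − S(j,i))/τ.
    Reciprocated pairs stay connected, doubly-absent pairs stay disconnected.
    Exact ties drop the edge (and are logged).  The result is symmetric.
    """
    if not 0.0 < tau < 1.0:
        raise ValidationError(f"tau must lie in (0, 1), got {tau}")
    a = net.adjacency.astype(bool)
    one_way = a & ~a.T
    present_conf = (s.values - tau) / (1.0 - tau)
    absent_conf = (tau - s.values.T) / tau
    keep = one_way & (present_conf > absent_conf)
    n_ties = int((one_way & (present_conf == absent_conf)).sum())
    if n_ties:
        logger.info(
            "post-symmetrization: %d tied pair(s) at tau=%g; edges dropped",
            n_ties, tau,
        )
    out = (a & a.T) | keep | keep.T
    return DirectedNetwork(out.astype(np.int8), net.node_labels)


def infer_threshold(
    s: StrengthMatrix, tau0: float, post_symmetrize_result: bool = False
) -> DirectedNetwork:
    """Fixed-threshold baseline: binarize at a given τ0, optionally symmetrize."""
    net = binarize(s, tau0)
    if post_symmetrize_result:
        net = post_symmetrize(net, s, tau0)
    return net
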