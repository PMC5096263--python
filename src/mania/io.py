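"""Readers, writers and the input manifest.

The canonical on-disk dialect is TSV with a header row of ROI labels:

* a per-ROI tractogram matrix has one row per seed voxel and one labeled
  column per target ROI (values are streamline fractions in [0, 1], or raw
  counts when the manifest declares counts mode);
* a strength matrix is a labeled N×N TSV (first column holds row labels).

A JSON manifest ties the per-ROI matrices together::

    {"roi_labels": [...], "matrix_paths": [...],
     "streamline_count": 5000, "mode": "fractions" | "counts"}

``streamline_count`` (the number of streamlines launched per seed voxel;
tractography default 5000) converts raw counts into fractions.  Matrices are
label-addressed: columns are matched to the manifest's ROI order by header
name, never by position.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError
from .inference import ManiaResult, StrengthMatrix, TractogramSet
from .network import DirectedNetwork

__all__ = [
    "Manifest",
    "read_manifest",
    "read_tractogram",
    "read_strength_matrix",
    "write_strength_matrix",
    "write_report",
    "read_report",
]

logger = logging.getLogger(__name__)

DEFAULT_STREAMLINE_COUNT = 5000


@dataclass(frozen=True)
class Manifest:
    """Names the ROIs and locates one tractogram matrix per ROI."""

    roi_labels: tuple[str, ...]
    matrix_paths: tuple[Path, ...]
    streamline_count: int = DEFAULT_STREAMLINE_COUNT
    mode: str = "fractions"
    metadata: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.roi_labels) != len(self.matrix_paths):
            raise ValidationError(
                f"{len(self.roi_labels)} labels but "
                f"{len(self.matrix_paths)} matrix paths"
            )
        if len(self.roi_labels) < 2:
            raise ValidationError("need at least 2 ROIs")
        if len(set(self.roi_labels)) != len(self.roi_labels):
            raise ValidationError("ROI labels must be unique")
        if self.mode not in ("fractions", "counts"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.streamline_count < 1:
            raise ValidationError("streamline_count must be positive")


def read_manifest(path: str | Path) -> Manifest:
    path = Path(path)
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValidationError(f"{path}: invalid JSON ({exc})") from exc
    for key in ("roi_labels", "matrix_paths"):
        if key not in raw:
            raise ValidationError(f"{path}: manifest missing {key!r}")
    base = path.parent
    return Manifest(
        roi_labels=tuple(raw["roi_labels"]),
        matrix_paths=tuple(
            (base / p) if not Path(p).is_absolute() else Path(p)
            for p in raw["matrix_paths"]
        ),
        streamline_count=int(raw.get("streamline_count", DEFAULT_STREAMLINE_COUNT)),
        mode=raw.get("mode", "fractions"),
        metadata=raw.get("metadata", {}),
    )


def _read_matrix(path: Path, sep: str) -> pd.DataFrame:
    if not path.exists():
        raise ValidationError(f"matrix file not found: {path}")
    return pd.read_csv(path, sep=sep, index_col=None)


def read_tractogram(manifest: Manifest | str | Path, sep: str = "\t") -> TractogramSet:
    """Load and validate the per-ROI voxel-to-ROI matrices of a manifest.

    Raw counts are divided by the manifest's streamline count.  A nonzero
    self-connection column is zeroed with a logged warning.
    """
    if not isinstance(manifest, Manifest):
        manifest = read_manifest(manifest)
    labels = list(manifest.roi_labels)
    matrices = []
    for i, path in enumerate(manifest.matrix_paths):
        df = _read_matrix(path, sep)
        missing = [l for l in labels if l not in df.columns]
        if missing:
            raise ValidationError(
                f"{path}: missing ROI columns {missing}; found {list(df.columns)}"
            )
        m = df[labels].to_numpy(dtype=float)
        if manifest.mode == "counts":
            m = m / manifest.streamline_count
        bad = np.argwhere((m < 0) | (m > 1))
        if bad.size:
            j, k = bad[0]
            raise ValidationError(
                f"{path}: value {m[j, k]} outside [0, 1] at row {j + 2}, "
                f"column {labels[k]!r}"
            )
        if np.any(m[:, i] != 0):
            logger.warning(
                "%s: self-connection column %r is nonzero; forcing to zero",
                path, labels[i],
            )
            m[:, i] = 0.0
        matrices.append(m)
    return TractogramSet(tuple(matrices), tuple(labels))


def read_strength_matrix(path: str | Path, sep: str = "\t") -> StrengthMatrix:
    """Read a labeled N×N strength TSV (row labels in the first column)."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"strength matrix not found: {path}")
    df = pd.read_csv(path, sep=sep, index_col=0)
    cols = [str(c) for c in df.columns]
    rows = [str(r) for r in df.index]
    if rows != cols:
        # align rows to the column order; rows are label-addressed
        try:
            df = df.loc[cols]
        except KeyError as exc:
            raise ValidationError(
                f"{path}: row labels {rows} do not match columns {cols}"
            ) from exc
    return StrengthMatrix(
        df.to_numpy(dtype=float), tuple(cols), provenance=str(path)
    )


def write_strength_matrix(s: StrengthMatrix, path: str | Path, sep: str = "\t") -> None:
    labels = list(s.roi_labels) if s.roi_labels else [
        f"ROI{i + 1}" for i in range(s.n_rois)
    ]
    pd.DataFrame(s.values, index=labels, columns=labels).to_csv(
        path, sep=sep, float_format="%.12g"
    )


def _round_floats(obj: Any) -> Any:
    """Canonicalize floats to 12 significant digits for stable reports."""
    if isinstance(obj, float):
        return float(f"{obj:.12g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v) for v in obj]
    return obj


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _network_payload(net: DirectedNetwork) -> dict[str, Any]:
    return {
        "n_nodes": net.n_nodes,
        "node_labels": list(net.node_labels) if net.node_labels else None,
        "edges": [[net.label_of(i), net.label_of(k)] for i, k in net.edges()],
    }


def write_report(
    result: ManiaResult,
    path: str | Path,
    inputs: Mapping[str, str | Path] | None = None,
    seed: int | None = None,
    confidence_table: list[dict[str, Any]] | None = None,
) -> None:
    """Serialize an inference result to canonical JSON.

    Keys are sorted and floats fixed at 12 significant digits, so identical
    runs produce byte-identical reports.  Input file hashes and the seed are
    recorded for provenance.
    """
    from . import __version__

    payload: dict[str, Any] = {
        "tool": "mania",
        "version": __version__,
        "seed": seed,
        "tau_star": result.tau_star,
        "rho_star": result.rho_star,
        "phi_min": result.phi_min,
        "post_symmetrized": result.post_symmetrized,
        "network": _network_payload(result.network),
        "symmetrized_network": (
            _network_payload(result.symmetrized)
            if result.symmetrized is not None
            else None
        ),
        "scan": [
            {
                "tau": r.tau,
                "rho": r.rho,
                "phi": r.phi,
                "phi_norm": r.phi_norm,
                "edge_count": r.edge_count,
                "eligible": r.eligible,
            }
            for r in result.scan
        ],
        "input_hashes": (
            {str(k): _sha256(v) for k, v in inputs.items()} if inputs else {}
        ),
        "confidence": confidence_table,
    }
    text = json.dumps(_round_floats(payload), sort_keys=True, indent=1,
                      allow_nan=True)
    Path(path).write_text(text + "\n")


def read_report(path: str | Path) -> dict[str, Any]:
    """Read back a report written by :func:`write_report`."""
    return json.loads(Path(path).read_text())
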