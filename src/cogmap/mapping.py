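"""Map-scale analysis: classical MDS projection and the GDV cluster index.

Treating each row of a (learned or ground-truth) SR matrix as a point in
state space, classical metric MDS embeds the rows in the plane while
preserving their mutual Euclidean distances — the resulting scatter is the
cognitive map at the chosen discount factor. Small discounts give
fine-grained maps with every state separated; discounts near one contract
states of the same semantic class into dense clusters.

Cluster quality is scored by the general discrimination value (GDV): after
z-scoring each dimension and scaling by 1/2, it is the mean intra-class
pairwise distance minus the mean inter-class pairwise distance, divided by
the square root of the dimensionality. A GDV of 0 means the classes are
unseparated; more negative values mean stronger clustering, approaching -1
for tight, well-separated classes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np

from .successor import SRMatrix

__all__ = ["CognitiveMap", "mds_project", "compute_gdv", "build_map"]


@dataclass(frozen=True)
class CognitiveMap:
    """A 2-D embedding of SR rows with class labels and a GDV score."""

    coordinates: np.ndarray  # (n_states, 2), centered at the origin
    labels: tuple[str, ...]
    gamma: float
    gdv: float
    state_names: tuple[str, ...] | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "coordinates": self.coordinates.tolist(),
                "labels": list(self.labels),
                "gamma": self.gamma,
                "gdv": self.gdv,
                "states": list(self.state_names) if self.state_names else None,
            }
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    def plot(self, path: str | Path | None = None, annotate: bool = False):
        """Scatter the map colored by class; optionally save to ``path``."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 5))
        classes = sorted(set(self.labels))
        for cls in classes:
            pts = self.coordinates[[l == cls for l in self.labels]]
            ax.scatter(pts[:, 0], pts[:, 1], label=cls, s=30)
        if annotate and self.state_names:
            for (x, y), name in zip(self.coordinates, self.state_names):
                ax.annotate(name, (x, y), fontsize=6)
        ax.set_title(f"gamma = {self.gamma:g}, GDV = {self.gdv:.3f}")
        ax.legend()
        if path is not None:
            fig.savefig(path, dpi=150, bbox_inches="tight")
            plt.close(fig)
        return fig


def mds_project(rows: np.ndarray, n_components: int = 2, return_eigenvalues: bool = False):
    """Classical (Torgerson) metric MDS of row vectors to ``n_components`` axes.

    Eigendecomposition of the doubly-centered squared-distance matrix;
    axes are ordered by decreasing eigenvalue and the output is exact
    whenever a Euclidean embedding of that dimension exists. Coordinates
    are centered at the origin and defined up to rotation/reflection; for
    reproducibility each axis' sign is fixed so its largest-magnitude
    coordinate is positive.
    """
    rows = np.asarray(rows, dtype=float)
    n = rows.shape[0]
    if n < 3:
        raise ValueError("MDS projection needs at least 3 points")
    diff = rows[:, None, :] - rows[None, :, :]
    D2 = (diff**2).sum(axis=2)
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ D2 @ J
    B = (B + B.T) / 2.0
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = np.clip(eigval[:n_components], 0.0, None)
    coords = eigvec[:, :n_components] * np.sqrt(pos)
    for j in range(coords.shape[1]):
        k = np.argmax(np.abs(coords[:, j]))
        if coords[k, j] < 0:
            coords[:, j] = -coords[:, j]
    if return_eigenvalues:
        return coords, eigval
    return coords


def compute_gdv(points: np.ndarray, labels: Sequence[str]) -> float:
    """General discrimination value of a labelled point cloud.

    Each dimension is z-scored over all points and scaled by 1/2
    (zero-variance dimensions are dropped with a warning); the score is
    ``(mean intra-class pairwise distance - mean inter-class pairwise
    distance) / sqrt(d)``. Requires at least two classes, each with at
    least two members.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    labels = list(labels)
    if len(labels) != points.shape[0]:
        raise ValueError("labels length must match the number of points")
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("GDV needs at least two classes")
    members = {c: np.flatnonzero([l == c for l in labels]) for c in classes}
    for c, idx in members.items():
        if len(idx) < 2:
            raise ValueError(f"class {c!r} has fewer than two members")

    std = points.std(axis=0)
    keep = std > 0
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} zero-variance dimension(s) from the GDV",
            RuntimeWarning,
            stacklevel=2,
        )
        points = points[:, keep]
        std = std[keep]
    d = points.shape[1]
    if d == 0:
        raise ValueError("no dimension with non-zero variance")
    Z = 0.5 * (points - points.mean(axis=0)) / std

    def mean_pairwise(A: np.ndarray, B: np.ndarray | None = None) -> float:
        if B is None:
            diff = A[:, None, :] - A[None, :, :]
            dist = np.sqrt((diff**2).sum(axis=2))
            iu = np.triu_indices(len(A), k=1)
            return float(dist[iu].mean())
        diff = A[:, None, :] - B[None, :, :]
        return float(np.sqrt((diff**2).sum(axis=2)).mean())

    intra = np.mean([mean_pairwise(Z[members[c]]) for c in classes])
    inter = np.mean(
        [mean_pairwise(Z[members[a]], Z[members[b]]) for a, b in combinations(classes, 2)]
    )
    return float((intra - inter) / np.sqrt(d))


def build_map(
    sr_rows: np.ndarray | SRMatrix,
    labels: Sequence[str],
    gamma: float | None = None,
    state_names: Sequence[str] | None = None,
) -> CognitiveMap:
    """Project SR rows to the plane and score the projection's clustering."""
    if isinstance(sr_rows, SRMatrix):
        if gamma is None:
            gamma = sr_rows.gamma
        if state_names is None:
            state_names = sr_rows.state_names
        sr_rows = sr_rows.normalized
    coords = mds_project(sr_rows)
    gdv = compute_gdv(coords, labels)
    return CognitiveMap(
        coordinates=coords,
        labels=tuple(labels),
        gamma=float(gamma) if gamma is not None else float("nan"),
        gdv=gdv,
        state_names=tuple(state_names) if state_names is not None else None,
    )
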