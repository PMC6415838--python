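"""Shared domain types for the vessel analysis pipeline.

Conventions used throughout the package:

* all volumes are indexed ``(z, y, x)`` with ``z`` the imaging depth axis;
* voxel spacing is a ``(dz, dy, dx)`` triple in micrometres;
* segmentation masks are ``uint8`` arrays with values ``{0, 1}``;
* displacement fields are *pull-back* fields in pixel units: the warped
  slice satisfies ``out(y, x) = in(y + u_y(y, x), x + u_x(y, x))``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

Spacing = tuple[float, float, float]


@dataclass
class ImageStack:
    """A 3D grayscale intensity volume with physical voxel spacing.

    Parameters
    ----------
    data
        ``(z, y, x)`` float array of intensities.
    voxel_size_um
        ``(dz, dy, dx)`` voxel edge lengths in micrometres.
    """

    data: np.ndarray
    voxel_size_um: Spacing = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D (z, y, x) array, got ndim={self.data.ndim}")
        self.voxel_size_um = tuple(float(s) for s in self.voxel_size_um)
        if len(self.voxel_size_um) != 3 or any(s <= 0 for s in self.voxel_size_um):
            raise ValueError(f"voxel spacings must be three positive numbers, got {self.voxel_size_um}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def copy(self) -> "ImageStack":
        return ImageStack(self.data.copy(), self.voxel_size_um)

    def require_finite(self) -> None:
        if not np.isfinite(self.data).all():
            raise ValueError("image stack contains NaN or infinite intensities")


@dataclass
class SliceDeformation:
    """Per-slice in-plane displacement fields of a stack.

    ``fields`` has shape ``(Z, 2, Y, X)``; ``fields[z, 0]`` is the ``y``
    component and ``fields[z, 1]`` the ``x`` component, in pixel units.
    Slice 0 is the fixed reference and carries the identity (zero) field.
    """

    fields: np.ndarray

    def __post_init__(self) -> None:
        self.fields = np.asarray(self.fields, dtype=np.float32)
        if self.fields.ndim != 4 or self.fields.shape[1] != 2:
            raise ValueError("deformation fields must have shape (Z, 2, Y, X)")

    @property
    def n_slices(self) -> int:
        return self.fields.shape[0]

    def max_magnitude_per_slice(self) -> np.ndarray:
        mag = np.sqrt(self.fields[:, 0] ** 2 + self.fields[:, 1] ** 2)
        return mag.reshape(self.n_slices, -1).max(axis=1)


@dataclass
class GraphNode:
    id: int
    coordinate: tuple[int, int, int]
    kind: str  # "endpoint" | "junction" | "loop"
    voxels: list[tuple[int, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.voxels:
            self.voxels = [tuple(self.coordinate)]


@dataclass
class GraphEdge:
    id: int
    path: np.ndarray  # (n, 3) ordered voxel coordinates, node to node inclusive
    u: int
    v: int

    def __post_init__(self) -> None:
        self.path = np.asarray(self.path, dtype=np.int64).reshape(-1, 3)


@dataclass
class CenterlineGraph:
    """Vascular network: nodes are endpoints/bifurcations, edges are vessels."""

    nodes: dict[int, GraphNode]
    edges: list[GraphEdge]
    voxel_size_um: Spacing = (1.0, 1.0, 1.0)

    def degree(self, node_id: int) -> int:
        d = 0
        for e in self.edges:
            if e.u == node_id:
                d += 1
            if e.v == node_id:
                d += 1
        return d

    def rasterize(self) -> np.ndarray:
        """All voxels covered by the graph (edge paths plus node clusters), (n, 3)."""
        vox: set[tuple[int, int, int]] = set()
        for n in self.nodes.values():
            vox.update(map(tuple, n.voxels))
        for e in self.edges:
            vox.update(map(tuple, e.path))
        if not vox:
            return np.empty((0, 3), dtype=np.int64)
        return np.array(sorted(vox), dtype=np.int64)

    def to_json_dict(self) -> dict:
        return {
            "voxel_size_um": list(self.voxel_size_um),
            "nodes": [
                {
                    "id": n.id,
                    "coordinate": list(map(int, n.coordinate)),
                    "kind": n.kind,
                    "voxels": [list(map(int, v)) for v in n.voxels],
                }
                for n in self.nodes.values()
            ],
            "edges": [
                {"id": e.id, "u": e.u, "v": e.v, "path": e.path.tolist()}
                for e in self.edges
            ],
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "CenterlineGraph":
        nodes = {
            n["id"]: GraphNode(
                id=n["id"],
                coordinate=tuple(n["coordinate"]),
                kind=n["kind"],
                voxels=[tuple(v) for v in n.get("voxels", [])],
            )
            for n in d["nodes"]
        }
        edges = [
            GraphEdge(id=e["id"], path=np.asarray(e["path"]), u=e["u"], v=e["v"])
            for e in d["edges"]
        ]
        return cls(nodes=nodes, edges=edges, voxel_size_um=tuple(d.get("voxel_size_um", (1, 1, 1))))

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh)

    @classmethod
    def load_json(cls, path) -> "CenterlineGraph":
        with open(path) as fh:
            return cls.from_json_dict(json.load(fh))


@dataclass
class VesselSegment:
    """Per-vessel morphometric record.

    ``tortuosity`` is path length over the Euclidean end-to-end distance
    (1.0 for a straight vessel, NaN for a closed loop).
    """

    edge_id: int
    path: np.ndarray
    length_um: float
    diameter_um: float
    tortuosity: float
    endpoints: tuple[tuple[int, int, int], tuple[int, int, int]]

    def __post_init__(self) -> None:
        self.path = np.asarray(self.path, dtype=np.int64).reshape(-1, 3)


def as_binary(volume: np.ndarray) -> np.ndarray:
    """Coerce a mask-like array to uint8 {0,1}, validating binarity."""
    arr = np.asarray(volume)
    if arr.dtype == bool:
        return arr.astype(np.uint8)
    vals = np.unique(arr)
    if not np.isin(vals, (0, 1, 255)).all():
        raise ValueError("segmentation volume is not binary")
    return (arr > 0).astype(np.uint8)
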