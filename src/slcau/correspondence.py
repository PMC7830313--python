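"""Dense semantic correspondence via landmark-guided region resampling.

Training a morphable model requires every scan to have the same number of
vertices with the same anatomical meaning per index.  Starting from a sparse
set of named landmarks shared by all scans, the face is partitioned into
non-overlapping regions bounded by landmarks; each region is resampled on a
fixed barycentric/bilinear grid so that the j-th sample of one scan matches
the j-th sample of every other scan.  Concatenating the per-region samples in
a fixed region order yields a registered shape vector.

This is a deliberately simplified registration: regions are quadrilateral (or
triangular) landmark-bounded patches, the interior grid is bilinear in the
corner landmarks and then projected onto the scan surface (nearest point on
the triangulated surface when faces are available, nearest vertex otherwise).
Sample ordering is lexicographic over (region index, grid row, grid column).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .meshio import RegisteredShape, TriMesh

__all__ = ["RegionSpec", "RegionMap", "partition_regions", "resample_region", "register_scan"]


@dataclass(frozen=True)
class RegionSpec:
    """One landmark-bounded region of a resampling scheme.

    ``corners`` are 3 or 4 landmark names in fixed (counter-clockwise) order;
    ``grid`` is the (rows, cols) sample lattice.
    """

    region_id: str
    corners: tuple
    grid: tuple

    @property
    def sample_count(self) -> int:
        return self.grid[0] * self.grid[1]


@dataclass
class RegionMap:
    """A full resampling scheme: ordered regions plus the derived topology id.

    Every scan registered against the same RegionMap yields a vector of
    identical length ``3 * total_samples`` whose indices share semantics.
    ``vertex_regions`` (optional) assigns each template vertex to exactly one
    region index — used by synthetic generators and locality diagnostics.
    """

    regions: list
    name: str = "scheme"
    vertex_regions: np.ndarray | None = None

    def __post_init__(self):
        if not self.regions:
            raise ValueError("region scheme has no regions")

    @property
    def total_samples(self) -> int:
        return sum(r.sample_count for r in self.regions)

    @property
    def region_ids(self) -> list:
        return [r.region_id for r in self.regions]

    @property
    def topology_id(self) -> str:
        spec = ";".join(f"{r.region_id}:{','.join(r.corners)}:{r.grid[0]}x{r.grid[1]}" for r in self.regions)
        digest = hashlib.sha1(spec.encode()).hexdigest()[:10]
        return f"{self.name}-{self.total_samples}-{digest}"

    def region_of_samples(self) -> np.ndarray:
        """Region index of every sample of a registered vector, in order."""
        out = np.concatenate([np.full(r.sample_count, i) for i, r in enumerate(self.regions)])
        return out.astype(np.int64)

    @classmethod
    def from_config(cls, cfg: dict) -> "RegionMap":
        """Build from a config mapping: {name, regions: [{id, corners, grid}]}."""
        regions = [
            RegionSpec(r["id"], tuple(r["corners"]), tuple(r["grid"])) for r in cfg["regions"]
        ]
        return cls(regions, name=cfg.get("name", "scheme"))


def partition_regions(landmarks: dict, scheme: RegionMap) -> RegionMap:
    """Validate a landmark set against a scheme and return the resolved RegionMap.

    Deterministic: the same landmarks and scheme always produce the same map.
    Raises ``KeyError`` naming the first missing landmark.
    """
    for region in scheme.regions:
        for name in region.corners:
            if name not in landmarks:
                raise KeyError(
                    f"landmark {name!r} required by region {region.region_id!r} is missing"
                )
    return RegionMap(list(scheme.regions), name=scheme.name, vertex_regions=scheme.vertex_regions)


def _grid_points(corners: np.ndarray, rows: int, cols: int) -> np.ndarray:
    """Bilinear (rows x cols) lattice inside a 3/4-corner patch, row-major.

    A single sample (1x1) sits at the patch centroid.  Triangular patches are
    handled as degenerate quads with the last corner repeated.
    """
    if corners.shape[0] == 3:
        corners = np.vstack([corners, corners[2]])
    c00, c10, c11, c01 = corners  # CCW order: (0,0) -> (1,0) -> (1,1) -> (0,1)
    u = np.full(rows, 0.5) if rows == 1 else np.linspace(0.0, 1.0, rows)
    v = np.full(cols, 0.5) if cols == 1 else np.linspace(0.0, 1.0, cols)
    uu, vv = np.meshgrid(u, v, indexing="ij")
    uu = uu.ravel()[:, None]
    vv = vv.ravel()[:, None]
    return (1 - uu) * (1 - vv) * c00 + uu * (1 - vv) * c10 + uu * vv * c11 + (1 - uu) * vv * c01


def _project_to_surface(points: np.ndarray, mesh: TriMesh) -> np.ndarray:
    if mesh.faces.size:
        import trimesh as _trimesh
        from trimesh.proximity import closest_point_naive

        tm = _trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
        closest, _, _ = closest_point_naive(tm, points)
        return np.asarray(closest, dtype=np.float64)
    _, idx = cKDTree(mesh.vertices).query(points)
    return mesh.vertices[idx]


def resample_region(mesh: TriMesh, region: RegionSpec, count: int | None = None) -> np.ndarray:
    """Sample a region of ``mesh`` on its fixed barycentric grid.

    Returns exactly ``count`` (default: the region's grid size) ordered points
    lying on the scan surface; the j-th sample is semantically matched across
    scans because the grid is anchored to the same named landmarks.
    """
    if mesh.landmarks is None:
        raise KeyError(f"mesh has no landmarks; region {region.region_id!r} needs {region.corners}")
    missing = [n for n in region.corners if n not in mesh.landmarks]
    if missing:
        raise KeyError(f"landmark {missing[0]!r} required by region {region.region_id!r} is missing")
    corners = np.array([mesh.landmarks[n] for n in region.corners])
    # degenerate patch: all corners (numerically) coincident
    if np.ptp(corners, axis=0).max() < 1e-12:
        raise ValueError(f"region {region.region_id!r} is degenerate (zero area)")
    if count is None:
        rows, cols = region.grid
    else:
        rows = int(round(np.sqrt(count)))
        while count % rows:
            rows -= 1
        cols = count // rows
    grid = _grid_points(corners, rows, cols)
    return _project_to_surface(grid, mesh)


def register_scan(mesh: TriMesh, region_map: RegionMap) -> RegisteredShape:
    """Resample every region of ``mesh`` and concatenate into a registered shape."""
    partition_regions(mesh.landmarks or {}, region_map)
    samples = [resample_region(mesh, region) for region in region_map.regions]
    vec = np.concatenate(samples, axis=0).reshape(-1)
    return RegisteredShape(vec, region_map.topology_id)
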