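"""Synthetic face corpora with known identity and localized AU-like deformations.

Real 3D face corpora are licensed downloads; the generator emulates their two
roles instead.  The template is a smooth half-ellipsoid "face" (lateral
half-width 60 mm, vertical 80 mm, depth 50 mm, apex = nose tip at max z, face
looking along +z) built on a polar vertex grid, with named landmarks and a
partition into labelled regions (left/right brows, left/right cheeks, mouth,
jaw, nose).

Subjects are the template plus a smooth low-frequency random identity field
(a handful of wide Gaussian bumps with random directions).  AU activations
are compact, cosine-tapered displacement fields supported on a single
labelled region — exactly zero outside it — and identical across subjects in
template coordinates, so expression/identity disentangling is achievable in
principle, the premise the analysis pipeline relies on.

Both fields are smooth functions over the surface, so they can be evaluated
at arbitrary surface points: raw scans are sampled on their own, much denser
and jittered point grid (real scanners resolve the face far more finely than
a shape model's vertex count), shuffled in order, and perturbed by zero-mean
Gaussian scanner noise.  The registered ground truth lives on the template
vertex grid.  Everything is deterministic given the config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .correspondence import RegionMap, RegionSpec
from .meshio import RegisteredShape, TriMesh, write_mesh

__all__ = [
    "AUSpec",
    "SyntheticConfig",
    "SyntheticCorpus",
    "IdentityField",
    "make_template",
    "sample_identity",
    "apply_synthetic_au",
    "au_displacement_field",
    "generate_corpus",
    "generate_dataset",
]

# half-ellipsoid semi-axes, mm
_AX, _AY, _AZ = 60.0, 80.0, 50.0

# angular sector boundaries (degrees) and radial bands of the region rule
_THETA_EDGES = [20.0, 90.0, 160.0, 225.0, 315.0]
_R_INNER, _R_MID = 0.25, 0.7

REGION_IDS = ["nose", "brow_r", "brow_l", "cheek_l", "cheek_r", "mouth", "jaw"]


@dataclass(frozen=True)
class AUSpec:
    """A synthetic action unit: a displacement field on one labelled region.

    ``kind``: ``bump`` (outward normal push), ``pull`` (tangential pull toward
    the region centre), ``asymmetric`` (bump restricted to one lateral half).
    ``magnitude`` is the peak displacement in mm at full intensity.
    """

    au_id: str
    region_id: str
    kind: str = "bump"
    magnitude: float = 6.0

    def __post_init__(self):
        if self.kind not in ("bump", "pull", "asymmetric"):
            raise ValueError(f"unknown AU field kind {self.kind!r}")
        if self.magnitude <= 0:
            raise ValueError("AU magnitude must be > 0")


def _default_au_specs():
    return [
        AUSpec("AU-BROW-L", "brow_l", "bump", 6.0),
        AUSpec("AU-BROW-R", "brow_r", "asymmetric", 6.0),
        AUSpec("AU-MOUTH", "mouth", "pull", 6.0),
        AUSpec("AU-CHEEK-L", "cheek_l", "bump", 6.0),
    ]


@dataclass
class SyntheticConfig:
    """Study conditions of the synthetic corpus.

    Defaults: 10 subjects, the four default AUs at 6 mm peak magnitude, 2 mm
    identity RMS, 0.1 mm scanner noise, one scan per condition, raw scans on
    an independent 4x-denser jittered point grid.
    """

    seed: int = 0
    m: int = 500
    n_subjects: int = 10
    identity_scale: float = 2.0
    au_specs: list = field(default_factory=_default_au_specs)
    scans_per_condition: int = 1
    noise_sigma: float = 0.1
    resample: bool = True
    raw_density: float = 4.0

    def __post_init__(self):
        if any(spec.magnitude <= 0 for spec in self.au_specs):
            raise ValueError("AU magnitudes must be > 0")


# --------------------------------------------------------------------------
# surface parameterization

def _surface_point(r: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Face surface: half-ellipsoid plus fixed relief (nose + undulations).

    The relief gives the surface tangential "features" (a protruding nose,
    brow/cheek-scale undulations) without which nearest-neighbour
    registration of a smooth ovoid would be tangentially ill-posed — real
    faces are registrable precisely because of such structure.
    """
    x = _AX * r * np.cos(theta)
    y = _AY * r * np.sin(theta)
    z = _AZ * np.sqrt(np.maximum(1.0 - r**2, 0.0))
    base = np.column_stack([x, y, z])
    normals = base / np.array([_AX**2, _AY**2, _AZ**2])
    normals /= np.maximum(np.linalg.norm(normals, axis=1, keepdims=True), 1e-12)
    height = 10.0 * np.exp(-(x**2 + y**2) / (2.0 * 9.0**2))  # nose at the apex
    height = height + 2.5 * np.sin(x / 7.0) * np.sin(y / 8.0)  # gentle relief
    return base + height[:, None] * normals


def _params_of(points: np.ndarray):
    """Invert the parameterization for on-surface points (uses x, y only)."""
    r = np.sqrt(np.clip((points[:, 0] / _AX) ** 2 + (points[:, 1] / _AY) ** 2, 0.0, 1.0))
    theta = np.arctan2(points[:, 1] / _AY, points[:, 0] / _AX)
    return r, np.degrees(theta)


def _region_rule(r: np.ndarray, theta_deg: np.ndarray) -> np.ndarray:
    """Disjoint, exhaustive region index per (r, theta)."""
    t = np.mod(theta_deg, 360.0)
    out = np.zeros(r.shape, dtype=np.int64)  # nose
    lateral = r > _R_INNER
    out[lateral & (t >= _THETA_EDGES[0]) & (t < _THETA_EDGES[1])] = REGION_IDS.index("brow_r")
    out[lateral & (t >= _THETA_EDGES[1]) & (t < _THETA_EDGES[2])] = REGION_IDS.index("brow_l")
    out[lateral & (t >= _THETA_EDGES[2]) & (t < _THETA_EDGES[3])] = REGION_IDS.index("cheek_l")
    out[lateral & ((t >= _THETA_EDGES[4]) | (t < _THETA_EDGES[0]))] = REGION_IDS.index("cheek_r")
    lower = lateral & (t >= _THETA_EDGES[3]) & (t < _THETA_EDGES[4])
    out[lower & (r <= _R_MID)] = REGION_IDS.index("mouth")
    out[lower & (r > _R_MID)] = REGION_IDS.index("jaw")
    return out


def region_of_points(points: np.ndarray) -> np.ndarray:
    """Region index of arbitrary on-surface points under the fixed rule."""
    r, t = _params_of(points)
    return _region_rule(r, t)


# --------------------------------------------------------------------------
# template

def make_template(m: int = 500, seed: int = 0, grid: tuple = (4, 4)) -> tuple:
    """Build the face-like template mesh and its region map.

    Vertices form ``1 + nr*ntheta <= m`` points (apex plus polar rings);
    landmarks sit at the (r, theta) corners of the region rule plus
    ``nose_tip`` at the apex (the max-z vertex by construction).  The region
    map carries both the landmark-bounded quad scheme (for raw-scan
    correspondence) and the per-vertex region assignment.
    """
    if m < 100:
        raise ValueError("template needs at least 100 vertices")
    del seed  # the template geometry is fully deterministic; kept for API symmetry
    ntheta = max(12, int(round(np.sqrt(2.0 * m))))
    nr = (m - 1) // ntheta
    if nr < 3:
        raise ValueError("template too small for the region rule")

    rs = [np.array([0.0])]
    thetas = [np.array([0.0])]
    for i in range(1, nr + 1):
        rs.append(np.full(ntheta, i / nr))
        thetas.append(2.0 * np.pi * np.arange(ntheta) / ntheta)
    r_all = np.concatenate(rs)
    th_all = np.concatenate(thetas)
    verts = _surface_point(r_all, th_all)

    faces = []
    for j in range(ntheta):  # apex fan
        faces.append([0, 1 + j, 1 + (j + 1) % ntheta])
    for i in range(1, nr):   # ring quads split into triangles
        a0 = 1 + (i - 1) * ntheta
        b0 = 1 + i * ntheta
        for j in range(ntheta):
            jn = (j + 1) % ntheta
            faces.append([a0 + j, b0 + j, b0 + jn])
            faces.append([a0 + j, b0 + jn, a0 + jn])
    faces = np.asarray(faces, dtype=np.int64)

    landmarks: dict = {"nose_tip": verts[0].copy()}
    r_edges = [_R_INNER, _R_MID, 1.0]
    for ti, tdeg in enumerate(_THETA_EDGES):
        for ri, redge in enumerate(r_edges):
            p = _surface_point(np.array([redge]), np.array([np.radians(tdeg)]))[0]
            landmarks[f"lm_t{ti}_r{ri}"] = p

    def quad(t0, t1, r0, r1):
        return (f"lm_t{t0}_r{r0}", f"lm_t{t1}_r{r0}", f"lm_t{t1}_r{r1}", f"lm_t{t0}_r{r1}")

    specs = [
        RegionSpec("nose", ("nose_tip", "lm_t0_r0", "lm_t2_r0", "lm_t3_r0"), grid),
        RegionSpec("brow_r", quad(0, 1, 0, 2), grid),
        RegionSpec("brow_l", quad(1, 2, 0, 2), grid),
        RegionSpec("cheek_l", quad(2, 3, 0, 2), grid),
        RegionSpec("cheek_r", quad(4, 0, 0, 2), grid),
        RegionSpec("mouth", quad(3, 4, 0, 1), grid),
        RegionSpec("jaw", quad(3, 4, 1, 2), grid),
    ]
    region_idx = _region_rule(r_all, np.degrees(th_all))
    region_map = RegionMap(specs, name="half-ellipsoid", vertex_regions=region_idx)

    mesh = TriMesh(verts, faces, landmarks, label="template")
    return mesh, region_map


def template_topology_id(mesh: TriMesh) -> str:
    return f"synthetic-face-{mesh.n_vertices}"


# --------------------------------------------------------------------------
# identity fields

@dataclass
class IdentityField:
    """A smooth low-frequency deformation: Gaussian bumps with fixed directions.

    Evaluable at arbitrary surface points, so the same subject identity can
    displace both the template grid and a dense raw-scan point cloud.
    """

    centres: np.ndarray    # (nb, 3)
    directions: np.ndarray  # (nb, 3) unit
    amplitude: float        # common scale factor, mm
    width: float = 40.0     # Gaussian width, mm

    def displacement(self, points: np.ndarray) -> np.ndarray:
        disp = np.zeros_like(points)
        for centre, direction in zip(self.centres, self.directions):
            d2 = np.sum((points - centre) ** 2, axis=1)
            disp += np.exp(-d2 / (2.0 * self.width**2))[:, None] * direction
        return self.amplitude * disp

    @classmethod
    def random(cls, template: TriMesh, identity_scale: float, seed: int, n_bumps: int = 5) -> "IdentityField":
        """Random field normalized to RMS ``identity_scale`` on the template."""
        rng = np.random.default_rng(seed)
        verts = template.vertices
        centres = verts[rng.integers(0, len(verts), size=n_bumps)]
        directions = rng.normal(size=(n_bumps, 3))
        directions /= np.linalg.norm(directions, axis=1, keepdims=True)
        fld = cls(centres, directions, 1.0)
        if identity_scale == 0:
            return cls(centres, directions, 0.0)
        rms = np.sqrt(np.mean(np.sum(fld.displacement(verts) ** 2, axis=1)))
        return cls(centres, directions, identity_scale / max(rms, 1e-12))


def sample_identity(template: TriMesh, identity_scale: float, seed: int) -> RegisteredShape:
    """Template plus a random identity field of RMS exactly ``identity_scale``."""
    fld = IdentityField.random(template, identity_scale, seed)
    verts = template.vertices + fld.displacement(template.vertices)
    return RegisteredShape(verts.reshape(-1), template_topology_id(template))


# --------------------------------------------------------------------------
# AU fields

def _region_stats(template: TriMesh, region_id: str):
    """Centroid and taper radius of a region, fixed by the template geometry."""
    ridx = REGION_IDS.index(region_id)
    mask = region_of_points(template.vertices) == ridx
    pts = template.vertices[mask]
    centroid = pts.mean(axis=0)
    dmax = float(np.max(np.linalg.norm(pts - centroid, axis=1)))
    x_median = float(np.median(pts[:, 0]))
    return centroid, max(dmax, 1e-12), x_median


def au_field_at(points: np.ndarray, spec: AUSpec, template: TriMesh) -> np.ndarray:
    """Unit-intensity AU displacement at arbitrary on-surface ``points``.

    Cosine-tapered from the region centroid; exactly zero outside the
    region.  Defined in template coordinates, so identical for every subject.
    """
    if spec.region_id not in REGION_IDS:
        raise ValueError(f"unknown region {spec.region_id!r}")
    centroid, dmax, x_median = _region_stats(template, spec.region_id)
    ridx = REGION_IDS.index(spec.region_id)
    mask = region_of_points(points) == ridx
    field = np.zeros_like(points)
    if not np.any(mask):
        return field
    pts = points[mask]
    d = np.linalg.norm(pts - centroid, axis=1)
    taper = 0.5 * (1.0 + np.cos(np.pi * np.minimum(d / dmax, 1.0)))
    if spec.kind == "asymmetric":
        taper = np.where(pts[:, 0] >= x_median, taper, 0.0)
    if spec.kind in ("bump", "asymmetric"):
        normals = pts / np.array([_AX**2, _AY**2, _AZ**2])
        normals /= np.maximum(np.linalg.norm(normals, axis=1, keepdims=True), 1e-12)
        field[mask] = spec.magnitude * taper[:, None] * normals
    else:
        # pull: skin drawn toward the region centre bunches up, so the motion
        # mixes the in-surface pull with an equal outward-normal component —
        # a purely tangential slide of a smooth surface would be invisible to
        # a scanner's point cloud
        to_centre = centroid - pts
        norms = np.linalg.norm(to_centre, axis=1, keepdims=True)
        pull_dir = np.where(norms > 1e-9, to_centre / np.maximum(norms, 1e-12), 0.0)
        normals = pts / np.array([_AX**2, _AY**2, _AZ**2])
        normals /= np.maximum(np.linalg.norm(normals, axis=1, keepdims=True), 1e-12)
        direction = (pull_dir + normals) / np.sqrt(2.0)
        field[mask] = spec.magnitude * taper[:, None] * direction
    return field


def au_displacement_field(template: TriMesh, region_map: RegionMap, spec: AUSpec) -> np.ndarray:
    """The (m, 3) unit-intensity AU field on the template vertices."""
    del region_map  # region membership follows the fixed template rule
    return au_field_at(template.vertices, spec, template)


def apply_synthetic_au(
    shape: RegisteredShape,
    spec: AUSpec,
    intensity: float,
    template: TriMesh,
    region_map: RegionMap | None = None,
) -> RegisteredShape:
    """Activate a synthetic AU on a registered shape at ``intensity`` in [0, 1].

    The field is evaluated on template coordinates (linear in intensity and
    identical across subjects).
    """
    field = au_displacement_field(template, region_map, spec)
    return RegisteredShape(shape.vector + intensity * field.reshape(-1), shape.topology_id)


# --------------------------------------------------------------------------
# corpora

@dataclass
class ScanEntry:
    """One generated scan: raw point cloud + registered ground truth."""

    subject_id: str
    label: str
    raw: TriMesh
    registered: RegisteredShape


@dataclass
class SyntheticCorpus:
    template: TriMesh
    region_map: RegionMap
    config: SyntheticConfig
    scans: list
    identities: dict

    @property
    def topology_id(self) -> str:
        return template_topology_id(self.template)

    def registered_shapes(self):
        return [e.registered for e in self.scans]

    def neutral_scans(self):
        return [e for e in self.scans if e.label == "neutral"]

    def au_scans(self):
        return [e for e in self.scans if e.label != "neutral"]


def _raw_surface_grid(m_raw: int, rng: np.random.Generator) -> np.ndarray:
    """A jittered dense polar grid of on-surface points (no fixed order)."""
    ntheta = max(16, int(round(np.sqrt(2.0 * m_raw))))
    nr = max(4, m_raw // ntheta)
    r = np.repeat((np.arange(1, nr + 1) - 0.5) / nr, ntheta)
    th = np.tile(2.0 * np.pi * np.arange(ntheta) / ntheta, nr)
    r = np.clip(r + rng.uniform(-0.25, 0.25, r.shape) / nr, 0.0, 1.0)
    th = th + rng.uniform(-0.25, 0.25, th.shape) * 2.0 * np.pi / ntheta
    return _surface_point(r, th)


def _make_raw(
    identity: IdentityField,
    au_spec: AUSpec | None,
    intensity: float,
    template: TriMesh,
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    subject_id: str,
    label: str,
    registered: RegisteredShape,
) -> TriMesh:
    if cfg.resample:
        base_pts = _raw_surface_grid(int(round(cfg.raw_density * template.n_vertices)), rng)
        pts = base_pts + identity.displacement(base_pts)
        if au_spec is not None:
            pts = pts + intensity * au_field_at(base_pts, au_spec, template)
        pts = pts[rng.permutation(len(pts))]
        faces = np.zeros((0, 3), dtype=np.int64)
    else:
        pts = registered.points.copy()
        faces = template.faces
    nose = registered.points[0].copy()  # apex vertex index 0 on the template grid
    if cfg.noise_sigma > 0:
        pts = pts + rng.normal(scale=cfg.noise_sigma, size=pts.shape)
    return TriMesh(pts, faces, {"nose_tip": nose}, subject_id=subject_id, label=label)


def generate_corpus(config: SyntheticConfig) -> SyntheticCorpus:
    """Generate the full in-memory corpus the config describes.

    Per subject: one neutral scan plus ``scans_per_condition`` scans per AU
    spec (full intensity), each as a raw point cloud together with its
    registered ground truth on the template grid.
    """
    template, region_map = make_template(config.m, config.seed)
    topo = template_topology_id(template)
    rng = np.random.default_rng(config.seed)
    scans = []
    identities = {}
    for s in range(config.n_subjects):
        sid = f"subj{s:03d}"
        ident = IdentityField.random(template, config.identity_scale, int(rng.integers(0, 2**31 - 1)))
        neutral_reg = RegisteredShape(
            (template.vertices + ident.displacement(template.vertices)).reshape(-1), topo
        )
        identities[sid] = neutral_reg
        scans.append(ScanEntry(
            sid, "neutral",
            _make_raw(ident, None, 0.0, template, config, rng, sid, "neutral", neutral_reg),
            neutral_reg,
        ))
        for spec in config.au_specs:
            for _ in range(config.scans_per_condition):
                expr = apply_synthetic_au(neutral_reg, spec, 1.0, template, region_map)
                scans.append(ScanEntry(
                    sid, spec.au_id,
                    _make_raw(ident, spec, 1.0, template, config, rng, sid, spec.au_id, expr),
                    expr,
                ))
    return SyntheticCorpus(template, region_map, config, scans, identities)


def generate_dataset(config: SyntheticConfig, out_dir) -> Path:
    """Write the corpus to disk: raw OBJ scans, ground truth, and a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    corpus = generate_corpus(config)
    write_mesh(corpus.template, out / "template.obj")
    manifest = {
        "config": {**asdict(config), "au_specs": [asdict(a) for a in config.au_specs]},
        "topology_id": corpus.topology_id,
        "scans": [],
    }
    gt_dir = out / "ground_truth"
    gt_dir.mkdir(exist_ok=True)
    for i, entry in enumerate(corpus.scans):
        name = f"{entry.subject_id}_{entry.label}_{i:04d}"
        write_mesh(entry.raw, out / f"{name}.obj")
        np.savetxt(gt_dir / f"{name}.txt", entry.registered.vector)
        manifest["scans"].append({
            "file": f"{name}.obj",
            "ground_truth": f"ground_truth/{name}.txt",
            "subject_id": entry.subject_id,
            "label": entry.label,
        })
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
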