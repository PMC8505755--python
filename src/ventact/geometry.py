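"""Synthetic torso-biventricular geometry.

Generates a biventricular tetrahedral mesh (thick-walled truncated-ellipsoid
LV with a thinner crescent RV shell), rule-based fibre/sheet/sheet-normal
frames, candidate root-node discretisations on the endocardial surfaces, and
standard 10-electrode positions on an enclosing torso box.

Units: lengths in cm throughout; node indices are 0-based everywhere,
including on-disk files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

# surface label codes (per node)
INTERIOR = 0
LV_ENDO = 1
RV_ENDO = 2
EPI = 3

SURFACE_NAMES = {INTERIOR: "INTERIOR", LV_ENDO: "LV_ENDO", RV_ENDO: "RV_ENDO", EPI: "EPI"}

# ventricle codes (per node / candidate)
V_NONE = 0
V_LV = 1
V_RV = 2

VENTRICLE_NAMES = {V_NONE: "NONE", V_LV: "LV", V_RV: "RV"}

#: resolution tags for the root-node discretisation with their coverage
#: radii in cm (every endocardial node must have a same-ventricle candidate
#: within this distance).
COVERAGE_RADIUS_CM = {"LOW": 2.5, "HIGH": 1.5}

#: anatomy presets spanning the target myocardial volume range
#: (approximately 74-171 cm^3 across the cohort).
ANATOMY_PRESETS = {
    "small": {"axes": (2.73, 2.73, 4.64), "wall_thickness": 0.856},
    "mid_a": {"axes": (2.744, 2.744, 4.64), "wall_thickness": 0.847},
    "mid_b": {"axes": (3.093, 3.093, 5.21), "wall_thickness": 0.936},
    "large": {"axes": (3.61, 3.61, 6.08), "wall_thickness": 1.054},
}


class GeometryError(ValueError):
    """Raised for degenerate or inconsistent geometric inputs."""


@dataclass
class BiventricularMesh:
    """Tetrahedral biventricular mesh with surface labels and fibre frames.

    Attributes
    ----------
    nodes : (N, 3) float array
        Node coordinates in cm.
    elements : (M, 4) int array
        Tetrahedron node-index quadruples (positive volume ordering).
    surface_label : (N,) int array
        One of ``INTERIOR``, ``LV_ENDO``, ``RV_ENDO``, ``EPI`` per node.
    transmural : (N,) float array
        Normalised wall depth in [0, 1]; 0 on endocardium, 1 on epicardium.
    ventricle : (N,) int array
        ``V_LV`` / ``V_RV`` on endocardial nodes, ``V_NONE`` elsewhere.
    fibres, sheets, normals : (M, 3) float arrays or None
        Per-element orthonormal frame (set by :func:`assign_fibre_frames`).
    helix_angle_deg : (M,) float array or None
        Per-element fibre helix angle in degrees.
    """

    nodes: np.ndarray
    elements: np.ndarray
    surface_label: np.ndarray
    transmural: np.ndarray
    ventricle: np.ndarray
    fibres: np.ndarray | None = None
    sheets: np.ndarray | None = None
    normals: np.ndarray | None = None
    helix_angle_deg: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    @property
    def has_frames(self) -> bool:
        return self.fibres is not None

    def nodes_with_label(self, label: int) -> np.ndarray:
        return np.flatnonzero(self.surface_label == label)

    @property
    def lv_endo_nodes(self) -> np.ndarray:
        return self.nodes_with_label(LV_ENDO)

    @property
    def rv_endo_nodes(self) -> np.ndarray:
        return self.nodes_with_label(RV_ENDO)

    @property
    def epi_nodes(self) -> np.ndarray:
        return self.nodes_with_label(EPI)

    @property
    def endo_nodes(self) -> np.ndarray:
        return np.flatnonzero((self.surface_label == LV_ENDO) | (self.surface_label == RV_ENDO))

    def element_volumes(self) -> np.ndarray:
        """Signed tetrahedron volumes (cm^3); positive for valid meshes."""
        p = self.nodes[self.elements]
        return np.einsum(
            "ij,ij->i",
            np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]),
            p[:, 3] - p[:, 0],
        ) / 6.0

    def myocardial_volume(self) -> float:
        """Total mesh volume in cm^3."""
        return float(self.element_volumes().sum())

    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.elements].mean(axis=1)

    def element_mean_transmural(self) -> np.ndarray:
        return self.transmural[self.elements].mean(axis=1)

    def validate(self) -> None:
        """Check all structural invariants; raise ``GeometryError`` on failure."""
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 3:
            raise GeometryError("nodes must be (N, 3)")
        if self.elements.ndim != 2 or self.elements.shape[1] != 4:
            raise GeometryError("elements must be (M, 4)")
        if self.elements.min() < 0 or self.elements.max() >= self.n_nodes:
            raise GeometryError("element indices out of range")
        for lbl, name in ((LV_ENDO, "LV_ENDO"), (RV_ENDO, "RV_ENDO"), (EPI, "EPI")):
            if not np.any(self.surface_label == lbl):
                raise GeometryError(f"no nodes labelled {name}")
        vols = self.element_volumes()
        if np.any(vols <= 0):
            raise GeometryError(f"{int(np.sum(vols <= 0))} non-positive element volumes")
        tm = self.transmural
        if np.any(tm < 0) or np.any(tm > 1):
            raise GeometryError("transmural coordinate outside [0, 1]")
        endo = self.endo_nodes
        if np.any(tm[endo] != 0.0):
            raise GeometryError("transmural coordinate non-zero on endocardium")
        if np.any(tm[self.epi_nodes] != 1.0):
            raise GeometryError("transmural coordinate != 1 on epicardium")
        if self.has_frames:
            check_frames(self.fibres, self.sheets, self.normals)

    def copy(self) -> "BiventricularMesh":
        return dataclasses.replace(
            self,
            nodes=self.nodes.copy(),
            elements=self.elements.copy(),
            surface_label=self.surface_label.copy(),
            transmural=self.transmural.copy(),
            ventricle=self.ventricle.copy(),
            fibres=None if self.fibres is None else self.fibres.copy(),
            sheets=None if self.sheets is None else self.sheets.copy(),
            normals=None if self.normals is None else self.normals.copy(),
            helix_angle_deg=None if self.helix_angle_deg is None else self.helix_angle_deg.copy(),
            metadata=dict(self.metadata),
        )


@dataclass
class ElectrodeSet:
    """Positions (cm) of the 10 standard ECG electrodes."""

    names: tuple
    positions: np.ndarray  # (10, 3)

    STANDARD_NAMES = ("RA", "LA", "LL", "RL", "V1", "V2", "V3", "V4", "V5", "V6")

    def __post_init__(self) -> None:
        if tuple(self.names) != self.STANDARD_NAMES:
            raise GeometryError(f"electrode names must be {self.STANDARD_NAMES}")
        if self.positions.shape != (10, 3):
            raise GeometryError("positions must be (10, 3)")

    def position(self, name: str) -> np.ndarray:
        return self.positions[self.names.index(name)]


@dataclass
class CandidateRootNodes:
    """Candidate earliest-activation sites on the endocardial surfaces."""

    node_ids: np.ndarray      # (K,) mesh node indices
    ventricle: np.ndarray     # (K,) V_LV / V_RV
    resolution: str           # LOW / HIGH / HYBRID

    @property
    def n_candidates(self) -> int:
        return self.node_ids.shape[0]

    def lv_candidates(self) -> np.ndarray:
        return self.node_ids[self.ventricle == V_LV]

    def rv_candidates(self) -> np.ndarray:
        return self.node_ids[self.ventricle == V_RV]

    def positions(self, mesh: BiventricularMesh) -> np.ndarray:
        return mesh.nodes[self.node_ids]


def check_frames(f: np.ndarray, s: np.ndarray, n: np.ndarray, tol: float = 1e-9) -> None:
    for name, v in (("fibre", f), ("sheet", s), ("normal", n)):
        err = np.abs(np.linalg.norm(v, axis=1) - 1.0).max()
        if err > tol:
            raise GeometryError(f"{name} vectors not unit length (max err {err:.2e})")
    for a, b, pair in ((f, s, "f.s"), (f, n, "f.n"), (s, n, "s.n")):
        err = np.abs(np.einsum("ij,ij->i", a, b)).max()
        if err > tol:
            raise GeometryError(f"frame not orthogonal: |{pair}| max {err:.2e}")


# ---------------------------------------------------------------------------
# implicit anatomy model


class _Ellipsoid:
    def __init__(self, centre, axes):
        self.centre = np.asarray(centre, float)
        self.axes = np.asarray(axes, float)

    def q(self, x: np.ndarray) -> np.ndarray:
        """Quadric value; < 1 inside, 1 on the surface."""
        return (((x - self.centre) / self.axes) ** 2).sum(axis=-1)

    def inside(self, x: np.ndarray) -> np.ndarray:
        return self.q(x) < 1.0

    def surface_distance(self, x: np.ndarray) -> np.ndarray:
        """First-order approximate distance to the ellipsoid surface."""
        d = x - self.centre
        q = ((d / self.axes) ** 2).sum(axis=-1)
        grad = 2.0 * np.linalg.norm(d / self.axes**2, axis=-1)
        return np.abs(q - 1.0) / np.maximum(grad, 1e-12)


class _Anatomy:
    """Implicit-surface model of a biventricular myocardium.

    LV wall lies between two concentric ellipsoids (outer = the given axes,
    inner = axes shrunk by the wall thickness).  The RV is a crescent shell
    attached on the -y side: its cavity is the part of an offset inner
    ellipsoid lying outside the LV outer surface, its free wall is thinner
    than the LV wall.  Everything is truncated at the base plane z = z_base.
    """

    def __init__(self, axes, wall_thickness, rv_wall_fraction=0.6, base_fraction=0.40):
        a, b, c = axes
        t = wall_thickness
        if t <= 0 or min(a, b, c) <= 0:
            raise GeometryError("axes and wall thickness must be positive")
        if t >= min(a, b, c):
            raise GeometryError(
                f"degenerate anatomy: wall thickness {t} cm >= smallest semi-axis "
                f"{min(a, b, c)} cm leaves no cavity"
            )
        self.axes = (a, b, c)
        self.t = t
        self.z_base = base_fraction * c
        self.lv_epi = _Ellipsoid((0.0, 0.0, 0.0), (a, b, c))
        self.lv_endo = _Ellipsoid((0.0, 0.0, 0.0), (a - t, b - t, c - t))
        t_rv = rv_wall_fraction * t
        rv_axes = np.array([0.62 * a, 0.80 * b, 0.88 * c])
        rv_centre = (0.0, -0.52 * b, -0.04 * c)
        self.rv_out = _Ellipsoid(rv_centre, rv_axes)
        self.rv_in = _Ellipsoid(rv_centre, rv_axes - t_rv)

    def inside_myocardium(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(x)
        below_base = x[:, 2] <= self.z_base
        in_heart = self.lv_epi.inside(x) | self.rv_out.inside(x)
        lv_cav = self.lv_endo.inside(x)
        rv_cav = self.rv_in.inside(x) & ~self.lv_epi.inside(x)
        return below_base & in_heart & ~lv_cav & ~rv_cav

    def classify_surface(self, x: np.ndarray) -> np.ndarray:
        """Surface label for boundary points by nearest implicit surface."""
        x = np.atleast_2d(x)
        inf = np.inf
        in_lv_epi = self.lv_epi.inside(x)
        in_rv_in = self.rv_in.inside(x)
        d_lv = self.lv_endo.surface_distance(x)
        d_lv_epi = self.lv_epi.surface_distance(x)
        d_rv_in = self.rv_in.surface_distance(x)
        d_rv_out = self.rv_out.surface_distance(x)
        d_base = np.abs(x[:, 2] - self.z_base)
        # EPI: LV outer surface away from the RV, RV outer surface away from
        # the LV, or the base plane.
        d_epi = np.minimum(
            np.where(~in_rv_in, d_lv_epi, inf),
            np.where(~in_lv_epi, d_rv_out, inf),
        )
        d_epi = np.minimum(d_epi, d_base)
        # RV endo: the RV inner surface on the free wall, or the LV outer
        # surface where it faces the RV cavity (septal wall).
        d_rv = np.minimum(
            np.where(~in_lv_epi, d_rv_in, inf),
            np.where(in_rv_in, d_lv_epi, inf),
        )
        dists = np.stack([d_lv, d_rv, d_epi], axis=1)
        labels = np.array([LV_ENDO, RV_ENDO, EPI])
        return labels[np.argmin(dists, axis=1)]


# Kuhn split of the unit cube: 6 tetrahedra around the (0 -> 7) diagonal.
# Corner bitmask: bit0 = +x, bit1 = +y, bit2 = +z.
_KUHN_TETS = np.array(
    [
        [0, 1, 3, 7],
        [0, 1, 5, 7],
        [0, 2, 3, 7],
        [0, 2, 6, 7],
        [0, 4, 5, 7],
        [0, 4, 6, 7],
    ]
)


def generate_synthetic_mesh(
    axes=(4.45, 4.45, 7.5),
    wall_thickness: float = 1.3,
    edge_length: float = 0.35,
    seed: int = 0,
    rv_wall_fraction: float = 0.6,
    base_fraction: float = 0.40,
    jitter_fraction: float = 0.12,
) -> BiventricularMesh:
    """Generate a synthetic biventricular tetrahedral mesh.

    The myocardium is carved from a background grid (Kuhn-tetrahedralised
    voxels of size ``edge_length``) by the implicit two-cavity anatomy model.
    Interior nodes are jittered deterministically (``seed``) to break grid
    symmetry; surface nodes are left on-grid so labels stay stable.

    Parameters
    ----------
    axes : (3,) floats
        Semi-axes (cm) of the outer LV ellipsoid, apex-to-base along +z.
    wall_thickness : float
        LV wall thickness (cm); the RV free wall is ``rv_wall_fraction`` of it.
    edge_length : float
        Target edge length / grid spacing (cm), within [0.1, 0.5].
    seed : int
        Seed for the interior-node jitter; same seed -> bitwise-identical mesh.

    Returns
    -------
    BiventricularMesh
        A validated mesh with transmural coordinates (fibre frames are
        assigned separately by :func:`assign_fibre_frames`).
    """
    if not (0.1 <= edge_length <= 0.5):
        raise GeometryError(f"edge_length {edge_length} outside [0.1, 0.5] cm")
    anatomy = _Anatomy(axes, wall_thickness, rv_wall_fraction, base_fraction)
    h = float(edge_length)

    a, b, c = anatomy.axes
    lo = np.array([-a, -1.45 * b, -c]) - h
    hi = np.array([a, b, anatomy.z_base]) + h
    nx, ny, nz = (np.ceil((hi - lo) / h).astype(int) + 1)

    ix, iy, iz = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    grid_pts = lo + h * np.stack([ix.ravel(), iy.ravel(), iz.ravel()], axis=1)

    def gid(i, j, k):
        return (i * ny + j) * nz + k

    # assemble all candidate tets from the background grid
    ci, cj, ck = np.meshgrid(
        np.arange(nx - 1), np.arange(ny - 1), np.arange(nz - 1), indexing="ij"
    )
    ci, cj, ck = ci.ravel(), cj.ravel(), ck.ravel()
    corner_ids = np.empty((ci.size, 8), dtype=np.int64)
    for corner in range(8):
        dx, dy, dz = corner & 1, (corner >> 1) & 1, (corner >> 2) & 1
        corner_ids[:, corner] = gid(ci + dx, cj + dy, ck + dz)
    tets = corner_ids[:, _KUHN_TETS].reshape(-1, 4)

    centroids = grid_pts[tets].mean(axis=1)
    keep = anatomy.inside_myocardium(centroids)
    tets = tets[keep]
    if tets.size == 0:
        raise GeometryError("empty myocardium: check axes/thickness")

    # compact node numbering
    used, inverse = np.unique(tets, return_inverse=True)
    elements = inverse.reshape(-1, 4).astype(np.int64)
    nodes = grid_pts[used].copy()

    # drop minor disconnected components (thin-wall voxelisation artefacts)
    n = nodes.shape[0]
    e = elements
    pairs = np.concatenate([e[:, [0, 1]], e[:, [0, 2]], e[:, [0, 3]],
                            e[:, [1, 2]], e[:, [1, 3]], e[:, [2, 3]]])
    adj = coo_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    n_comp, comp = connected_components(adj, directed=False)
    if n_comp > 1:
        sizes = np.bincount(comp)
        main = int(np.argmax(sizes))
        elem_keep = np.all(comp[elements] == main, axis=1)
        elements = elements[elem_keep]
        used2, inverse2 = np.unique(elements, return_inverse=True)
        elements = inverse2.reshape(-1, 4).astype(np.int64)
        nodes = nodes[used2]

    # boundary faces -> boundary nodes
    faces = np.sort(
        np.concatenate([elements[:, [1, 2, 3]], elements[:, [0, 2, 3]],
                        elements[:, [0, 1, 3]], elements[:, [0, 1, 2]]]),
        axis=1,
    )
    uniq_faces, counts = np.unique(faces, axis=0, return_counts=True)
    boundary_nodes = np.unique(uniq_faces[counts == 1])

    surface_label = np.full(nodes.shape[0], INTERIOR, dtype=np.int8)
    surface_label[boundary_nodes] = anatomy.classify_surface(nodes[boundary_nodes])

    # deterministic jitter on interior nodes only
    rng = np.random.default_rng(seed)
    interior = np.flatnonzero(surface_label == INTERIOR)
    jitter = rng.uniform(-jitter_fraction * h, jitter_fraction * h, size=(interior.size, 3))
    nodes[interior] += jitter

    # fix orientation: ensure positive volumes
    p = nodes[elements]
    vol = np.einsum(
        "ij,ij->i", np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), p[:, 3] - p[:, 0]
    )
    flip = vol < 0
    elements[flip] = elements[flip][:, [0, 1, 3, 2]]

    # transmural coordinate: distance-ratio between endo and epi node sets
    endo_mask = (surface_label == LV_ENDO) | (surface_label == RV_ENDO)
    epi_mask = surface_label == EPI
    if not endo_mask.any() or not epi_mask.any():
        raise GeometryError("failed to label endocardial/epicardial surfaces")
    d_endo, _ = cKDTree(nodes[endo_mask]).query(nodes)
    d_epi, _ = cKDTree(nodes[epi_mask]).query(nodes)
    transmural = d_endo / (d_endo + d_epi)
    transmural[endo_mask] = 0.0
    transmural[epi_mask] = 1.0

    ventricle = np.full(nodes.shape[0], V_NONE, dtype=np.int8)
    ventricle[surface_label == LV_ENDO] = V_LV
    ventricle[surface_label == RV_ENDO] = V_RV

    mesh = BiventricularMesh(
        nodes=nodes,
        elements=elements,
        surface_label=surface_label,
        transmural=transmural,
        ventricle=ventricle,
        metadata={
            "axes": tuple(float(v) for v in axes),
            "wall_thickness": float(wall_thickness),
            "edge_length": h,
            "seed": int(seed),
            "rv_wall_fraction": float(rv_wall_fraction),
            "base_fraction": float(base_fraction),
        },
    )
    mesh.metadata["myocardial_volume_cm3"] = mesh.myocardial_volume()
    mesh.validate()
    return mesh


# ---------------------------------------------------------------------------
# rule-based fibre frames


def _element_gradients(nodes: np.ndarray, elements: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Per-element gradient of a linear nodal field on tetrahedra."""
    p = nodes[elements]
    v = values[elements]
    # solve J^T g = dv with J rows = edge vectors from node 0
    edges = p[:, 1:] - p[:, :1]           # (M, 3, 3)
    dv = v[:, 1:] - v[:, :1]              # (M, 3)
    return np.linalg.solve(edges, dv[..., None])[..., 0]


def assign_fibre_frames(
    mesh: BiventricularMesh,
    endo_angle_deg: float = 60.0,
    epi_angle_deg: float = -60.0,
) -> BiventricularMesh:
    """Assign per-element orthonormal fibre/sheet/sheet-normal frames.

    The helix angle interpolates linearly in the element's mean transmural
    coordinate d: alpha(d) = endo_angle + d * (epi_angle - endo_angle).  The
    fibre lies in the local circumferential-longitudinal plane rotated by
    alpha, the sheet vector is transmural, and the sheet-normal completes a
    right-handed orthonormal triple.
    """
    if mesh.transmural is None:
        raise GeometryError("mesh has no transmural coordinates")
    mesh = mesh.copy()
    d = mesh.element_mean_transmural()
    alpha = np.deg2rad(endo_angle_deg + d * (epi_angle_deg - endo_angle_deg))

    grad = _element_gradients(mesh.nodes, mesh.elements, mesh.transmural)
    gnorm = np.linalg.norm(grad, axis=1)
    centroids = mesh.element_centroids()
    # transmural axis: gradient of the transmural field; radial fallback
    # where the field is locally flat
    radial = centroids.copy()
    radial[:, 2] = 0.0
    rnorm = np.linalg.norm(radial, axis=1)
    radial[rnorm < 1e-9] = [1.0, 0.0, 0.0]
    radial /= np.maximum(np.linalg.norm(radial, axis=1), 1e-12)[:, None]
    w = np.where(gnorm[:, None] > 1e-9, grad / np.maximum(gnorm, 1e-12)[:, None], radial)

    z = np.array([0.0, 0.0, 1.0])
    lon = z - w * w[:, 2:3]
    lnorm = np.linalg.norm(lon, axis=1)
    # where the transmural axis is along z (apex cap), fall back to x
    bad = lnorm < 1e-9
    if bad.any():
        alt = np.array([1.0, 0.0, 0.0]) - w[bad] * w[bad, 0:1]
        lon[bad] = alt
        lnorm = np.linalg.norm(lon, axis=1)
    lon /= lnorm[:, None]
    circ = np.cross(w, lon)

    f = np.cos(alpha)[:, None] * circ + np.sin(alpha)[:, None] * lon
    s = w
    n = np.cross(f, s)

    mesh.fibres = f
    mesh.sheets = s
    mesh.normals = n
    mesh.helix_angle_deg = np.rad2deg(alpha)
    check_frames(f, s, n)
    return mesh


# ---------------------------------------------------------------------------
# root-node candidate discretisation


def _farthest_point_sample(points: np.ndarray, radius: float) -> np.ndarray:
    """Greedy farthest-point sampling until every point is within ``radius``
    of a sample.  Deterministic: starts from the point closest to the
    centroid; ties broken by index."""
    centroid = points.mean(axis=0)
    d0 = np.linalg.norm(points - centroid, axis=1)
    first = int(np.argmin(d0))
    chosen = [first]
    dist = np.linalg.norm(points - points[first], axis=1)
    while dist.max() > radius:
        nxt = int(np.argmax(dist))
        chosen.append(nxt)
        dist = np.minimum(dist, np.linalg.norm(points - points[nxt], axis=1))
    return np.array(chosen, dtype=np.int64)


def discretise_root_candidates(mesh: BiventricularMesh, resolution: str = "LOW") -> CandidateRootNodes:
    """Build candidate root nodes covering each endocardial surface.

    ``LOW`` guarantees a same-ventricle candidate within 2.5 cm of every
    endocardial node, ``HIGH`` within 1.5 cm; ``HYBRID`` combines the LOW
    radius on the RV with the HIGH radius on the LV.
    """
    resolution = resolution.upper()
    if resolution == "HYBRID":
        radii = {V_LV: COVERAGE_RADIUS_CM["HIGH"], V_RV: COVERAGE_RADIUS_CM["LOW"]}
    elif resolution in COVERAGE_RADIUS_CM:
        r = COVERAGE_RADIUS_CM[resolution]
        radii = {V_LV: r, V_RV: r}
    else:
        raise GeometryError(f"unknown resolution {resolution!r}")

    ids, vents = [], []
    for vcode, label in ((V_LV, LV_ENDO), (V_RV, RV_ENDO)):
        surf = mesh.nodes_with_label(label)
        if surf.size == 0:
            raise GeometryError(f"empty endocardial surface {SURFACE_NAMES[label]}")
        local = _farthest_point_sample(mesh.nodes[surf], radii[vcode])
        ids.append(surf[local])
        vents.append(np.full(local.size, vcode, dtype=np.int8))
    return CandidateRootNodes(
        node_ids=np.concatenate(ids),
        ventricle=np.concatenate(vents),
        resolution=resolution,
    )


def coverage_distance(mesh: BiventricularMesh, candidates: CandidateRootNodes) -> dict:
    """Max distance from any endocardial node to its nearest same-ventricle
    candidate, per ventricle (cm)."""
    out = {}
    for vcode, label, name in ((V_LV, LV_ENDO, "LV"), (V_RV, RV_ENDO, "RV")):
        surf = mesh.nodes_with_label(label)
        cand = candidates.node_ids[candidates.ventricle == vcode]
        d, _ = cKDTree(mesh.nodes[cand]).query(mesh.nodes[surf])
        out[name] = float(d.max())
    return out


# ---------------------------------------------------------------------------
# electrodes


def place_electrodes(mesh: BiventricularMesh, torso_scale: float = 1.0) -> ElectrodeSet:
    """Place the 10 standard electrodes on a torso box enclosing the heart.

    Anterior is +x, patient-left is +y, base is +z.  Precordial electrodes
    V1-V6 sweep a left-anterior arc; limb electrodes sit at the torso box
    corners.  All offsets from the heart centroid scale with ``torso_scale``.
    """
    centre = mesh.nodes.mean(axis=0)
    half = (mesh.nodes.max(axis=0) - mesh.nodes.min(axis=0)) / 2.0
    hx, hy, hz = half * 1.6  # torso box comfortably outside the heart
    r = 1.5 * max(hx, hy)

    offsets = {
        "RA": np.array([0.0, -1.2 * hy, 1.5 * hz]),
        "LA": np.array([0.0, 1.2 * hy, 1.5 * hz]),
        "LL": np.array([0.0, 1.2 * hy, -1.8 * hz]),
        "RL": np.array([0.0, -1.2 * hy, -1.8 * hz]),
    }
    arc_deg = [-30.0, -15.0, 0.0, 15.0, 35.0, 55.0]
    arc_z = [0.25, 0.15, 0.05, -0.05, -0.10, -0.15]
    for i, (ang, fz) in enumerate(zip(arc_deg, arc_z), start=1):
        th = np.deg2rad(ang)
        offsets[f"V{i}"] = np.array([r * np.cos(th), r * np.sin(th), fz * hz])

    names = ElectrodeSet.STANDARD_NAMES
    positions = np.stack([centre + torso_scale * offsets[nm] for nm in names])
    return ElectrodeSet(names=names, positions=positions)


# ---------------------------------------------------------------------------
# I/O


def save_mesh_vtk(mesh: BiventricularMesh, path) -> None:
    """Write the mesh as a VTK legacy ASCII unstructured grid."""
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nbiventricular mesh\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} double\n")
        np.savetxt(fh, mesh.nodes, fmt="%.17g")
        m = mesh.n_elements
        fh.write(f"CELLS {m} {5 * m}\n")
        cells = np.column_stack([np.full(m, 4, dtype=np.int64), mesh.elements])
        np.savetxt(fh, cells, fmt="%d")
        fh.write(f"CELL_TYPES {m}\n")
        np.savetxt(fh, np.full(m, 10, dtype=np.int64), fmt="%d")
        fh.write(f"POINT_DATA {mesh.n_nodes}\n")
        fh.write("SCALARS surface_label int 1\nLOOKUP_TABLE default\n")
        np.savetxt(fh, mesh.surface_label, fmt="%d")
        fh.write("SCALARS transmural double 1\nLOOKUP_TABLE default\n")
        np.savetxt(fh, mesh.transmural, fmt="%.17g")
        fh.write("SCALARS ventricle int 1\nLOOKUP_TABLE default\n")
        np.savetxt(fh, mesh.ventricle, fmt="%d")
        if mesh.has_frames:
            fh.write(f"CELL_DATA {m}\n")
            for name, arr in (("fibre", mesh.fibres), ("sheet", mesh.sheets), ("normal", mesh.normals)):
                fh.write(f"VECTORS {name} double\n")
                np.savetxt(fh, arr, fmt="%.17g")


def load_mesh_vtk(path) -> BiventricularMesh:
    """Read a mesh written by :func:`save_mesh_vtk`."""
    with open(path) as fh:
        tokens = fh.read().split()

    def find(keyword, start=0):
        for i in range(start, len(tokens)):
            if tokens[i] == keyword:
                return i
        raise GeometryError(f"VTK keyword {keyword} not found in {path}")

    i = find("POINTS")
    n = int(tokens[i + 1])
    pts = np.array(tokens[i + 3 : i + 3 + 3 * n], dtype=float).reshape(n, 3)
    i = find("CELLS")
    m = int(tokens[i + 1])
    cells = np.array(tokens[i + 3 : i + 3 + 5 * m], dtype=np.int64).reshape(m, 5)[:, 1:]

    def read_scalar(name, dtype):
        j = find(name)
        # SCALARS <name> <type> 1 / LOOKUP_TABLE default
        start = j + 5
        return np.array(tokens[start : start + n], dtype=dtype)

    surface = read_scalar("surface_label", np.int8)
    transmural = read_scalar("transmural", float)
    ventricle = read_scalar("ventricle", np.int8)

    fibres = sheets = normals = None
    try:
        j = find("CELL_DATA")
    except GeometryError:
        j = None
    if j is not None:
        def read_vec(name):
            k = find(name)
            start = k + 2
            return np.array(tokens[start : start + 3 * m], dtype=float).reshape(m, 3)
        fibres, sheets, normals = read_vec("fibre"), read_vec("sheet"), read_vec("normal")

    return BiventricularMesh(
        nodes=pts, elements=cells, surface_label=surface,
        transmural=transmural, ventricle=ventricle,
        fibres=fibres, sheets=sheets, normals=normals,
    )


def save_mesh_csv(mesh: BiventricularMesh, directory) -> None:
    """Write nodes.csv, elements.csv, labels.csv into ``directory``."""
    import os

    os.makedirs(directory, exist_ok=True)
    np.savetxt(
        os.path.join(directory, "nodes.csv"), mesh.nodes, delimiter=",",
        header="x,y,z", comments="", fmt="%.17g",
    )
    np.savetxt(
        os.path.join(directory, "elements.csv"), mesh.elements, delimiter=",",
        header="n0,n1,n2,n3", comments="", fmt="%d",
    )
    labels = np.column_stack([mesh.surface_label, mesh.ventricle, mesh.transmural])
    np.savetxt(
        os.path.join(directory, "labels.csv"), labels, delimiter=",",
        header="surface_label,ventricle,transmural", comments="", fmt="%.17g",
    )


def load_mesh_csv(directory) -> BiventricularMesh:
    import os

    nodes = np.loadtxt(os.path.join(directory, "nodes.csv"), delimiter=",", skiprows=1)
    elements = np.loadtxt(
        os.path.join(directory, "elements.csv"), delimiter=",", skiprows=1, dtype=np.int64
    )
    labels = np.loadtxt(os.path.join(directory, "labels.csv"), delimiter=",", skiprows=1)
    return BiventricularMesh(
        nodes=nodes,
        elements=elements,
        surface_label=labels[:, 0].astype(np.int8),
        transmural=labels[:, 2],
        ventricle=labels[:, 1].astype(np.int8),
    )


def save_electrodes_csv(electrodes: ElectrodeSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("name,x,y,z\n")
        for nm, p in zip(electrodes.names, electrodes.positions):
            fh.write(f"{nm},{p[0]:.17g},{p[1]:.17g},{p[2]:.17g}\n")


def load_electrodes_csv(path) -> ElectrodeSet:
    names, rows = [], []
    with open(path) as fh:
        next(fh)
        for line in fh:
            parts = line.strip().split(",")
            names.append(parts[0])
            rows.append([float(v) for v in parts[1:4]])
    return ElectrodeSet(names=tuple(names), positions=np.array(rows))


def save_candidates_csv(candidates: CandidateRootNodes, path) -> None:
    with open(path, "w") as fh:
        fh.write("candidate_id,node_id,ventricle\n")
        for i, (nid, v) in enumerate(zip(candidates.node_ids, candidates.ventricle)):
            fh.write(f"{i},{nid},{VENTRICLE_NAMES[int(v)]}\n")


def load_candidates_csv(path, resolution: str = "LOW") -> CandidateRootNodes:
    ids, vents = [], []
    name_to_code = {v: k for k, v in VENTRICLE_NAMES.items()}
    with open(path) as fh:
        next(fh)
        for line in fh:
            _, nid, vname = line.strip().split(",")
            ids.append(int(nid))
            vents.append(name_to_code[vname])
    return CandidateRootNodes(
        node_ids=np.array(ids, dtype=np.int64),
        ventricle=np.array(vents, dtype=np.int8),
        resolution=resolution,
    )
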