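"""Anisotropic graph-Eikonal activation simulator.

Activation times are computed by multi-source Dijkstra shortest paths on the
mesh edge graph.  Edge travel times use an orthotropic metric built from the
local fibre/sheet/sheet-normal frame in the myocardium and an isotropic fast
speed on edges lying within one endocardial surface.

Time unit: ms.  Speeds: cm/s.  t[ms] = 1000 * L[cm] / v[cm/s].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.csgraph import dijkstra

from ventact.geometry import (
    LV_ENDO,
    RV_ENDO,
    BiventricularMesh,
    CandidateRootNodes,
)

#: physiological bounds (cm/s)
ENDO_SPEED_BOUNDS = (100.0, 200.0)
MYO_SPEED_BOUNDS = (25.0, 90.0)
_ORDER_TOL = 1e-9

#: active root-node count range
ROOT_COUNT_RANGE = (6, 10)


class EikonalError(RuntimeError):
    pass


@dataclass(frozen=True)
class ConductionSpeeds:
    """The four conduction speeds (cm/s).

    Invariants: endocardial in [100, 200]; 25 <= sheet_normal <= sheet <=
    fibre <= 90 (ordering enforced with 1e-9 tie tolerance).
    """

    endocardial: float
    fibre: float
    sheet: float
    sheet_normal: float

    def __post_init__(self):
        lo, hi = ENDO_SPEED_BOUNDS
        if not (lo <= self.endocardial <= hi):
            raise ValueError(f"endocardial speed {self.endocardial} outside [{lo}, {hi}] cm/s")
        mlo, mhi = MYO_SPEED_BOUNDS
        for name, v in (("fibre", self.fibre), ("sheet", self.sheet), ("sheet_normal", self.sheet_normal)):
            if not (mlo <= v <= mhi):
                raise ValueError(f"{name} speed {v} outside [{mlo}, {mhi}] cm/s")
        if self.fibre < self.sheet - _ORDER_TOL or self.sheet < self.sheet_normal - _ORDER_TOL:
            raise ValueError(
                "speed ordering violated: need fibre >= sheet >= sheet_normal, got "
                f"{self.fibre}/{self.sheet}/{self.sheet_normal}"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.endocardial, self.fibre, self.sheet, self.sheet_normal])

    @classmethod
    def from_array(cls, arr) -> "ConductionSpeeds":
        return cls(float(arr[0]), float(arr[1]), float(arr[2]), float(arr[3]))

    def scaled(self, c: float) -> "ConductionSpeeds":
        """Speeds multiplied by c (bypasses bound checks; for scaling laws)."""
        obj = object.__new__(ConductionSpeeds)
        object.__setattr__(obj, "endocardial", self.endocardial * c)
        object.__setattr__(obj, "fibre", self.fibre * c)
        object.__setattr__(obj, "sheet", self.sheet * c)
        object.__setattr__(obj, "sheet_normal", self.sheet_normal * c)
        return obj


@dataclass
class ParameterSet:
    """One candidate solution: four speeds + binary root-node activation."""

    speeds: ConductionSpeeds
    root_active: np.ndarray  # boolean over candidate root nodes

    def __post_init__(self):
        self.root_active = np.asarray(self.root_active, dtype=bool)

    @property
    def n_active(self) -> int:
        return int(self.root_active.sum())

    def validate(self, check_count: bool = True) -> None:
        if check_count:
            lo, hi = ROOT_COUNT_RANGE
            if not (lo <= self.n_active <= hi):
                raise ValueError(f"active root count {self.n_active} outside [{lo}, {hi}]")

    def as_vector(self) -> np.ndarray:
        """Full parameter vector (4 speeds + activation bits) for duplicate tests."""
        return np.concatenate([self.speeds.as_array(), self.root_active.astype(float)])

    def copy(self) -> "ParameterSet":
        return ParameterSet(speeds=self.speeds, root_active=self.root_active.copy())


@dataclass
class ActivationMap:
    """Per-node activation times in ms.

    ``node_ids`` identifies the mesh nodes the times refer to (the full mesh
    for simulator output; an epicardial subset after restriction).
    """

    times_ms: np.ndarray
    node_ids: np.ndarray
    params: ParameterSet | None = None

    @property
    def n_nodes(self) -> int:
        return self.times_ms.shape[0]

    def restricted_to(self, node_ids: np.ndarray) -> "ActivationMap":
        pos = {int(n): i for i, n in enumerate(self.node_ids)}
        try:
            idx = np.array([pos[int(n)] for n in node_ids], dtype=np.int64)
        except KeyError as exc:
            raise EikonalError(f"node {exc} not present in activation map") from exc
        return ActivationMap(
            times_ms=self.times_ms[idx],
            node_ids=np.asarray(node_ids, dtype=np.int64),
            params=self.params,
        )


@dataclass
class PropagationGraph:
    """Precomputed edge graph with per-edge geometric metric terms.

    ``proj_sq`` columns hold (e.f)^2, (e.s)^2, (e.n)^2 for the edge vector e
    against the edge-averaged orthonormal frame; ``length`` is |e| in cm and
    ``endocardial`` flags edges with both endpoints on the same endocardial
    surface.
    """

    n_nodes: int
    edges: np.ndarray        # (E, 2) int, i < j
    proj_sq: np.ndarray      # (E, 3)
    length: np.ndarray       # (E,)
    endocardial: np.ndarray  # (E,) bool

    def edge_times_ms(self, speeds: ConductionSpeeds) -> np.ndarray:
        v = np.array([speeds.fibre, speeds.sheet, speeds.sheet_normal])
        t_myo = 1000.0 * np.sqrt(self.proj_sq @ (1.0 / v**2))
        t_endo = 1000.0 * self.length / speeds.endocardial
        return np.where(self.endocardial, t_endo, t_myo)

    def weight_matrix(self, speeds: ConductionSpeeds) -> csr_matrix:
        w = self.edge_times_ms(speeds)
        i, j = self.edges[:, 0], self.edges[:, 1]
        return coo_matrix(
            (np.concatenate([w, w]), (np.concatenate([i, j]), np.concatenate([j, i]))),
            shape=(self.n_nodes, self.n_nodes),
        ).tocsr()


def edge_traversal_time(
    edge_vector: np.ndarray,
    frame: np.ndarray,
    speeds: ConductionSpeeds,
    endocardial_edge: bool = False,
) -> float:
    """Travel time (ms) of one edge.

    Myocardial edges: t = 1000 * sqrt(e^T M e) with
    M = f f^T / v_f^2 + s s^T / v_s^2 + n n^T / v_n^2.
    Endocardial edges: t = 1000 * |e| / v_endo.
    """
    e = np.asarray(edge_vector, dtype=float)
    norm = np.linalg.norm(e)
    if norm == 0.0:
        raise EikonalError("zero-length edge")
    if endocardial_edge:
        return float(1000.0 * norm / speeds.endocardial)
    f, s, n = np.asarray(frame, dtype=float)
    q = (
        (e @ f) ** 2 / speeds.fibre**2
        + (e @ s) ** 2 / speeds.sheet**2
        + (e @ n) ** 2 / speeds.sheet_normal**2
    )
    return float(1000.0 * np.sqrt(q))


def _node_frames(mesh: BiventricularMesh) -> tuple[np.ndarray, np.ndarray]:
    """Volume-weighted per-node average of element fibre and sheet vectors."""
    vols = np.abs(mesh.element_volumes())
    n = mesh.n_nodes
    f_acc = np.zeros((n, 3))
    s_acc = np.zeros((n, 3))
    wf = vols[:, None] * mesh.fibres
    ws = vols[:, None] * mesh.sheets
    for k in range(4):
        np.add.at(f_acc, mesh.elements[:, k], wf)
        np.add.at(s_acc, mesh.elements[:, k], ws)
    return f_acc, s_acc


def _orthonormalise(f: np.ndarray, s: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    fn = np.linalg.norm(f, axis=1)
    f = f / np.maximum(fn, 1e-30)[:, None]
    s = s - f * np.einsum("ij,ij->i", s, f)[:, None]
    sn = np.linalg.norm(s, axis=1)
    s = s / np.maximum(sn, 1e-30)[:, None]
    return f, s, np.cross(f, s)


def build_propagation_graph(
    mesh: BiventricularMesh, neighbourhood_order: int = 2
) -> PropagationGraph:
    """Build the Dijkstra propagation graph for a mesh with fibre frames.

    ``neighbourhood_order=1`` uses element edges only; ``2`` augments with
    neighbours-of-neighbours within each node's element star, which reduces
    the graph-metrication error of the shortest-path approximation.
    """
    if not mesh.has_frames:
        raise EikonalError("mesh has no fibre frames; call assign_fibre_frames first")
    n = mesh.n_nodes
    e = mesh.elements
    pairs = np.concatenate([e[:, [0, 1]], e[:, [0, 2]], e[:, [0, 3]],
                            e[:, [1, 2]], e[:, [1, 3]], e[:, [2, 3]]])
    pairs = np.sort(pairs, axis=1)
    adj = coo_matrix(
        (np.ones(len(pairs), dtype=np.int8), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    adj = ((adj + adj.T) > 0).astype(np.int8)
    if neighbourhood_order == 2:
        adj2 = ((adj @ adj) > 0).astype(np.int8)
        full = ((adj + adj2) > 0).tocoo()
    elif neighbourhood_order == 1:
        full = adj.tocoo()
    else:
        raise EikonalError("neighbourhood_order must be 1 or 2")
    mask = full.row < full.col
    edges = np.column_stack([full.row[mask], full.col[mask]]).astype(np.int64)

    vec = mesh.nodes[edges[:, 1]] - mesh.nodes[edges[:, 0]]
    length = np.linalg.norm(vec, axis=1)
    if np.any(length == 0):
        raise EikonalError("zero-length edge in propagation graph")

    f_acc, s_acc = _node_frames(mesh)
    f_e = f_acc[edges[:, 0]] + f_acc[edges[:, 1]]
    s_e = s_acc[edges[:, 0]] + s_acc[edges[:, 1]]
    f_e, s_e, n_e = _orthonormalise(f_e, s_e)

    proj_sq = np.column_stack([
        np.einsum("ij,ij->i", vec, f_e) ** 2,
        np.einsum("ij,ij->i", vec, s_e) ** 2,
        np.einsum("ij,ij->i", vec, n_e) ** 2,
    ])

    lbl = mesh.surface_label
    li, lj = lbl[edges[:, 0]], lbl[edges[:, 1]]
    endo = (li == lj) & ((li == LV_ENDO) | (li == RV_ENDO))

    return PropagationGraph(
        n_nodes=n, edges=edges, proj_sq=proj_sq, length=length, endocardial=endo
    )


def shortest_times(
    n_nodes: int, edges: np.ndarray, weights: np.ndarray, sources: np.ndarray
) -> np.ndarray:
    """Multi-source Dijkstra times on an undirected weighted graph.

    All sources start at time 0; returns the earliest arrival per node
    (inf for unreachable nodes).
    """
    edges = np.asarray(edges, dtype=np.int64)
    weights = np.asarray(weights, dtype=float)
    i, j = edges[:, 0], edges[:, 1]
    g = coo_matrix(
        (np.concatenate([weights, weights]), (np.concatenate([i, j]), np.concatenate([j, i]))),
        shape=(n_nodes, n_nodes),
    ).tocsr()
    return dijkstra(g, directed=False, indices=np.asarray(sources, dtype=np.int64), min_only=True)


def simulate_activation(
    mesh: BiventricularMesh,
    candidates: CandidateRootNodes,
    params: ParameterSet,
    graph: PropagationGraph | None = None,
) -> ActivationMap:
    """Simulate the activation time map for one parameter set.

    All active root nodes fire at t = 0; times elsewhere are shortest-path
    travel times under the anisotropic edge metric.  Passing a prebuilt
    ``graph`` skips the (speed-independent) graph construction.
    """
    if params.n_active < 1:
        raise EikonalError("at least one active root node required")
    if graph is None:
        graph = build_propagation_graph(mesh)
    sources = candidates.node_ids[params.root_active]
    w = graph.edge_times_ms(params.speeds)
    times = shortest_times(graph.n_nodes, graph.edges, w, sources)
    if np.any(np.isinf(times)):
        bad = int(np.flatnonzero(np.isinf(times))[0])
        raise EikonalError(f"node {bad} unreachable from active root nodes")
    return ActivationMap(times_ms=times, node_ids=np.arange(graph.n_nodes), params=params)


def extract_epicardial_map(atm: ActivationMap, mesh: BiventricularMesh) -> ActivationMap:
    """Restrict an activation map to the nodes labelled EPI."""
    epi = mesh.epi_nodes
    keep = epi[np.isin(epi, atm.node_ids)]
    return atm.restricted_to(keep)


def save_activation_csv(atm: ActivationMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("node_id,activation_time_ms\n")
        for nid, t in zip(atm.node_ids, atm.times_ms):
            fh.write(f"{nid},{t:.17g}\n")


def load_activation_csv(path) -> ActivationMap:
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    data = np.atleast_2d(data)
    return ActivationMap(times_ms=data[:, 1], node_ids=data[:, 0].astype(np.int64))
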