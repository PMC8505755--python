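"""Shared fixtures: session-scoped meshes and brute-force oracle helpers."""

import numpy as np
import pytest

from ventact.geometry import (
    ANATOMY_PRESETS,
    EPI,
    LV_ENDO,
    RV_ENDO,
    BiventricularMesh,
    assign_fibre_frames,
    discretise_root_candidates,
    generate_synthetic_mesh,
    place_electrodes,
)
from ventact.eikonal import build_propagation_graph


@pytest.fixture(scope="session")
def mesh_small():
    p = ANATOMY_PRESETS["small"]
    return assign_fibre_frames(generate_synthetic_mesh(
        axes=p["axes"], wall_thickness=p["wall_thickness"], edge_length=0.45, seed=1
    ))


@pytest.fixture(scope="session")
def candidates_low(mesh_small):
    return discretise_root_candidates(mesh_small, "LOW")


@pytest.fixture(scope="session")
def candidates_high(mesh_small):
    return discretise_root_candidates(mesh_small, "HIGH")


@pytest.fixture(scope="session")
def electrodes(mesh_small):
    return place_electrodes(mesh_small)


@pytest.fixture(scope="session")
def graph_small(mesh_small):
    return build_propagation_graph(mesh_small)


@pytest.fixture(scope="session")
def mesh_coarse():
    """~2,500-node mesh for the SMC-ABC acceptance runs."""
    p = ANATOMY_PRESETS["mid_b"]
    return assign_fibre_frames(generate_synthetic_mesh(
        axes=p["axes"], wall_thickness=p["wall_thickness"], edge_length=0.42, seed=1
    ))


# Kuhn split used to build convex grid meshes for metrication tests
_KUHN = np.array([[0, 1, 3, 7], [0, 1, 5, 7], [0, 2, 3, 7],
                  [0, 2, 6, 7], [0, 4, 5, 7], [0, 4, 6, 7]])


def make_grid_mesh(n: int = 7, h: float = 0.5) -> BiventricularMesh:
    """Convex block of Kuhn tetrahedra with constant axis-aligned frames."""
    ix, iy, iz = np.meshgrid(range(n), range(n), range(n), indexing="ij")
    pts = h * np.stack([ix.ravel(), iy.ravel(), iz.ravel()], 1).astype(float)

    def gid(i, j, k):
        return (i * n + j) * n + k

    ci, cj, ck = np.meshgrid(range(n - 1), range(n - 1), range(n - 1), indexing="ij")
    ci, cj, ck = ci.ravel(), cj.ravel(), ck.ravel()
    corners = np.empty((ci.size, 8), np.int64)
    for c in range(8):
        corners[:, c] = gid(ci + (c & 1), cj + ((c >> 1) & 1), ck + ((c >> 2) & 1))
    tets = corners[:, _KUHN].reshape(-1, 4)
    m = tets.shape[0]
    npts = pts.shape[0]
    lbl = np.zeros(npts, np.int8)
    lbl[0], lbl[1], lbl[2] = LV_ENDO, RV_ENDO, EPI  # placate label invariants
    return BiventricularMesh(
        nodes=pts, elements=tets, surface_label=lbl,
        transmural=np.zeros(npts), ventricle=np.zeros(npts, np.int8),
        fibres=np.tile([1.0, 0.0, 0.0], (m, 1)),
        sheets=np.tile([0.0, 1.0, 0.0], (m, 1)),
        normals=np.tile([0.0, 0.0, 1.0], (m, 1)),
    )


def brute_force_shortest(n_nodes, edges, weights, sources):
    """All-simple-paths minimum travel times (exponential; tiny graphs only)."""
    adj = [[] for _ in range(n_nodes)]
    for (i, j), w in zip(edges, weights):
        adj[i].append((j, w))
        adj[j].append((i, w))
    best = np.full(n_nodes, np.inf)
    for s in sources:
        best[s] = 0.0

    def dfs(node, cost, visited):
        for nxt, w in adj[node]:
            if nxt in visited:
                continue
            c = cost + w
            if c < best[nxt]:
                best[nxt] = c
            dfs(nxt, c, visited | {nxt})

    for s in sources:
        dfs(s, 0.0, {s})
    return best


def random_connected_graph(rng, max_nodes=10, max_edges=20):
    """Random connected weighted graph (guaranteed spanning tree + extras)."""
    n = int(rng.integers(2, max_nodes + 1))
    edges = set()
    for v in range(1, n):
        u = int(rng.integers(0, v))
        edges.add((u, v))
    extra = int(rng.integers(0, max_edges - len(edges) + 1))
    for _ in range(extra):
        u, v = rng.integers(0, n, 2)
        if u != v:
            edges.add((min(u, v), max(u, v)))
    edges = sorted(edges)
    weights = rng.uniform(0.1, 5.0, len(edges))
    return n, np.array(edges), weights


def brute_force_dtw(a, b, cfg):
    """Exhaustive admissible-path enumeration (branch-and-bound pruned).

    Returns (min total cost, cell count of the minimising path); infeasible
    pairs give (inf, None).  Semantics mirror the documented DP contract but
    are implemented independently.
    """
    from ventact.discrepancy import band_halfwidth, resolved_penalties

    la, lb = len(a), len(b)
    pen0, pen1 = resolved_penalties(np.asarray(b, float), cfg)
    h0, h1 = band_halfwidth(lb, cfg)
    denom = max(la + lb - 2, 1)
    slope = (la - 1) / (lb - 1) if lb > 1 else 0.0
    best = [np.inf, None]

    def admissible(i, j):
        u = (i + j) / denom
        return lb <= 1 or abs(i - j * slope) <= h0 + (h1 - h0) * u

    def local(i, j):
        d = a[i] - b[j]
        return d * d if cfg.local_cost == "sq" else abs(d)

    def penalty(i, j):
        u = (i + j) / denom
        return pen0 + (pen1 - pen0) * u

    def rec(i, j, cost, run_dir, run_len, ncells):
        if cost >= best[0]:
            return
        if i == la - 1 and j == lb - 1:
            best[0], best[1] = cost, ncells
            return
        if i < la - 1 and j < lb - 1 and admissible(i + 1, j + 1):
            rec(i + 1, j + 1, cost + local(i + 1, j + 1), 0, 0, ncells + 1)
        if j < lb - 1 and not (run_dir == 1 and run_len >= cfg.max_consecutive_warps) \
                and admissible(i, j + 1):
            rec(i, j + 1, cost + local(i, j + 1) + penalty(i, j + 1),
                1, run_len + 1 if run_dir == 1 else 1, ncells + 1)
        if i < la - 1 and not (run_dir == 2 and run_len >= cfg.max_consecutive_warps) \
                and admissible(i + 1, j):
            rec(i + 1, j, cost + local(i + 1, j) + penalty(i + 1, j),
                2, run_len + 1 if run_dir == 2 else 1, ncells + 1)

    if admissible(0, 0):
        rec(0, 0, local(0, 0), 0, 0, 1)
    return best[0], best[1]
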