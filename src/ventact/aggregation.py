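"""Population aggregation and error metrics.

Collapses a final SMC-ABC population into one solution (median speeds,
k-means root-node centroids initialised from the modal configuration) and
computes speed, root-node, and signal-agreement error metrics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from ventact.geometry import V_LV, V_RV, BiventricularMesh, CandidateRootNodes
from ventact.eikonal import ConductionSpeeds
from ventact.smc_abc import Population


class AggregationError(ValueError):
    pass


@dataclass
class AggregatedSolution:
    """Single solution summarising a population."""

    speeds: ConductionSpeeds
    root_centroids: np.ndarray   # (k, 3) positions in cm
    centroid_ventricle: np.ndarray  # (k,) V_LV / V_RV

    @property
    def k(self) -> int:
        return self.root_centroids.shape[0]


@dataclass
class EvaluationReport:
    speed_errors_percent: dict          # name -> signed %
    speed_abs_errors_percent: dict      # name -> |%|
    root_distance_cm: dict              # "LV"/"RV" -> (mean, sd)
    root_count_error: dict              # "LV"/"RV" -> |delta count|
    pearson_r: float | None = None

    def to_json(self, path=None) -> str:
        payload = {
            "speed_errors_percent": self.speed_errors_percent,
            "speed_abs_errors_percent": self.speed_abs_errors_percent,
            "root_distance_cm": {k: list(v) for k, v in self.root_distance_cm.items()},
            "root_count_error": self.root_count_error,
            "pearson_r": self.pearson_r,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def to_text(self) -> str:
        lines = ["speed errors (signed %, |%|):"]
        for name in ("endocardial", "fibre", "sheet", "sheet_normal"):
            lines.append(
                f"  {name:13s} {self.speed_errors_percent[name]:+7.2f}  "
                f"{self.speed_abs_errors_percent[name]:6.2f}"
            )
        for v in ("LV", "RV"):
            m, sd = self.root_distance_cm[v]
            lines.append(
                f"{v}: closest-centroid distance {m:.2f} +/- {sd:.2f} cm, "
                f"count error {self.root_count_error[v]}"
            )
        if self.pearson_r is not None:
            lines.append(f"Pearson r: {self.pearson_r:.3f}")
        return "\n".join(lines)


def aggregate_speeds(pop: Population) -> ConductionSpeeds:
    """Component-wise median of the population's conduction speeds.

    Medians of per-member ordered tuples preserve the myocardial ordering.
    """
    if pop.size == 0:
        raise AggregationError("empty population")
    arr = np.stack([m.speeds.as_array() for m in pop.members])
    med = np.median(arr, axis=0)
    return ConductionSpeeds.from_array(med)


def _lloyd(points: np.ndarray, centroids: np.ndarray, max_iter: int = 300) -> np.ndarray:
    """Plain Lloyd iterations; stops when assignments stabilise.  The
    within-cluster sum of squares is checked non-increasing per iteration."""
    assign = None
    prev_obj = np.inf
    for _ in range(max_iter):
        d2 = ((points[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        new_assign = np.argmin(d2, axis=1)
        obj = float(d2[np.arange(points.shape[0]), new_assign].sum())
        assert obj <= prev_obj + 1e-9, "k-means objective increased"
        prev_obj = obj
        if assign is not None and np.array_equal(new_assign, assign):
            break
        assign = new_assign
        for c in range(centroids.shape[0]):
            mask = assign == c
            if mask.any():
                pts = points[mask]
                # exact for zero-variance clusters (unanimous populations)
                centroids[c] = pts[0] if np.all(pts == pts[0]) else pts.mean(axis=0)
    return centroids


def modal_configuration(pop: Population) -> tuple[np.ndarray | None, int]:
    """Most frequent root-node configuration and its multiplicity.

    Returns (activation vector, count); the vector is None when every
    configuration is unique.  Ties break on first occurrence.
    """
    keys = {}
    order = []
    for m in pop.members:
        key = m.root_active.tobytes()
        if key not in keys:
            keys[key] = [0, m.root_active]
            order.append(key)
        keys[key][0] += 1
    best_key = max(order, key=lambda k: keys[k][0])
    count, vec = keys[best_key]
    if count == 1:
        return None, 1
    return vec, count


def aggregate_root_nodes(
    pop: Population, candidates: CandidateRootNodes, mesh: BiventricularMesh
) -> tuple[np.ndarray, np.ndarray]:
    """k-means centroids of all active root-node positions in the population.

    k and the initial centroids come from the modal (most frequent)
    configuration; if all configurations are unique, k falls back to the
    modal active-root count and initialisation to the lowest-discrepancy
    member.  Returns (centroids (k, 3), centroid ventricle tags).
    """
    if pop.size == 0:
        raise AggregationError("empty population")
    positions = candidates.positions(mesh)
    pooled = np.concatenate([positions[m.root_active] for m in pop.members])

    modal, count = modal_configuration(pop)
    if modal is not None:
        init = positions[modal].copy()
    else:
        counts = np.array([m.n_active for m in pop.members])
        k = int(np.bincount(counts).argmax())
        if pop.evaluated:
            best = int(np.argmin(pop.discrepancies))
        else:
            best = 0
        base = positions[pop.members[best].root_active]
        init = base[:k].copy() if base.shape[0] >= k else base.copy()

    centroids = _lloyd(pooled, init)

    # tag each centroid with the ventricle of its nearest candidate
    d = np.linalg.norm(positions[None, :, :] - centroids[:, None, :], axis=2)
    vent = candidates.ventricle[np.argmin(d, axis=1)]
    return centroids, vent


def aggregate(pop: Population, candidates: CandidateRootNodes, mesh: BiventricularMesh) -> AggregatedSolution:
    centroids, vent = aggregate_root_nodes(pop, candidates, mesh)
    return AggregatedSolution(
        speeds=aggregate_speeds(pop), root_centroids=centroids, centroid_ventricle=vent
    )


def speed_error_percent(inferred: float, truth: float) -> float:
    """Signed percentage error 100 * (S' - S) / S."""
    if truth <= 0:
        raise AggregationError("ground-truth speed must be positive")
    return 100.0 * (inferred - truth) / truth


def root_node_errors(
    centroids: np.ndarray,
    centroid_ventricle: np.ndarray,
    true_positions: np.ndarray,
    true_ventricle: np.ndarray,
) -> dict:
    """Per-ventricle closest-centroid distances and count errors.

    For each true root node: Euclidean distance to the nearest centroid of
    the same ventricle.  Count error = |#centroids - #true| per ventricle.
    """
    if true_positions.shape[0] == 0:
        raise AggregationError("no ground-truth root nodes")
    out = {}
    for vcode, name in ((V_LV, "LV"), (V_RV, "RV")):
        t = true_positions[true_ventricle == vcode]
        c = centroids[centroid_ventricle == vcode]
        if t.shape[0] == 0:
            out[name] = {"distances_cm": np.array([]), "mean_cm": np.nan, "sd_cm": np.nan,
                         "count_error": abs(c.shape[0])}
            continue
        if c.shape[0] == 0:
            out[name] = {"distances_cm": np.full(t.shape[0], np.inf), "mean_cm": np.inf,
                         "sd_cm": np.nan, "count_error": t.shape[0]}
            continue
        d = np.linalg.norm(t[:, None, :] - c[None, :, :], axis=2).min(axis=1)
        out[name] = {
            "distances_cm": d,
            "mean_cm": float(d.mean()),
            "sd_cm": float(d.std()),
            "count_error": abs(c.shape[0] - t.shape[0]),
        }
    return out


def pearson_correlation(predicted, target) -> float:
    """Product-moment correlation between two equal-length data vectors."""
    p = np.asarray(predicted, dtype=float).ravel()
    t = np.asarray(target, dtype=float).ravel()
    if p.shape != t.shape or p.size < 3:
        raise AggregationError("need equal-length vectors with >= 3 samples")
    if p.std() == 0 or t.std() == 0:
        raise AggregationError("zero-variance input")
    return float(np.corrcoef(p, t)[0, 1])


def qrs_pearson(predicted, target) -> float:
    """Mean per-lead Pearson correlation for two QRS recordings (resampled
    to the shorter common length)."""
    n = min(predicted.n_samples, target.n_samples)
    rs = []
    for i in range(predicted.samples.shape[1]):
        a = np.interp(np.linspace(0, 1, n), np.linspace(0, 1, predicted.n_samples),
                      predicted.samples[:, i])
        b = np.interp(np.linspace(0, 1, n), np.linspace(0, 1, target.n_samples),
                      target.samples[:, i])
        if a.std() == 0 or b.std() == 0:
            continue
        rs.append(pearson_correlation(a, b))
    if not rs:
        raise AggregationError("no leads with variance")
    return float(np.mean(rs))


def evaluate_solution(
    solution: AggregatedSolution,
    truth_speeds: ConductionSpeeds,
    true_root_positions: np.ndarray,
    true_root_ventricle: np.ndarray,
    pearson_r: float | None = None,
) -> EvaluationReport:
    names = ("endocardial", "fibre", "sheet", "sheet_normal")
    signed = {
        nm: speed_error_percent(getattr(solution.speeds, nm), getattr(truth_speeds, nm))
        for nm in names
    }
    errs = root_node_errors(
        solution.root_centroids, solution.centroid_ventricle,
        true_root_positions, true_root_ventricle,
    )
    return EvaluationReport(
        speed_errors_percent=signed,
        speed_abs_errors_percent={nm: abs(v) for nm, v in signed.items()},
        root_distance_cm={v: (errs[v]["mean_cm"], errs[v]["sd_cm"]) for v in ("LV", "RV")},
        root_count_error={v: int(errs[v]["count_error"]) for v in ("LV", "RV")},
        pearson_r=pearson_r,
    )


def save_centroids_csv(solution: AggregatedSolution, path) -> None:
    from ventact.geometry import VENTRICLE_NAMES

    with open(path, "w") as fh:
        fh.write("x,y,z,ventricle\n")
        for p, v in zip(solution.root_centroids, solution.centroid_ventricle):
            fh.write(f"{p[0]:.17g},{p[1]:.17g},{p[2]:.17g},{VENTRICLE_NAMES[int(v)]}\n")
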