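"""Prediction-target discrepancies.

Epicardial activation maps are compared by RMSE.  12-lead QRS complexes are
compared by a constrained dynamic-time-warping (DTW) cost plus a QRS-width
penalty.  The DTW dynamic programme enforces:

* common start and end: paths run from (0, 0) to (la-1, lb-1);
* a warping-slope constraint: at most ``max_consecutive_warps`` (default 2)
  consecutive non-diagonal steps in the same direction, so one sample of one
  signal can align to at most 3 samples of the other;
* a parallelogram band: cells too far from the stretched diagonal are
  inadmissible, with a half-width opening linearly from
  ``band_start_halfwidth`` samples at the start to
  ``band_end_fraction * len(b)`` at the end;
* additive penalties on non-diagonal steps whose weight decays linearly
  from ``start_penalty_weight`` at the path start to ``end_penalty_weight``
  at the end.

The total cost (sum of per-cell local costs plus warp penalties) is
normalised by the number of cells on the optimal path.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

#: sentinel cost for pairs with no admissible alignment
INFEASIBLE_COST = float(np.finfo(np.float64).max)

# DP states: 0 = last step diagonal (or path start);
# 1/2 = run of 1/2 consecutive steps advancing j only;
# 3/4 = run of 1/2 consecutive steps advancing i only.
_N_STATES = 5


class DiscrepancyError(ValueError):
    pass


@dataclass(frozen=True)
class DTWConfig:
    """Configuration of the constrained DTW discrepancy.

    ``start_penalty_weight``/``end_penalty_weight`` are relative to the
    target signal's amplitude range when ``penalty_relative_to_range`` is
    True (the default), otherwise absolute.
    """

    max_consecutive_warps: int = 2
    start_penalty_weight: float = 0.2
    end_penalty_weight: float = 0.0
    width_penalty_weight: float = 0.02
    band_start_halfwidth: float = 2.0
    band_end_fraction: float = 0.25
    penalty_relative_to_range: bool = True
    local_cost: str = "abs"

    def __post_init__(self):
        if self.start_penalty_weight < self.end_penalty_weight or self.end_penalty_weight < 0:
            raise DiscrepancyError("need start_penalty_weight >= end_penalty_weight >= 0")
        if self.width_penalty_weight < 0:
            raise DiscrepancyError("width_penalty_weight must be >= 0")
        if self.max_consecutive_warps != 2:
            raise DiscrepancyError("only max_consecutive_warps = 2 is supported")
        if self.local_cost not in ("abs", "sq"):
            raise DiscrepancyError("local_cost must be 'abs' or 'sq'")


@dataclass
class DTWResult:
    cost: float                 # path-length-normalised total cost
    total_cost: float
    path: np.ndarray | None     # (L, 2) aligned index pairs, or None
    feasible: bool


@dataclass
class DiscrepancyValue:
    """Scalar discrepancy with modality tag and optional per-lead detail."""

    value: float
    modality: str               # "ATM" or "ECG"
    per_lead: dict | None = None

    def __float__(self) -> float:
        return float(self.value)


def atm_rmse(predicted, target) -> DiscrepancyValue:
    """Root-mean-square error (ms) between two activation maps.

    Accepts ``ActivationMap`` objects (same node set and ordering required)
    or plain arrays.
    """
    p = np.asarray(getattr(predicted, "times_ms", predicted), dtype=float)
    t = np.asarray(getattr(target, "times_ms", target), dtype=float)
    pn = getattr(predicted, "node_ids", None)
    tn = getattr(target, "node_ids", None)
    if pn is not None and tn is not None and not np.array_equal(pn, tn):
        raise DiscrepancyError("activation maps cover different node sets")
    if p.shape != t.shape:
        raise DiscrepancyError(f"length mismatch: {p.shape} vs {t.shape}")
    return DiscrepancyValue(value=float(np.sqrt(np.mean((p - t) ** 2))), modality="ATM")


def _dtw_kernel(a, b, h0, h1, pen_start, pen_end, use_sq):
    """Constrained-DTW dynamic programme.

    Returns (feasible, total_cost, best_end_state, back) where ``back`` holds
    the predecessor state of each (i, j, state) or -1.
    """
    la = a.shape[0]
    lb = b.shape[0]
    big = np.inf
    dp = np.full((la, lb, _N_STATES), big)
    back = np.full((la, lb, _N_STATES), -1, dtype=np.int8)

    denom = la + lb - 2
    if denom <= 0:
        denom = 1
    slope = (la - 1.0) / (lb - 1.0) if lb > 1 else 0.0

    for i in range(la):
        for j in range(lb):
            u = (i + j) / denom
            # parallelogram band
            half = h0 + (h1 - h0) * u
            dev = i - j * slope if lb > 1 else 0.0
            if dev > half or dev < -half:
                continue
            d = a[i] - b[j]
            loc = d * d if use_sq else abs(d)
            pen = pen_start + (pen_end - pen_start) * u
            if i == 0 and j == 0:
                dp[0, 0, 0] = loc
                back[0, 0, 0] = 0
                continue
            # diagonal step into (i, j) -> state 0
            if i > 0 and j > 0:
                best = big
                barg = -1
                for s in range(_N_STATES):
                    v = dp[i - 1, j - 1, s]
                    if v < best:
                        best = v
                        barg = s
                if barg >= 0 and best < big:
                    dp[i, j, 0] = best + loc
                    back[i, j, 0] = barg
            # j-advance (warp) into (i, j)
            if j > 0:
                best = big
                barg = -1
                for s in (0, 3, 4):
                    v = dp[i, j - 1, s]
                    if v < best:
                        best = v
                        barg = s
                if barg >= 0 and best < big:
                    dp[i, j, 1] = best + loc + pen
                    back[i, j, 1] = barg
                if dp[i, j - 1, 1] < big:
                    dp[i, j, 2] = dp[i, j - 1, 1] + loc + pen
                    back[i, j, 2] = 1
            # i-advance (warp) into (i, j)
            if i > 0:
                best = big
                barg = -1
                for s in (0, 1, 2):
                    v = dp[i - 1, j, s]
                    if v < best:
                        best = v
                        barg = s
                if barg >= 0 and best < big:
                    dp[i, j, 3] = best + loc + pen
                    back[i, j, 3] = barg
                if dp[i - 1, j, 3] < big:
                    dp[i, j, 4] = dp[i - 1, j, 3] + loc + pen
                    back[i, j, 4] = 3
    best = big
    barg = -1
    for s in range(_N_STATES):
        v = dp[la - 1, lb - 1, s]
        if v < best:
            best = v
            barg = s
    if barg < 0:
        return False, 0.0, -1, back
    return True, best, barg, back


try:  # pragma: no cover - exercised implicitly when numba is present
    from numba import njit as _njit

    _dtw_kernel_jit = _njit(cache=False)(_dtw_kernel)
except ImportError:  # pragma: no cover
    _dtw_kernel_jit = _dtw_kernel


def _trace_path(back: np.ndarray, end_state: int) -> np.ndarray:
    la, lb = back.shape[0], back.shape[1]
    i, j, s = la - 1, lb - 1, end_state
    cells = [(i, j)]
    while (i, j) != (0, 0):
        prev = int(back[i, j, s])
        if s == 0:
            i, j = i - 1, j - 1
        elif s in (1, 2):
            j = j - 1
        else:
            i = i - 1
        s = prev
        cells.append((i, j))
    return np.array(cells[::-1], dtype=np.int64)


def resolved_penalties(b: np.ndarray, cfg: DTWConfig) -> tuple[float, float]:
    """Absolute start/end warp-penalty weights for a given target signal."""
    if cfg.penalty_relative_to_range:
        scale = float(np.ptp(b))
        return cfg.start_penalty_weight * scale, cfg.end_penalty_weight * scale
    return cfg.start_penalty_weight, cfg.end_penalty_weight


def band_halfwidth(b_len: int, cfg: DTWConfig) -> tuple[float, float]:
    """Band half-width (samples) at path start and end."""
    h0 = cfg.band_start_halfwidth
    return h0, max(h0, cfg.band_end_fraction * b_len)


def constrained_dtw(a, b, cfg: DTWConfig | None = None) -> DTWResult:
    """Align two single-lead series under slope/band/endpoint constraints.

    Returns the path-length-normalised cost and the optimal path; when no
    admissible path exists the cost is the ``INFEASIBLE_COST`` sentinel and
    the result is flagged infeasible.
    """
    cfg = cfg or DTWConfig()
    a = np.ascontiguousarray(np.asarray(a, dtype=np.float64))
    b = np.ascontiguousarray(np.asarray(b, dtype=np.float64))
    if a.size == 0 or b.size == 0:
        raise DiscrepancyError("empty series")
    pen0, pen1 = resolved_penalties(b, cfg)
    h0, h1 = band_halfwidth(b.shape[0], cfg)
    feasible, total, end_state, back = _dtw_kernel_jit(
        a, b, h0, h1, pen0, pen1, cfg.local_cost == "sq"
    )
    if not feasible:
        return DTWResult(cost=INFEASIBLE_COST, total_cost=INFEASIBLE_COST, path=None, feasible=False)
    path = _trace_path(back, end_state)
    return DTWResult(
        cost=total / path.shape[0], total_cost=float(total), path=path, feasible=True
    )


def qrs_width_penalty(a, b, weight: float = 1.0) -> float:
    """weight * |duration(a) - duration(b)| in ms; symmetric in a, b."""
    da = float(getattr(a, "duration_ms", a))
    db = float(getattr(b, "duration_ms", b))
    return weight * abs(da - db)


def ecg_discrepancy(predicted, target, cfg: DTWConfig | None = None) -> DiscrepancyValue:
    """Mean constrained-DTW cost over the 8 independent leads plus the
    QRS-width penalty.

    Derived leads (III, augmented) are excluded to avoid double counting.
    Any infeasible per-lead alignment makes the whole discrepancy the
    infeasible sentinel.
    """
    from ventact.pseudo_ecg import INDEPENDENT_LEADS

    cfg = cfg or DTWConfig()
    if tuple(predicted.lead_names) != tuple(target.lead_names):
        raise DiscrepancyError("lead sets differ")
    per_lead = {}
    costs = []
    for name in INDEPENDENT_LEADS:
        res = constrained_dtw(predicted.lead(name), target.lead(name), cfg)
        per_lead[name] = res.cost
        if not res.feasible:
            return DiscrepancyValue(value=INFEASIBLE_COST, modality="ECG", per_lead=per_lead)
        costs.append(res.cost)
    width = qrs_width_penalty(predicted, target, cfg.width_penalty_weight)
    return DiscrepancyValue(
        value=float(np.mean(costs) + width), modality="ECG", per_lead=per_lead
    )


def check_path_admissible(path: np.ndarray, la: int, lb: int, cfg: DTWConfig) -> bool:
    """Verify a warping path honours endpoint, slope, and band constraints."""
    if tuple(path[0]) != (0, 0) or tuple(path[-1]) != (la - 1, lb - 1):
        return False
    h0, h1 = band_halfwidth(lb, cfg)
    denom = max(la + lb - 2, 1)
    slope = (la - 1.0) / (lb - 1.0) if lb > 1 else 0.0
    run_dir, run_len = 0, 0
    for k in range(1, len(path)):
        di, dj = path[k] - path[k - 1]
        if (di, dj) not in ((1, 1), (0, 1), (1, 0)):
            return False
        if (di, dj) == (1, 1):
            run_dir, run_len = 0, 0
        else:
            d = 1 if (di, dj) == (0, 1) else 2
            run_len = run_len + 1 if run_dir == d else 1
            run_dir = d
            if run_len > cfg.max_consecutive_warps:
                return False
        i, j = path[k]
        u = (i + j) / denom
        half = h0 + (h1 - h0) * u
        if lb > 1 and abs(i - j * slope) > half:
            return False
    return True
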