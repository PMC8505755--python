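"""Sequential Monte Carlo approximate Bayesian computation (SMC-ABC).

Evolves a fixed-size population of parameter sets (four conduction speeds +
a binary root-node activation vector) by iteratively replacing the worst
12.5% of members with mutated-or-copied survivors, until either every
discrepancy falls below the tolerance (MATCHED) or more than half the
population are exact duplicates (COLLAPSED).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import qmc

from ventact.geometry import BiventricularMesh, CandidateRootNodes, ElectrodeSet
from ventact.eikonal import (
    ENDO_SPEED_BOUNDS,
    MYO_SPEED_BOUNDS,
    ROOT_COUNT_RANGE,
    ConductionSpeeds,
    ParameterSet,
    PropagationGraph,
    build_propagation_graph,
    extract_epicardial_map,
    simulate_activation,
)
from ventact.discrepancy import (
    INFEASIBLE_COST,
    DTWConfig,
    atm_rmse,
    ecg_discrepancy,
)

logger = logging.getLogger(__name__)

CONTINUE = "CONTINUE"
MATCHED = "MATCHED"
COLLAPSED = "COLLAPSED"
MAX_ITERATIONS = "MAX_ITERATIONS"


class InferenceError(RuntimeError):
    pass


@dataclass
class InferenceConfig:
    """Hyperparameters of the SMC-ABC loop (single calibration reused
    across subjects, modalities, and resolutions)."""

    population_size: int = 512
    replacement_fraction: float = 0.125
    tolerance: float = 1.0
    duplicate_fraction_threshold: float = 0.5
    max_iterations: int = 100
    speed_sigma_endo: float = 5.0
    speed_sigma_myo: float = 2.5
    root_move_probability: float = 0.5
    root_toggle_probability: float = 0.5
    root_move_radius_cm: float = 2.0
    retry_cap: int = 10
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.replacement_fraction < 1.0):
            raise InferenceError("replacement_fraction must be in (0, 1)")
        if not (0.0 < self.duplicate_fraction_threshold <= 1.0):
            raise InferenceError("duplicate_fraction_threshold must be in (0, 1]")
        if self.population_size < 2:
            raise InferenceError("population_size must be >= 2")


@dataclass
class Population:
    """Fixed-size collection of parameter sets with discrepancies."""

    members: list                      # list[ParameterSet]
    discrepancies: np.ndarray          # (n,) float, NaN = not evaluated
    iteration: int = 0
    seed: int | None = None

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def evaluated(self) -> bool:
        return not np.any(np.isnan(self.discrepancies))

    def member_matrix(self) -> np.ndarray:
        """(n, 4 + K) matrix of full parameter vectors."""
        return np.stack([m.as_vector() for m in self.members])

    def duplicate_count(self) -> int:
        """Number of members that exactly duplicate another member."""
        mat = self.member_matrix()
        return self.size - np.unique(mat, axis=0).shape[0]

    def duplicate_fraction(self) -> float:
        return self.duplicate_count() / self.size

    def copy(self) -> "Population":
        return Population(
            members=[m.copy() for m in self.members],
            discrepancies=self.discrepancies.copy(),
            iteration=self.iteration,
            seed=self.seed,
        )


def sample_prior_lhs(
    candidates: CandidateRootNodes, n: int = 512, seed: int = 0
) -> Population:
    """Draw the initial population from the uniform prior.

    Speeds: Latin-hypercube stratification over the 4-D box
    [100, 200] x [25, 90]^3, with the three myocardial coordinates reordered
    descending to enforce fibre >= sheet >= sheet-normal.  Root nodes: the
    active count is uniform over {6..10}; that many candidates are drawn
    uniformly without replacement.
    """
    if n < 2:
        raise InferenceError("population size must be >= 2")
    k = candidates.n_candidates
    lo, hi = ROOT_COUNT_RANGE
    if k < lo:
        raise InferenceError(f"only {k} candidate root nodes; need at least {lo}")
    hi = min(hi, k)
    if math.comb(k, lo) < 1:
        raise InferenceError("candidate set too small for requested population")

    ss = np.random.SeedSequence(seed)
    lhs_seed, root_seed = ss.spawn(2)
    sampler = qmc.LatinHypercube(d=4, seed=np.random.default_rng(lhs_seed))
    unit = sampler.random(n)
    endo = ENDO_SPEED_BOUNDS[0] + unit[:, 0] * (ENDO_SPEED_BOUNDS[1] - ENDO_SPEED_BOUNDS[0])
    myo = MYO_SPEED_BOUNDS[0] + unit[:, 1:] * (MYO_SPEED_BOUNDS[1] - MYO_SPEED_BOUNDS[0])
    myo = -np.sort(-myo, axis=1)  # descending: fibre >= sheet >= sheet-normal

    rng = np.random.default_rng(root_seed)
    members = []
    for i in range(n):
        count = int(rng.integers(lo, hi + 1))
        chosen = rng.choice(k, size=count, replace=False)
        active = np.zeros(k, dtype=bool)
        active[chosen] = True
        ps = ParameterSet(
            speeds=ConductionSpeeds(float(endo[i]), *(float(v) for v in myo[i])),
            root_active=active,
        )
        ps.validate()
        members.append(ps)
    return Population(
        members=members, discrepancies=np.full(n, np.nan), iteration=0, seed=seed
    )


def build_forward_operator(
    mesh: BiventricularMesh,
    candidates: CandidateRootNodes,
    modality: str,
    electrodes: ElectrodeSet | None = None,
    graph: PropagationGraph | None = None,
    upstroke_tau: float = 1.0,
):
    """Closure mapping a ParameterSet to its predicted target-space data.

    ``modality`` is "ATM" (epicardial activation map) or "ECG" (12-lead QRS).
    """
    modality = modality.upper()
    if graph is None:
        graph = build_propagation_graph(mesh)
    if modality == "ATM":

        def forward(params: ParameterSet):
            atm = simulate_activation(mesh, candidates, params, graph=graph)
            return extract_epicardial_map(atm, mesh)

        return forward
    if modality == "ECG":
        if electrodes is None:
            raise InferenceError("ECG modality requires an ElectrodeSet")
        from ventact.pseudo_ecg import PseudoECGModel, compute_qrs

        model = PseudoECGModel(mesh, electrodes, upstroke_tau=upstroke_tau)

        def forward(params: ParameterSet):
            atm = simulate_activation(mesh, candidates, params, graph=graph)
            return compute_qrs(atm, mesh, electrodes, model=model)

        return forward
    raise InferenceError(f"unknown modality {modality!r}")


def _discrepancy_fn(modality: str, dtw_cfg: DTWConfig | None):
    modality = modality.upper()
    if modality == "ATM":
        return lambda pred, target: float(atm_rmse(pred, target))
    if modality == "ECG":
        cfg = dtw_cfg or DTWConfig()
        return lambda pred, target: float(ecg_discrepancy(pred, target, cfg))
    raise InferenceError(f"unknown modality {modality!r}")


def _evaluate_member(member, forward, target, disc_fn) -> float:
    try:
        return disc_fn(forward(member), target)
    except Exception as exc:  # simulator failure -> sentinel, logged
        logger.warning("member evaluation failed (%s); assigning sentinel", exc)
        return INFEASIBLE_COST


def evaluate_population(
    pop: Population, forward, target, modality: str, dtw_cfg: DTWConfig | None = None
) -> Population:
    """Evaluate every member's discrepancy (order-independent)."""
    disc_fn = _discrepancy_fn(modality, dtw_cfg)
    out = pop.copy()
    out.discrepancies = np.array(
        [_evaluate_member(m, forward, target, disc_fn) for m in out.members]
    )
    return out


def select_replacement_set(pop: Population, replacement_fraction: float) -> tuple[float, np.ndarray]:
    """Indices of the ceil(fraction * size) worst members and the cutoff.

    The cutoff is the largest discrepancy among the survivors; mutants must
    beat it to be accepted.  Ties are broken by member index (stable sort).
    """
    if not pop.evaluated:
        raise InferenceError("population has unevaluated members")
    n = pop.size
    k = math.ceil(replacement_fraction * n)
    order = np.argsort(pop.discrepancies, kind="stable")
    worst = np.sort(order[n - k :])
    cutoff = float(pop.discrepancies[order[n - k - 1]])
    return cutoff, worst


def mutate(
    member: ParameterSet,
    cfg: InferenceConfig,
    candidates: CandidateRootNodes,
    positions: np.ndarray,
    rng: np.random.Generator,
) -> ParameterSet:
    """MCMC proposal: truncated-Gaussian speed perturbation plus a root-node
    toggle-or-relocate move.

    The output always satisfies the parameter-set invariants; invalid root
    proposals are re-drawn up to ``cfg.retry_cap`` times, after which the
    roots are returned unchanged.
    """
    lo_e, hi_e = ENDO_SPEED_BOUNDS
    lo_m, hi_m = MYO_SPEED_BOUNDS

    def trunc_normal(x, sigma, lo, hi):
        if sigma == 0.0:
            return x
        for _ in range(100):
            prop = rng.normal(x, sigma)
            if lo <= prop <= hi:
                return prop
        return min(max(x, lo), hi)

    endo = trunc_normal(member.speeds.endocardial, cfg.speed_sigma_endo, lo_e, hi_e)
    myo = np.array([
        trunc_normal(member.speeds.fibre, cfg.speed_sigma_myo, lo_m, hi_m),
        trunc_normal(member.speeds.sheet, cfg.speed_sigma_myo, lo_m, hi_m),
        trunc_normal(member.speeds.sheet_normal, cfg.speed_sigma_myo, lo_m, hi_m),
    ])
    myo = -np.sort(-myo)
    speeds = ConductionSpeeds(float(endo), float(myo[0]), float(myo[1]), float(myo[2]))

    active = member.root_active.copy()
    lo_r, hi_r = ROOT_COUNT_RANGE
    hi_r = min(hi_r, active.size)
    if rng.random() < cfg.root_move_probability:
        done = False
        for _ in range(cfg.retry_cap):
            if rng.random() < cfg.root_toggle_probability:
                idx = int(rng.integers(active.size))
                count = active.sum() + (-1 if active[idx] else 1)
                if lo_r <= count <= hi_r:
                    active[idx] = ~active[idx]
                    done = True
                    break
            else:
                on = np.flatnonzero(active)
                src = int(on[rng.integers(on.size)])
                near = np.flatnonzero(
                    (np.linalg.norm(positions - positions[src], axis=1) <= cfg.root_move_radius_cm)
                    & ~active
                )
                if near.size > 0:
                    dst = int(near[rng.integers(near.size)])
                    active[src] = False
                    active[dst] = True
                    done = True
                    break
        if not done:
            logger.debug("root-move proposal failed %d times; keeping roots", cfg.retry_cap)
            active = member.root_active.copy()

    out = ParameterSet(speeds=speeds, root_active=active)
    out.validate()
    return out


def replacement_step(
    pop: Population,
    forward,
    target,
    modality: str,
    cfg: InferenceConfig,
    candidates: CandidateRootNodes,
    positions: np.ndarray,
    rng: np.random.Generator,
    dtw_cfg: DTWConfig | None = None,
) -> Population:
    """Replace the worst members by mutated-or-copied survivors.

    Each replaced slot takes a mutated copy of a uniformly chosen survivor
    if the mutant's discrepancy beats the cutoff, otherwise the unmodified
    survivor copy.  Survivors are never modified; population size is
    unchanged.
    """
    disc_fn = _discrepancy_fn(modality, dtw_cfg)
    cutoff, worst = select_replacement_set(pop, cfg.replacement_fraction)
    survivors = np.setdiff1d(np.arange(pop.size), worst)
    out = pop.copy()
    for slot in worst:
        keeper = int(survivors[rng.integers(survivors.size)])
        mutant = mutate(pop.members[keeper], cfg, candidates, positions, rng)
        mutant_disc = _evaluate_member(mutant, forward, target, disc_fn)
        if mutant_disc <= cutoff:
            out.members[slot] = mutant
            out.discrepancies[slot] = mutant_disc
        else:
            out.members[slot] = pop.members[keeper].copy()
            out.discrepancies[slot] = pop.discrepancies[keeper]
    out.iteration = pop.iteration + 1
    return out


def check_stopping(pop: Population, cfg: InferenceConfig) -> str:
    """MATCHED if every discrepancy <= tolerance; COLLAPSED if the duplicate
    fraction strictly exceeds the threshold; else CONTINUE.  MATCHED takes
    precedence."""
    if not pop.evaluated:
        raise InferenceError("population has unevaluated members")
    if np.all(pop.discrepancies <= cfg.tolerance):
        return MATCHED
    if pop.duplicate_fraction() > cfg.duplicate_fraction_threshold:
        return COLLAPSED
    return CONTINUE


def run_inference(
    mesh: BiventricularMesh,
    candidates: CandidateRootNodes,
    target,
    modality: str,
    cfg: InferenceConfig,
    dtw_cfg: DTWConfig | None = None,
    electrodes: ElectrodeSet | None = None,
    graph: PropagationGraph | None = None,
) -> tuple[Population, list, str]:
    """Full SMC-ABC loop: returns (final population, per-iteration trace,
    final status).

    Fully reproducible given ``cfg.seed``; the trace records cutoff,
    min/median/max discrepancy, and duplicate fraction per iteration.
    """
    forward = build_forward_operator(mesh, candidates, modality, electrodes=electrodes, graph=graph)
    pop = sample_prior_lhs(candidates, cfg.population_size, seed=cfg.seed)
    positions = candidates.positions(mesh)
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(3)[2])
    pop = evaluate_population(pop, forward, target, modality, dtw_cfg)

    trace = []
    status = MAX_ITERATIONS
    for it in range(cfg.max_iterations + 1):
        d = pop.discrepancies
        cutoff, _ = select_replacement_set(pop, cfg.replacement_fraction)
        state = check_stopping(pop, cfg)
        trace.append({
            "iteration": pop.iteration,
            "cutoff": cutoff,
            "min_discrepancy": float(d.min()),
            "median_discrepancy": float(np.median(d)),
            "max_discrepancy": float(d.max()),
            "duplicate_fraction": pop.duplicate_fraction(),
            "status": state,
        })
        logger.info(
            "iter %3d cutoff %.4g disc[min/med/max] %.4g/%.4g/%.4g dup %.1f%% %s",
            pop.iteration, cutoff, d.min(), np.median(d), d.max(),
            100 * pop.duplicate_fraction(), state,
        )
        if state in (MATCHED, COLLAPSED):
            status = state
            break
        if it == cfg.max_iterations:
            break
        pop = replacement_step(
            pop, forward, target, modality, cfg, candidates, positions, rng, dtw_cfg
        )
    return pop, trace, status


# ---------------------------------------------------------------------------
# I/O


def save_population_csv(pop: Population, path) -> None:
    """One row per member: 4 speeds, activation bitmask, discrepancy."""
    with open(path, "w") as fh:
        fh.write("endocardial,fibre,sheet,sheet_normal,root_bitmask,discrepancy\n")
        for m, d in zip(pop.members, pop.discrepancies):
            bits = "".join("1" if b else "0" for b in m.root_active)
            s = m.speeds
            fh.write(
                f"{s.endocardial:.17g},{s.fibre:.17g},{s.sheet:.17g},"
                f"{s.sheet_normal:.17g},{bits},{d:.17g}\n"
            )


def load_population_csv(path) -> Population:
    members, disc = [], []
    with open(path) as fh:
        next(fh)
        for line in fh:
            e, f, s, n, bits, d = line.strip().split(",")
            members.append(ParameterSet(
                speeds=ConductionSpeeds(float(e), float(f), float(s), float(n)),
                root_active=np.array([c == "1" for c in bits]),
            ))
            disc.append(float(d))
    return Population(members=members, discrepancies=np.array(disc))


def save_trace_csv(trace: list, path) -> None:
    import pandas as pd

    pd.DataFrame(trace).to_csv(path, index=False)
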