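"""Experiment protocols built on the collocation solver.

These functions implement the study design around the decomposition: the
normalized moment-error metric (NRMSE) with its upper/lower admissibility
limits, the synergy-count selection rule, the multi-start pure-synergy
protocol, held-out-condition validation with frozen weightings, the
effort-weight (K) sweep with its termination statistic, and the PCA
dimensionality check on the joint moments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.optimize import nnls

from .collocation import (CollocationGrid, OcpSpec, SolveResult, solve,
                          transcribe)
from .muscle import MuscleSet
from .synergy import SynergyStructure, make_initial_guess
from .trial import TrialData

__all__ = [
    "NrmseLimits",
    "SweepResult",
    "nrmse",
    "nrmse_limits",
    "nrmse_upper_limit",
    "nrmse_lower_limit",
    "select_num_synergies",
    "pure_synergy_solve",
    "validate_fixed_weights",
    "choose_effort_weight",
    "delta_threshold",
    "optimal_synergy_sweep",
    "moment_dimensionality",
]

log = logging.getLogger("torquesyn")


@dataclass
class NrmseLimits:
    """Admissibility band for the moment-tracking error, in percent."""

    upper: float
    lower: float

    def __post_init__(self) -> None:
        if not self.upper > self.lower > 0:
            raise ValueError(f"need upper > lower > 0, got {self.upper}, {self.lower}")


@dataclass
class SweepResult:
    """Outcome of the effort-weight (K) sweep."""

    results: dict[float, SolveResult]
    chosen_K: float
    activation_costs: dict[float, float]
    deltas: dict[float, float]
    exhausted: bool
    nrmse_at_chosen: float
    nrmse_upper: float
    nrmse_ok: bool

    def __post_init__(self) -> None:
        if self.chosen_K not in self.results:
            raise ValueError("chosen K is not among the solved values")


# ---------------------------------------------------------------------------
# NRMSE and its limits
# ---------------------------------------------------------------------------

def _as_dicts(M, M_star):
    if not isinstance(M, dict):
        M, M_star = {"_": np.asarray(M)}, {"_": np.asarray(M_star)}
    if set(M) != set(M_star):
        raise ValueError("condition sets differ between simulated and experimental")
    return M, M_star


def nrmse(M, M_star) -> float:
    """Normalized RMS joint-moment error, percent.

    sqrt of the squared errors summed over conditions, nodes and DOFs,
    normalized by the node/DOF count and by the global moment range taken
    cumulatively over all conditions, nodes and DOFs.
    """
    M, M_star = _as_dicts(M, M_star)
    sq = 0.0
    n_nodes = 0
    NJ = None
    lo, hi = np.inf, -np.inf
    for c in M:
        a = np.asarray(M[c], dtype=float)
        b = np.asarray(M_star[c], dtype=float)
        if a.shape != b.shape:
            raise ValueError(f"shape mismatch in condition {c!r}")
        if NJ is None:
            NJ = b.shape[1]
        elif b.shape[1] != NJ:
            raise ValueError("DOF count differs between conditions")
        sq += float(np.sum((a - b) ** 2))
        n_nodes += b.shape[0]
        lo = min(lo, float(b.min()))
        hi = max(hi, float(b.max()))
    rng = hi - lo
    if rng <= 0:
        raise ValueError("experimental moments have zero range")
    return 100.0 * np.sqrt(sq / (NJ * n_nodes)) / rng


def _moment_tables(trials: list[TrialData], grid: CollocationGrid | None):
    """Experimental moments per condition, resampled on the grid if given."""
    out = {}
    for tr in trials:
        if grid is not None:
            tr = tr.resample(grid.times[tr.condition])
        out[tr.condition] = tr.moments
    return out


def nrmse_upper_limit(trials: list[TrialData],
                      grid: CollocationGrid | None = None) -> float:
    """NRMSE when every error equals 5% of its own DOF-and-condition range."""
    tables = _moment_tables(trials, grid)
    sq = 0.0
    n_nodes = 0
    NJ = None
    lo, hi = np.inf, -np.inf
    for c, Ms in tables.items():
        NJ = Ms.shape[1]
        rng_j = Ms.max(axis=0) - Ms.min(axis=0)
        if np.any(rng_j <= 0):
            raise ValueError(f"zero moment range at a DOF of condition {c!r}")
        sq += float(Ms.shape[0] * np.sum((0.05 * rng_j) ** 2))
        n_nodes += Ms.shape[0]
        lo = min(lo, float(Ms.min()))
        hi = max(hi, float(Ms.max()))
    return 100.0 * np.sqrt(sq / (NJ * n_nodes)) / (hi - lo)


def nrmse_lower_limit(trials: list[TrialData],
                      grid: CollocationGrid | None = None) -> float:
    """NRMSE when every error is 1 N*m; algebraically 100/(global range)."""
    tables = _moment_tables(trials, grid)
    sq = 0.0
    n_nodes = 0
    NJ = None
    lo, hi = np.inf, -np.inf
    for c, Ms in tables.items():
        NJ = Ms.shape[1]
        sq += float(Ms.shape[0] * NJ * 1.0)
        n_nodes += Ms.shape[0]
        lo = min(lo, float(Ms.min()))
        hi = max(hi, float(Ms.max()))
    rng = hi - lo
    if rng <= 0:
        raise ValueError("experimental moments have zero range")
    return 100.0 * np.sqrt(sq / (NJ * n_nodes)) / rng


def nrmse_limits(trials: list[TrialData],
                 grid: CollocationGrid | None = None) -> NrmseLimits:
    return NrmseLimits(upper=nrmse_upper_limit(trials, grid),
                       lower=nrmse_lower_limit(trials, grid))


def select_num_synergies(nrmse_by_nsyn: dict[int, float],
                         limits: NrmseLimits) -> int:
    """Highest synergy count whose NRMSE lies strictly inside the limits."""
    if not nrmse_by_nsyn:
        raise ValueError("empty NRMSE table")
    admissible = [n for n, e in nrmse_by_nsyn.items()
                  if limits.lower < e < limits.upper]
    log.info("synergy-count selection table: %s, limits (%.3f, %.3f), admissible %s",
             dict(sorted(nrmse_by_nsyn.items())), limits.lower, limits.upper,
             sorted(admissible))
    if not admissible:
        raise ValueError(
            f"no admissible synergy count: NRMSE table {nrmse_by_nsyn} vs "
            f"limits ({limits.lower:.3f}, {limits.upper:.3f})"
        )
    return max(admissible)


# ---------------------------------------------------------------------------
# multi-start pure-synergy protocol
# ---------------------------------------------------------------------------

def _start_seed(seed: int, j: int) -> int:
    return int(np.random.SeedSequence([int(seed), int(j)]).generate_state(1)[0]
               % (2 ** 31))


def _start_pattern(j: int) -> str:
    """Start-family schedule: one model-informed start, then the arbitrary
    families of the multi-start protocol (alternating constant / sine)."""
    if j == 0:
        return "static"
    return "constant" if j % 2 == 1 else "sine-pulses"


def pure_synergy_solve(trials: list[TrialData], muscles: MuscleSet, n_syn: int,
                       n_starts: int = 15, seed: int = 0,
                       grid: CollocationGrid | None = None,
                       scheme: str = "hermite-simpson",
                       options: dict | None = None,
                       polish_nfev: int = 400) -> SolveResult:
    """Best-of-multistart solve of the pure-synergy (K = 0) problem.

    Starts alternate between the constant and sine-pulse excitation pattern
    families, each with its own sub-seed; the minimum-NRMSE converged
    solution is selected and, when ``polish_nfev`` > 0, its local
    optimization is continued with that extra iteration budget. The
    per-start NRMSE list is attached as ``per_start_nrmse``.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    if grid is None:
        grid = CollocationGrid.from_trials(trials)
    spec = OcpSpec(trials=trials, muscles=muscles, n_syn=n_syn, K=0.0,
                   scheme=scheme, options=options or {})
    nlp = transcribe(spec, grid)
    best = None
    per_start = []
    failures = []
    for j in range(n_starts):
        pattern = _start_pattern(j)
        try:
            guess = make_initial_guess(pattern, trials, n_syn, _start_seed(seed, j),
                                       muscles, grid=grid, scheme=scheme)
            res = solve(nlp, guess)
        except Exception as exc:
            failures.append(f"start {j}: {exc}")
            per_start.append(np.nan)
            continue
        per_start.append(res.nrmse)
        if res.success and (best is None or res.nrmse < best.nrmse):
            best = res
    if best is None:
        raise RuntimeError(
            "all starts failed: " + "; ".join(failures or ["no converged solve"])
        )
    if polish_nfev > 0:
        warm = {"W": best.structure.W, "H": dict(best.structure.H),
                "a": {c: best.states[c]["a"] for c in best.states},
                "l": {c: best.states[c]["l"] for c in best.states}}
        polished = solve(nlp, warm, options={"max_nfev": polish_nfev})
        if polished.success and polished.nrmse <= best.nrmse:
            best = polished
    best.per_start_nrmse = per_start
    return best


def validate_fixed_weights(trials_new: list[TrialData], W: np.ndarray,
                           muscles: MuscleSet, seed: int = 0,
                           n_starts: int = 5,
                           grid: CollocationGrid | None = None,
                           scheme: str = "hermite-simpson",
                           options: dict | None = None) -> SolveResult:
    """Solve held-out conditions with the weighting matrix frozen.

    Only the synergy controls and muscle states are free; the returned
    structure carries exactly the supplied ``W``.
    """
    W = np.asarray(W, dtype=float)
    if grid is None:
        grid = CollocationGrid.from_trials(trials_new)
    n_syn = W.shape[1]
    spec = OcpSpec(trials=trials_new, muscles=muscles, n_syn=n_syn, K=0.0,
                   scheme=scheme, fixed_W=W, options=options or {})
    nlp = transcribe(spec, grid)
    best = None
    per_start = []
    for j in range(n_starts):
        pattern = _start_pattern(j)
        guess = make_initial_guess(pattern, trials_new, n_syn,
                                   _start_seed(seed, j), muscles, grid=grid,
                                   scheme=scheme)
        # project the pattern excitations onto the frozen weightings
        guess["W"] = W
        for c, U in guess.pop("_patterns").items():
            H = np.stack([nnls(W, U[:, t])[0] for t in range(U.shape[1])], axis=1)
            guess["H"][c] = H
        res = solve(nlp, guess)
        per_start.append(res.nrmse)
        if res.success and (best is None or res.nrmse < best.nrmse):
            best = res
    if best is None:
        raise RuntimeError("all validation starts failed")
    best.per_start_nrmse = per_start
    return best


# ---------------------------------------------------------------------------
# effort-weight sweep
# ---------------------------------------------------------------------------

def choose_effort_weight(activation_costs: dict[float, float],
                         deltas: dict[float, float],
                         K_grid: list[float]) -> tuple[float, bool]:
    """Apply the sweep termination rule to completed cost/threshold tables.

    Walks the grid in order; the first K whose activation-cost reduction to
    the next K falls below its threshold is chosen. Returns ``(K,
    exhausted)`` with ``exhausted`` set when the rule never fires.
    """
    for K, K_next in zip(K_grid[:-1], K_grid[1:]):
        drop = activation_costs[K] - activation_costs[K_next]
        if drop < deltas[K]:
            return K, False
    return K_grid[-1], True


def delta_threshold(result: SolveResult) -> float:
    """Termination statistic of the K sweep.

    The activation cost that would be shed if every activation dropped by
    0.01 (floored at the 0.01 lower bound), summed over conditions, nodes
    and muscles.
    """
    total = 0.0
    for c in result.states:
        a = result.states[c]["a"]
        lowered = np.maximum(0.01, a - 0.01)
        total += float(np.sum(a ** 2 - lowered ** 2))
    return total


def optimal_synergy_sweep(trials: list[TrialData], muscles: MuscleSet, n_syn: int,
                          K_grid: list[float] | None = None, seed: int = 0,
                          n_starts: int = 15, warm_start: bool = True,
                          grid: CollocationGrid | None = None,
                          scheme: str = "hermite-simpson",
                          options: dict | None = None,
                          base_result: SolveResult | None = None) -> SweepResult:
    """Sweep the effort weight K; stop when the cost reduction is insignificant.

    The K = 0 entry is the pure-synergy solution (multi-start, or a
    previously computed ``base_result``); subsequent K values are
    warm-started from the previous solution (or re-run from the multi-start
    protocol when ``warm_start`` is false). Termination: the first K whose
    activation-cost reduction to the next K falls below the
    :func:`delta_threshold` statistic. The chosen solution's NRMSE is
    checked against the upper limit and recorded.
    """
    if K_grid is None:
        K_grid = [0.0, 100.0, 200.0, 300.0, 400.0, 500.0]
    K_grid = [float(k) for k in K_grid]
    if K_grid != sorted(K_grid) or K_grid[0] != 0.0:
        raise ValueError("K grid must be increasing and start at 0")
    if grid is None:
        grid = CollocationGrid.from_trials(trials)

    results: dict[float, SolveResult] = {}
    if base_result is not None:
        results[0.0] = base_result
    else:
        results[0.0] = pure_synergy_solve(trials, muscles, n_syn,
                                          n_starts=n_starts, seed=seed,
                                          grid=grid, scheme=scheme,
                                          options=options)

    def solve_at(K, prev: SolveResult) -> SolveResult:
        spec = OcpSpec(trials=trials, muscles=muscles, n_syn=n_syn, K=K,
                       scheme=scheme, options=options or {})
        nlp = transcribe(spec, grid)
        if warm_start:
            guess = {
                "W": prev.structure.W,
                "H": dict(prev.structure.H),
                "a": {c: prev.states[c]["a"] for c in prev.states},
                "l": {c: prev.states[c]["l"] for c in prev.states},
            }
            return solve(nlp, guess)
        best = None
        for j in range(n_starts):
            pattern = _start_pattern(j)
            guess = make_initial_guess(pattern, trials, n_syn,
                                       _start_seed(seed, j), muscles,
                                       grid=grid, scheme=scheme)
            res = solve(nlp, guess)
            if res.success and (best is None or res.objective < best.objective):
                best = res
        if best is None:
            raise RuntimeError(f"all starts failed at K={K}")
        return best

    chosen = None
    exhausted = False
    for idx, K in enumerate(K_grid[:-1]):
        K_next = K_grid[idx + 1]
        if K_next not in results:
            results[K_next] = solve_at(K_next, results[K])
        costs = {k: r.activation_cost for k, r in results.items()}
        deltas = {k: delta_threshold(r) for k, r in results.items()}
        K_rule, exhausted_rule = choose_effort_weight(
            costs, deltas, K_grid[:idx + 2])
        if not exhausted_rule:
            chosen = K_rule
            break
    if chosen is None:
        chosen = K_grid[-1]
        exhausted = True

    upper = nrmse_upper_limit(trials, grid)
    err = results[chosen].nrmse
    return SweepResult(
        results=results,
        chosen_K=chosen,
        activation_costs={k: r.activation_cost for k, r in results.items()},
        deltas={k: delta_threshold(r) for k, r in results.items()},
        exhausted=exhausted,
        nrmse_at_chosen=err,
        nrmse_upper=upper,
        nrmse_ok=bool(err < upper),
    )


# ---------------------------------------------------------------------------
# joint-moment dimensionality
# ---------------------------------------------------------------------------

def moment_dimensionality(trials: list[TrialData], variance_threshold: float = 0.9,
                          return_spectrum: bool = False):
    """Principal components needed to reach the variance threshold.

    Joint-moment samples from all conditions are pooled into NJ-dimensional
    vectors; the smallest component count whose cumulative explained
    variance reaches the threshold is returned (with the full spectrum if
    requested).
    """
    if not 0 < variance_threshold <= 1:
        raise ValueError("variance_threshold must lie in (0, 1]")
    X = np.vstack([tr.moments for tr in trials])
    NJ = X.shape[1]
    if X.shape[0] < NJ:
        raise ValueError(f"need at least {NJ} pooled samples, got {X.shape[0]}")
    Xc = X - X.mean(axis=0)
    s = np.linalg.svd(Xc, compute_uv=False)
    var = s ** 2
    total = var.sum()
    if total == 0:
        raise ValueError("moments have zero variance")
    frac = var / total
    cum = np.cumsum(frac)
    count = int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)
    count = min(count, NJ)
    if return_spectrum:
        return count, frac
    return count
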