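"""Synergy comparison statistics.

Two synergy sets are compared by (1) matching synergies through the
similarity index — the dot product of unit-normalized weighting vectors —
via optimal assignment, (2) Pearson correlations between the matched
control signals per condition, and (3) a single "mean correlation" over all
control signals interpolated to 30 points per gait cycle and concatenated
in a fixed synergy-major order. Values above 0.8 indicate high similarity,
0.5-0.8 moderate, below 0.5 low.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import pearsonr

__all__ = [
    "ComparisonReport",
    "similarity_index",
    "match_synergies",
    "control_correlation",
    "mean_correlation",
    "classify_similarity",
    "compare_structures",
]

POINTS_PER_CYCLE = 30


@dataclass
class ComparisonReport:
    """Correspondence map and similarity/correlation statistics."""

    correspondence: dict[int, int]          # synergy of A -> synergy of B
    si_per_synergy: list[float]
    si_mean: float
    si_sd: float
    rho_per_signal: dict[str, list[float]]  # condition -> rho per synergy (A order)
    rho_mean: float
    bands: dict[str, str]

    def __post_init__(self) -> None:
        vals = sorted(self.correspondence.values())
        if vals != list(range(len(vals))):
            raise ValueError("correspondence must be a bijection")

    def to_dict(self) -> dict:
        return {
            "correspondence": {str(k): int(v) for k, v in self.correspondence.items()},
            "si_per_synergy": [float(x) for x in self.si_per_synergy],
            "si_mean": float(self.si_mean),
            "si_sd": float(self.si_sd),
            "rho_per_signal": {c: [float(x) for x in v]
                               for c, v in self.rho_per_signal.items()},
            "rho_mean": float(self.rho_mean),
            "bands": dict(self.bands),
        }


def similarity_index(w1, w2) -> float:
    """Dot product of the unit-normalized weighting vectors (1 = identical)."""
    w1 = np.asarray(w1, dtype=float)
    w2 = np.asarray(w2, dtype=float)
    if w1.shape != w2.shape or w1.ndim != 1:
        raise ValueError("weighting vectors must be 1-D and of equal length")
    n1, n2 = np.linalg.norm(w1), np.linalg.norm(w2)
    if n1 == 0 or n2 == 0:
        raise ValueError("zero weighting vector")
    return float(w1 @ w2 / (n1 * n2))


def match_synergies(W_a, W_b) -> dict[int, int]:
    """Bijection A->B maximizing total similarity (optimal assignment).

    Ties resolve deterministically (lowest index) through the assignment
    solver's lexicographic behavior on the fixed-order cost matrix.
    """
    W_a = np.asarray(W_a, dtype=float)
    W_b = np.asarray(W_b, dtype=float)
    if W_a.shape != W_b.shape:
        raise ValueError(f"shape mismatch: {W_a.shape} vs {W_b.shape}")
    n = W_a.shape[1]
    S = np.array([[similarity_index(W_a[:, i], W_b[:, j]) for j in range(n)]
                  for i in range(n)])
    rows, cols = linear_sum_assignment(-S)
    return {int(i): int(j) for i, j in zip(rows, cols)}


def control_correlation(h_a, h_b):
    """Pearson correlation (and p-value) between two control signals."""
    h_a = np.asarray(h_a, dtype=float)
    h_b = np.asarray(h_b, dtype=float)
    if h_a.shape != h_b.shape or h_a.ndim != 1:
        raise ValueError("control signals must be 1-D and equally sampled")
    if np.ptp(h_a) == 0 or np.ptp(h_b) == 0:
        raise ValueError("constant control signal")
    r = pearsonr(h_a, h_b)
    return float(r.statistic), float(r.pvalue)


def _cycle_resample(h: np.ndarray, times: np.ndarray, cycle_times: np.ndarray,
                    average_cycles: bool = True) -> np.ndarray:
    """Interpolate a control signal to 30 points per gait cycle.

    With ``average_cycles`` the per-cycle traces are averaged into a single
    30-point profile; otherwise cycles are concatenated.
    """
    chunks = []
    for c0, c1 in zip(cycle_times[:-1], cycle_times[1:]):
        tq = np.linspace(c0, c1, POINTS_PER_CYCLE, endpoint=False)
        chunks.append(np.interp(tq, times, h))
    if average_cycles:
        return np.mean(chunks, axis=0)
    return np.concatenate(chunks)


def mean_correlation(H_a: dict, H_b: dict, correspondence: dict[int, int],
                     times: dict, cycle_times: dict,
                     average_cycles: bool = True,
                     times_b: dict | None = None,
                     cycle_times_b: dict | None = None) -> float:
    """Single Pearson rho over all controls, 30 points per gait cycle.

    Signals are resampled per cycle, cycle-averaged by default, and
    concatenated synergy-major then condition (conditions in sorted label
    order) — the same fixed order for both sets, which is all Pearson's
    rho requires. The two sets may be sampled on different grids
    (``times_b``/``cycle_times_b`` default to the first set's); only the
    30-point-per-cycle resample enters the statistic.
    """
    conds = sorted(H_a)
    if sorted(H_b) != conds:
        raise ValueError("condition sets differ")
    tb = times_b if times_b is not None else times
    cb = cycle_times_b if cycle_times_b is not None else cycle_times
    va, vb = [], []
    n_syn = len(correspondence)
    for k in range(n_syn):
        for c in conds:
            va.append(_cycle_resample(H_a[c][k], times[c], cycle_times[c],
                                      average_cycles))
            vb.append(_cycle_resample(H_b[c][correspondence[k]], tb[c],
                                      cb[c], average_cycles))
    r, _ = control_correlation(np.concatenate(va), np.concatenate(vb))
    return r


def classify_similarity(value: float) -> str:
    """Band a similarity index or correlation: high / moderate / low.

    Above 0.8 is high; 0.5 through 0.8 inclusive is moderate; below 0.5 is
    low (both boundaries belong to the moderate band).
    """
    if not np.isfinite(value):
        raise ValueError("non-finite similarity value")
    if value > 0.8:
        return "high"
    if value >= 0.5:
        return "moderate"
    return "low"


def compare_structures(struct_a, struct_b, times: dict, cycle_times: dict,
                       muscles: list[int] | None = None,
                       average_cycles: bool = True,
                       normalize: bool = True,
                       times_b: dict | None = None) -> ComparisonReport:
    """Full comparison of two synergy structures sharing a muscle set.

    ``muscles`` restricts the weighting comparison to a subset of muscle
    indices (for cross-study comparisons where only some muscles are
    shared). Controls are compared per synergy and condition, plus the
    pooled mean correlation.

    Weightings and controls are only determined up to a per-synergy scale
    exchange (W D, D^-1 H); by default both structures are first rescaled
    to unit-norm weighting columns so control magnitudes are comparable in
    the pooled correlation (the similarity index is scale-invariant either
    way).
    """
    if normalize:
        struct_a = struct_a.normalized()
        struct_b = struct_b.normalized()
    tb = times_b if times_b is not None else times
    W_a, W_b = struct_a.W, struct_b.W
    if muscles is not None:
        W_a, W_b = W_a[muscles, :], W_b[muscles, :]
    corr = match_synergies(W_a, W_b)
    si = [similarity_index(W_a[:, k], W_b[:, corr[k]]) for k in corr]
    rho_per = {}
    for c in sorted(struct_a.H):
        rho_per[c] = []
        for k in corr:
            ha = _cycle_resample(struct_a.H[c][k], times[c], cycle_times[c],
                                 average_cycles)
            hb = _cycle_resample(struct_b.H[c][corr[k]], tb[c],
                                 cycle_times[c], average_cycles)
            r, _ = control_correlation(ha, hb)
            rho_per[c].append(r)
    rho_mean = mean_correlation(struct_a.H, struct_b.H, corr, times,
                                cycle_times, average_cycles, times_b=tb)
    si_mean = float(np.mean(si))
    return ComparisonReport(
        correspondence=corr,
        si_per_synergy=si,
        si_mean=si_mean,
        si_sd=float(np.std(si, ddof=1)) if len(si) > 1 else 0.0,
        rho_per_signal=rho_per,
        rho_mean=rho_mean,
        bands={"si_mean": classify_similarity(si_mean),
               "rho_mean": classify_similarity(rho_mean)},
    )
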