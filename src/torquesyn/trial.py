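"""Per-condition experimental (or synthetic) input bundle.

A trial holds everything the torque decomposition consumes for one movement
condition (a "walking speed"): the joint-moment time series to be
reproduced, the muscle-tendon lengths and signed moment arms that define
each muscle's geometry over time, and the gait-cycle boundaries used for
time normalization of synergy controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TrialData"]


@dataclass
class TrialData:
    """One condition's time grid and experimental series.

    Attributes
    ----------
    condition : label of the movement condition.
    time : (P,) strictly increasing sample times, s.
    moments : (P, NJ) joint moments, N*m.
    mt_lengths : (P, m) muscle-tendon lengths, m.
    moment_arms : (P, m, NJ) signed moment arms, m.
    cycle_times : gait-cycle boundary times (len n_cycles + 1), s.
    dof_names, muscle_names : column labels.
    """

    condition: str
    time: np.ndarray
    moments: np.ndarray
    mt_lengths: np.ndarray
    moment_arms: np.ndarray
    cycle_times: np.ndarray
    dof_names: list[str] = field(default_factory=list)
    muscle_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.moments = np.asarray(self.moments, dtype=float)
        self.mt_lengths = np.asarray(self.mt_lengths, dtype=float)
        self.moment_arms = np.asarray(self.moment_arms, dtype=float)
        self.cycle_times = np.asarray(self.cycle_times, dtype=float)
        P = len(self.time)
        if P < 2 or np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing with >= 2 samples")
        if self.moments.shape[0] != P or self.mt_lengths.shape[0] != P \
                or self.moment_arms.shape[0] != P:
            raise ValueError("inconsistent sample counts across arrays")
        if self.moment_arms.shape[1] != self.mt_lengths.shape[1] \
                or self.moment_arms.shape[2] != self.moments.shape[1]:
            raise ValueError(
                f"moment_arms shape {self.moment_arms.shape} inconsistent with "
                f"moments {self.moments.shape} / mt_lengths {self.mt_lengths.shape}"
            )
        for arr, name in ((self.moments, "moments"),
                          (self.mt_lengths, "mt_lengths"),
                          (self.moment_arms, "moment_arms")):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
        t0, t1 = self.time[0], self.time[-1]
        if np.any(self.cycle_times < t0 - 1e-9) or np.any(self.cycle_times > t1 + 1e-9):
            raise ValueError("cycle boundaries outside the time window")
        if not self.dof_names:
            self.dof_names = [f"dof{j}" for j in range(self.n_dofs)]
        if not self.muscle_names:
            self.muscle_names = [f"m{i}" for i in range(self.n_muscles)]

    @property
    def n_dofs(self) -> int:
        return self.moments.shape[1]

    @property
    def n_muscles(self) -> int:
        return self.mt_lengths.shape[1]

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])

    @property
    def n_cycles(self) -> int:
        return max(len(self.cycle_times) - 1, 1)

    @property
    def cycle_period(self) -> float:
        return self.duration / self.n_cycles

    def resample(self, times: np.ndarray) -> "TrialData":
        """Linear interpolation of every series onto new sample times."""
        times = np.asarray(times, dtype=float)
        if times[0] < self.time[0] - 1e-9 or times[-1] > self.time[-1] + 1e-9:
            raise ValueError("resample times outside the trial window")

        def interp_cols(arr):
            flat = arr.reshape(arr.shape[0], -1)
            out = np.empty((len(times), flat.shape[1]))
            for c in range(flat.shape[1]):
                out[:, c] = np.interp(times, self.time, flat[:, c])
            return out.reshape((len(times),) + arr.shape[1:])

        return TrialData(
            condition=self.condition,
            time=times,
            moments=interp_cols(self.moments),
            mt_lengths=interp_cols(self.mt_lengths),
            moment_arms=interp_cols(self.moment_arms),
            cycle_times=self.cycle_times,
            dof_names=list(self.dof_names),
            muscle_names=list(self.muscle_names),
        )
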