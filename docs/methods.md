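# Methods

`torquesyn` decomposes joint-moment time series into muscle synergies by
solving an optimal control problem over Hill-type muscle dynamics. This
note records the model, the numerical choices behind the solver, what the
synthetic plant does and does not emulate, and the known limitations.

## Problem statement

For each movement condition *s* (a "walking speed"), the inputs are joint
moments M\*<sub>j</sub>(t) at N<sub>J</sub> degrees of freedom,
muscle-tendon lengths L<sup>MT</sup><sub>i</sub>(t) and signed moment arms
R<sub>ij</sub>(t) for *m* muscles, typically three gait cycles per
condition. The decomposition finds a non-negative weighting matrix **W**
(m × N<sub>syn</sub>), shared across all conditions, and non-negative
control signals h<sub>sk</sub>(t) per condition, such that the excitations

u<sub>is</sub>(t) = Σ<sub>k</sub> W<sub>ik</sub> h<sub>sk</sub>(t),  0 < u < 1,

driven through activation dynamics ȧ = f₃(a, u) and contraction dynamics
l̇ = f₂(a, l, L<sup>MT</sup>), produce muscle forces whose moment-arm
weighted sum M<sub>j</sub> = Σ<sub>i</sub> R<sub>ij</sub> F<sub>i</sub>
tracks M\*. The objective is the discretized sum of squared moment errors,
optionally plus K · Σ a² (the "effort" or optimal-synergy variant; K = 0 is
the pure-synergy variant). Skeletal equations of motion are deliberately
excluded: moments, lengths and arms are precomputed inputs.

## Muscle model

The muscle-tendon actuator is the standard dimensionless Hill curve set:

| element | form | constants (defaults) |
|---|---|---|
| active force-length | exp(−(l̃−1)²/γ) | γ = 0.45 |
| passive force-length | (e^{k(l̃−1)/ε₀ᵐ}−1)/(e^k−1), floored at 0 | k = 4, ε₀ᵐ = 0.6 |
| tendon | exponential toe to 0.609 ε₀ᵗ, then linear | F_toe = 0.33, k_toe = 3 |
| force-velocity | hyperbolic, concentric/eccentric branches | A_f = 0.25, F_len = 1.4 |
| activation | two-regime first order, tanh-blended | τ_act = 20 ms, τ_deact = 50 ms |
| pennation | constant thickness, l sin α = l₀ sin α₀ | — |

Notes on the less-standard points:

- **Tendon linear slope.** The linear-region slope is set to
  (1 − F_toe)/(ε₀ᵗ − 0.609 ε₀ᵗ) so that tendon force equals F_max *exactly*
  at the strain parameter ε₀ᵗ (`eps_t_max`) — that parameter's definition —
  rather than the commonly printed 1.712/ε₀ᵗ, which lands at 0.999 F_max.
- **Activation law.** ȧ = (u − a)·[w/τ_act + (1 − w)/τ_deact] with
  w = ½ + ½ tanh(40 (u − a)). The tanh blend makes the two-regime law C¹ so
  the collocation problem stays differentiable; at |u − a| ≳ 0.1 it is
  numerically identical to the hard-switched law. The published variants of
  this law differ between sources; this is the package's documented choice.
- **Velocity inversion.** Fiber velocity is obtained in closed form by
  inverting the force-velocity hyperbola given the tendon force implied by
  the geometry. Outside the physical branch (active force below 0 or above
  95% of the eccentric asymptote) the inverse continues linearly, and the
  result passes through a C¹ saturation that is exactly linear up to v_max
  and rolls off to a hard cap of 1.6 v_max. Both guards only activate far
  from equilibrium (they protect the per-interval Newton solves, not the
  converged solutions).
- **Singularity guards.** Activation and excitation are bounded below by
  0.01 (the force-velocity inversion divides by a·f_L). Normalized fiber
  length is clamped to [0.05, 1.8] inside curve evaluations, with a module
  counter (`muscle.clamp_counter`) tallying excursions.

## Transcription and solver

States (a, l per muscle) and controls (h per synergy) live at P equispaced
collocation nodes per condition (~0.1 s spacing by default, ≈35 nodes over
three gait cycles). Between adjacent nodes the dynamics are enforced by
defect equations of a Hermite–Simpson scheme evaluated on **4 refined
sub-steps per interval**, with controls interpolated linearly. A plain
trapezoidal scheme and other sub-step counts are selectable
(`OcpSpec(scheme=..., n_substeps=...)`).

Why sub-steps: at ~12 nodes per gait cycle a single per-interval rule
(trapezoidal or Hermite–Simpson) leaves a discretization bias of order
0.5–5% NRMSE. An optimizer happily *exploits* that bias — it can push the
node-sampled moment error well below the bias by making the controls
wiggle, at the cost of a solution that a forward simulation of the same
ODEs no longer reproduces. Refining the inter-node integration removes the
bias, so the collocation solution is dynamically consistent by
construction: the forward-vs-collocation NRMSE of solutions is ~0.01% on
the default fixture. For the same reason, the muscle-tendon length seen by
the transcription between nodes is the linear interpolant of its *node*
values (the transcribed problem is fully defined by node data and the
forward check consumes exactly the same inputs).

The solver condenses the transcription: for any candidate (W, H, a₀, l₀)
the defect equations are solved interval by interval with a safeguarded
(bracketed) Newton method, eliminating the states exactly; the reduced
nonlinear least-squares problem is then solved by trust-region Gauss–Newton
(`scipy.optimize.least_squares`, TRF) with forward sensitivities propagated
analytically through the implicit steps (implicit function theorem; the
fiber-velocity partials use central differences of the closed-form
inverse). Excitation bounds enter as a smooth clamp (width 10⁻³) inside the
dynamics plus a hinge penalty on u > 1; non-negativity of W and H and the
state bounds are hard solver bounds. The returned full decision vector
satisfies every defect equation to Newton tolerance (~10⁻¹²), which is the
package's substitute for a general sparse NLP solver; the objective value,
NRMSE and activation cost reported on a solution are recomputable from its
stored trajectories.

The hot loop (per-interval Newton plus sensitivity recursions) is compiled
with numba; a pure-numpy reference implementation of the same recursions is
kept and the test suite asserts parity between the two.

### Multi-start protocol

Each decomposition is restarted from several initial guesses: NNMF of
arbitrary excitation patterns (per-muscle constants, or 1–3 seeded
half-sine pulses per gait cycle) with muscle states obtained by integrating
the dynamics under the reconstructed excitations. The first start is
model-informed instead of arbitrary: per-node non-negative least squares of
a linearized static muscle model against the moments (classic static
optimization), then NNMF. At desk scale the arbitrary starts alone often
stall in mixed-grouping local minima; the static start reliably lands in
the global basin, and the arbitrary starts remain as independent probes of
the solution's uniqueness. The minimum-NRMSE start is selected and its
local optimization continued with a deeper iteration budget (default: 6
starts × 300 evaluations, 1200-evaluation polish). The 15-start,
arbitrary-only protocol is a parameter choice away.

## Metrics and protocols

- **NRMSE**: √(Σ errors²/(N_J · ΣP)) normalized by the global experimental
  moment range over all conditions, nodes and DOFs, in percent.
- **Admissibility limits**: upper limit from substituting 5% of each
  DOF-and-condition moment range as the error; lower limit from
  substituting a constant 1 N·m (algebraically 100/range %).
- **Count selection**: the largest N_syn whose multi-start NRMSE lies
  strictly inside the limits.
- **Effort sweep**: K ∈ {0, 100, …, 500}, warm-started; stop at the first
  K whose activation-cost drop to the next K falls below
  Δ = Σ a² − Σ max(0.01, a − 0.01)² (the cost shed if every activation
  dropped by 0.01). The Δ sum runs over *all muscles* — its printed form
  indexes activations by DOF count, which is dimensionally inconsistent
  with the effort term and treated as a typo.
- **Frozen-weightings validation**: held-out conditions are solved with W
  fixed; only controls and states are free.
- **Comparison statistics**: synergies are matched by optimal assignment
  on the similarity index (dot product of unit-norm weighting vectors);
  controls are compared per synergy/condition by Pearson correlation and
  pooled into a single correlation after interpolation to 30 points per
  gait cycle (cycle-averaged by default; per-cycle mode available),
  concatenated synergy-major then condition. Both structures are first
  rescaled to unit-norm weighting columns: the model is invariant under
  (W D, D⁻¹ H) for positive diagonal D, and the pooled statistic is
  deliberately scale-sensitive, so a normalization convention is required
  for it to be well-defined. Bands: > 0.8 high, 0.5–0.8 moderate (both
  boundaries moderate), < 0.5 low.
- **Moment dimensionality**: PCA (SVD of centered pooled moments); the
  smallest component count reaching the variance threshold (default 90%).

## Synthetic plant

The plant emulates a scaled lower-limb model driven through gait: 8
muscles with literature-scale Hill parameters (F_max 1–3 kN, l₀ 8–12 cm,
tendon 1.6–2.4 l₀), 3 DOFs, two training conditions (cycle periods 1.25 s
and 1.0 s, three cycles each) plus a held-out intermediate condition
(1.1 s). Muscle-tendon lengths are cycle-periodic two-harmonic signals
whose excursions keep normalized fiber length near [0.6, 1.3]; moment arms
are cycle-periodic signed sinusoids (≤ 0.06 m) with each muscle spanning
1–2 DOFs and every DOF actuated in both directions. The ground truth is a
sparse shared W (2–4 dominant muscles per synergy) with per-condition
raised-cosine bump-train controls, rejection-sampled until every
excitation lies in (0.02, 0.95); "experimental" moments come from an
adaptive Runge–Kutta integration of the true structure (optionally with
seeded Gaussian moment noise, relative to the global moment range; the
default study is noise-free). The resulting joint moments span ≈220 N·m,
which puts the 1 N·m lower limit near 0.46% and the 5% upper limit near
2.2% — the scale of adult walking data.

Deliberate simplifications: moment arms are drawn independently of the
muscle-tendon lengths (there is no joint-angle coordinate, so R ≠ ∂L/∂q);
no skeletal dynamics, no ground reaction forces, no EMG. Passing the
recovery study therefore shows that the estimator inverts its own model
class under realistic signal scales and redundancy — not that it is robust
to the kinematic inconsistencies, soft-tissue artifact or model mismatch
of real motion-capture pipelines.

## Known limitations and observed behavior

- **The count-selection band presumes an irreducible misfit floor.** On
  real data, model error keeps the best NRMSE between the limits at the
  minimal sufficient count. On the noise-free synthetic fixture the
  decomposition at the true count converges to ~0.15% NRMSE — *below* the
  1 N·m lower limit — so the selection rule reports "no admissible count"
  rather than the true count: every candidate is either too poor (count
  2, just above the upper limit) or "too good". The NRMSE-vs-count curve
  itself behaves as expected (sharp drop at the true count). With moment
  noise of ~1% of range the floor moves into the band and the rule
  recovers its intended behavior.
- The (W, H) factorization is unique only up to permutation and scale,
  and only as identifiable as the controls are diverse; with overlapping
  bump timings the per-condition correlations of individual synergies can
  be low even when the pooled statistics are high.
- Fiber-velocity sensitivities are finite-difference at the innermost
  level; near curve kinks (clamp and branch boundaries) the Jacobian is
  only approximately one-sided, which trust-region Gauss–Newton tolerates
  but a line-search method might not.
- Runtimes (single CPU): one multi-start decomposition at one count ≈ 2–4
  min at the default sizes; the full study (counts 2–4, consistency check,
  K sweep, held-out validation) ≈ 10–15 min.
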