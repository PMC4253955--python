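# torquesyn

Synergy-constrained decomposition of joint moments: recover a shared set of
non-negative muscle weightings **W** and per-condition synergy control
signals h<sub>sk</sub>(t) that, when driven through Hill-type muscle
activation and contraction dynamics, reproduce experimental joint-moment
time series.

Muscle-synergy analysis usually factorizes surface EMG. This tool instead
extracts synergies from standard motion-capture products — inverse-dynamics
joint moments plus the musculoskeletal model's muscle-tendon lengths and
moment arms — so synergy structure can be studied in subjects or datasets
where EMG is unavailable, and the recovered structure is quantitatively
tied to the biomechanical output it must reproduce.

## The problem it solves

Given, per movement condition *s* (e.g. a walking speed), moments
M\*<sub>j</sub>(t) at N<sub>J</sub> degrees of freedom, muscle-tendon
lengths L<sup>MT</sup><sub>i</sub>(t) and signed moment arms
R<sub>ij</sub>(t) for *m* muscles, find non-negative **W** (shared across
conditions) and h<sub>sk</sub>(t) ≥ 0 minimizing

J = Σ<sub>s</sub> Σ<sub>n</sub> ( Σ<sub>j</sub> [M<sub>jn</sub> − M\*<sub>jn</sub>]² + K Σ<sub>i</sub> a<sub>in</sub>² )

subject to muscle dynamics ȧᵢ = f₃(aᵢ, uᵢ), l̇ᵢ = f₂(aᵢ, lᵢ, L<sup>MT</sup>ᵢ),
force generation F<sub>i</sub> = f₁(lᵢ, L<sup>MT</sup>ᵢ), the moment map
M<sub>j</sub> = Σ<sub>i</sub> R<sub>ij</sub> F<sub>i</sub>, and the linear
synergy combination uᵢ = Σ<sub>k</sub> W<sub>ik</sub> h<sub>sk</sub> with
0.01 ≤ u ≤ 1. K = 0 is the *pure-synergy* problem; K > 0 adds an effort
(activation-squared) penalty, with K chosen by a sweep and an
activation-cost significance rule.

The continuous problem is transcribed by direct collocation (states and
controls at ~35 equispaced nodes per condition; Hermite–Simpson defects
integrated on refined sub-steps) and solved by a condensed trust-region
Gauss–Newton method with analytic sensitivities — see `docs/methods.md`.

Around the core solver the package implements the full study protocol:
multi-start solves from NNMF-factorized excitation patterns, the NRMSE
goodness metric with 5%-of-range / 1 N·m admissibility limits, synergy-count
selection, forward-dynamic consistency checking, frozen-weightings
validation on held-out conditions, synergy comparison statistics
(similarity index, optimal matching, per-signal and pooled Pearson
correlations on a 30-points-per-cycle grid), joint-moment PCA
dimensionality, and a synthetic gait plant with known ground truth for
end-to-end validation.

## Worked example

Recover a known 3-synergy structure from synthetic gait data (8 muscles, 3
DOFs, two speeds of three gait cycles each, noise-free moments):

```python
from torquesyn.study import default_fixture, run_recovery_study

study = run_recovery_study(seed=0, verbose=True)
```

prints (single CPU, ~10–15 min):

```
  n_syn=2: NRMSE 2.192% (starts: ['2.23', '3.74', '4.89', '2.41', '2.43', '4.82'])
  n_syn=3: NRMSE 0.141% (starts: ['0.22', '2.37', '4.84', '0.14', '2.33', '1.89'])
  n_syn=4: NRMSE 0.176% (starts: ['0.94', '1.41', '4.11', '2.66', '1.10', '1.45'])
  recovery: SI 0.959, rho 0.908
  forward check: vs collocation 0.0075%
  K sweep: chosen K=200, costs {0: 67.6, 100: 25.6, 200: 24.0, 300: 23.1}
  held-out validation: NRMSE 1.310%
```

Reading the numbers: the moment-tracking error (NRMSE, normalized by the
~220 N·m global moment range) collapses from 2.19% with two synergies to
0.14% at the true count of three — two synergies cannot span the moment
structure, three reproduce it almost exactly, and a fourth is redundant.
The recovered weightings match the generating ones with mean similarity
index 0.96 and the control signals correlate at ρ = 0.91 after optimal
matching. Forward integration of the recovered structure through the
continuous muscle dynamics reproduces the collocation moments to 0.0075%,
confirming the solution respects the dynamics rather than the grid. The
effort sweep picks K = 200: raising K from 0 to 100 cuts the activation
cost from 67.6 to 25.6, the further drop to 24.0 at K = 200 is the last
one exceeding the significance threshold, and moment tracking stays
admissible. Weightings frozen from the two training speeds reproduce a
held-out intermediate speed at 1.31% NRMSE — inside the admissibility band
(0.47%, 2.17%) — supporting speed-invariant muscle groupings.

On this noise-free fixture the count-*selection* rule itself reports "no
admissible count": the fits at counts 3–4 are *better* than the 1 N·m
lower limit that flags redundancy on real data. `docs/methods.md`
discusses why that is inherent to noise-free synthetic data.

### Command line

```
torquesyn --seed 0 --out-dir out make-fixture
torquesyn --out-dir out decompose out/trials --n-syn 3
torquesyn --out-dir out validate out/trials out/structure/weightings.csv
torquesyn --out-dir out sweep-k out/trials --n-syn 3
torquesyn --out-dir out simulate out/trials out/structure
torquesyn --out-dir out compare out/structure out/truth out/trials
torquesyn --out-dir out dimensionality out/trials
```

Each subcommand writes CSV result bundles plus a JSON decision record; all
randomness flows from `--seed`.

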