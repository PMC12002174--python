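# lvgames

Tools for studying what happens to evolutionary game dynamics when the
game is *not* the only source of fitness differences.

The replicator equation, ẋᵢ = xᵢ(fᵢ − f̄), assumes that all types share
the same intrinsic growth rate, so that fitness differences arise only
from the payoff matrix. Most biological populations violate this
assumption. `lvgames` starts instead from the generalized Lotka–Volterra
(LV) equations for absolute abundances,

    ṅᵢ = nᵢ (rᵢ + Σⱼ aᵢⱼ nⱼ),

where `aᵢⱼ` is the per-capita effect of type *j* on type *i* and `rᵢ` is
the intrinsic growth rate of type *i* when rare and alone. Writing the
dynamics of relative frequencies x₁ = n₁/(n₁+n₂) gives

    ẋ₁ = (n₁+n₂) x₁ x₂ [ (r₁−r₂)/(n₁+n₂) + f₁ − f₂ ],

which reduces to the replicator equation (up to a rescaling of time by
the positive factor n₁+n₂) exactly when r₁ = r₂. When the rates differ,
no stand-alone frequency equation exists, and predictions made from the
payoff matrix alone can be qualitatively wrong.

The package is for theoretical ecologists and evolutionary game
theorists who want to:

- **simulate** the four dynamical systems side by side (LV abundances,
  replicator frequencies, the exact coupled frequency/total-abundance
  system, and a frequency-dependent LV variant), with tight default
  tolerances that preserve neutral cycles and conserved quantities;
- **classify** the long-run outcome of any bounded two-type system
  (dominance, coexistence, bistability, joint extinction, unbounded)
  directly from `(A, r)`: unequal rates shift the classic game-quadrant
  boundaries from `(a₁₁, a₂₂)` to `(a₁₁ r₂/r₁, a₂₂ r₁/r₂)`, each
  boundary being a mutual-invasibility condition;
- **assemble** multi-type communities step by step — one rare
  introduction at a time into a fully relaxed resident community — and
  ask whether a target community (e.g. a full Rock–Paper–Scissors
  cycle) can be built at all.

## Worked example: a social dilemma that is not a dilemma

The interaction matrix `A = [[−3, −5], [1, −4]]` obeys the payoff
ranking `a₂₁ > a₁₁ > a₂₂ > a₁₂` of a Prisoner's Dilemma: type 2
("defector") beats type 1 ("cooperator") in every pairwise encounter.
The replicator prediction is extinction of cooperators. But the
dilemma evaporates if cooperators hold an intrinsic growth-rate
advantage:

```python
>>> import numpy as np, lvgames as lv
>>> A = np.array([[-3., -5.], [1., -4.]])
>>> lv.critical_r1(A, 1.0)          # minimal r1 for coexistence, at r2 = 1
1.25
```

A 25 % growth advantage suffices. With `r = (2, 1)` the LV flow carries
`(0.1, 0.1)` to a stable interior point:

```python
>>> s = lv.example_system("pd_coexistence")   # same A, r = (2, 1)
>>> traj = lv.integrate_lv(s, [0.1, 0.1], 200.0)
>>> traj.final                                 # interior equilibrium (3/17, 5/17)
array([0.17647059, 0.29411765])
>>> traj.frequencies()[-1, 0]                  # cooperator frequency -> 3/8
0.3749999999921237
```

while the replicator equation for the same matrix sends the cooperator
frequency to zero. `check_equivalence` quantifies the discrepancy, and
confirms the exact equivalence at equal rates:

```python
>>> lv.check_equivalence(lv.example_system("pd_equal"), [0.1, 0.1], 100.0)
EquivalenceReport(max_orbit_deviation=5.724729024159103e-11, equivalent=True, threshold=1e-06)
```

The same analysis is available from the shell:

```sh
$ lvgames classify pd_coexistence
{
  "game_class": "PRISONERS_DILEMMA",
  "ecological_class": "EXPLOITATION",
  "outcome": "COEXISTENCE",
  "boundaries": {"a21_threshold": -1.5, "a12_threshold": -8.0},
  ...
}
```

The matrix still *reads* as a Prisoner's Dilemma, but the dynamical
outcome is coexistence: the game-theoretic label has lost its meaning.

## Assembling a cyclic community

With the symmetric Rock–Paper–Scissors matrix (self-limitation −1,
winning +α, losing −α, α = 1.3) and equal growth rates, every pairwise
encounter is a dominance relation, so no introduction order can build
the three-type cycle — each newcomer simply replaces the resident.
Speeding Rock up to r_R = 2.5 turns the R+P pair into a coexistence
pair, through which the full community assembles:

```sh
$ lvgames assemble rps_equal --search R,P,S      # "possible": false
$ lvgames assemble rps_fast_rock --search R,P,S  # "possible": true, order R,P,S
```

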