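# colicomp

Cross-induction competition between bacteriocin-producing bacteria: a
well-mixed ODE model, its 1D/2D reaction–diffusion extension, and the assay
computations (spot titer, luminescence response ratio, induction calls,
potency–induction correlation) used to characterize the underlying biology.

## The problem

Colicins are narrow-spectrum protein toxins with which *E. coli* strains kill
close relatives. Producers are immune to their own toxin, and because colicin
release requires the producing cell to lyse, production is costly. When two
*producer* strains compete, a twist appears: each strain's toxin (via the SOS
stress response) can *induce* the other strain's toxin production. Potent
toxins tend to be strong inducers — so a strain with a deadly, strongly
inducing colicin arms its weaker opponent without reciprocation, and can lose
the fight. `colicomp` is a package for exploring when that happens, for
people studying microbial interference competition and toxin-mediated
community dynamics.

## The model

Two strains with frequencies $u_A, u_B$ (relative to a shared carrying
capacity of 1) produce toxins with densities $c_A, c_B$. For $i \in \{A,B\}$
and $j$ the competitor:

$$\dot u_i = \beta_i u_i (1 - u_A - u_B) - \delta u_i - \gamma_{j\to i}\, c_j u_i - \varepsilon\,(s + l_{j\to i}\, c_j)\, u_i$$

$$\dot c_i = (s + l_{j\to i}\, c_j)\, u_i - d\, c_i$$

with growth $\beta_i$, background death $\delta$, per-pair kill coefficients
$\gamma_{j\to i}$, basal toxin production $s$, per-pair induction
coefficients $l_{j\to i}$, toxin decay $d$, and an optional lysis-cost
coefficient $\varepsilon$ (default 0). The spatial version adds
$D_u \nabla^2 u_i$ and $D_c \nabla^2 c_i$, integrated with an explicit
finite-difference scheme on 1D/2D grids with no-flux boundaries. See
`docs/methods.md` for assumptions, parameter conventions (including the two
published readings of the per-strain symbols $\gamma_i$, $l_i$), and
numerical choices.

The assay side implements the two standard bench readouts: the spot titer
(inverse of the greatest dilution still clearing an inhibition zone on a
sensitive lawn) and the reporter response ratio (induced over non-induced
luminescence, with ratios above 2 called as induction), plus the Pearson
correlation between a colicin's titer and the mean response it triggers. A
published 8×8 reference response panel ships with the package, and seeded
synthetic generators emulate every input so the whole pipeline runs without
external data.

## Worked example

```python
from colicomp import run_competition, reference_response_panel, find_critical_frequency
from colicomp.assays import induction_matrix
from colicomp.synth import gen_competition_scenarios

# a weak inducer (A) vs a slightly more potent, strongly inducing strain (B)
pr = gen_competition_scenarios()["weak_vs_strong"]
traj, outcome = run_competition(pr.params, pr.init)
print(f"outcome: {outcome.label}")
print(f"community minimum during the fight: {outcome.crash_depth:.3f} (started at 0.6)")
print(f"final density of the weak inducer: {outcome.final_state.u_A:.3f}")

# induction calls on the published reference panel at the ratio > 2 threshold
calls = induction_matrix(reference_response_panel(), threshold=2.0)
print(f"induced calls across the panel: {calls.total}")
print(f"calls in the ColE6 column: {int(calls.counts['ColE6'])}")

# exchange-symmetric strains: the critical initial frequency is 1/2
res = find_critical_frequency(gen_competition_scenarios()["symmetric"].params,
                              u_total=0.6, tol=1e-3)
print(f"symmetric critical frequency: {res.rho_c:.4f}")
```

prints

```
outcome: A_wins
community minimum during the fight: 0.322 (started at 0.6)
final density of the weak inducer: 0.900
induced calls across the panel: 36
calls in the ColE6 column: 1
symmetric critical frequency: 0.5005
```

The weak inducer wins: B's strong induction makes A hyper-produce toxin A,
the community density dips while B is eliminated, and A recovers to the
single-strain equilibrium $1 - \delta/\beta = 0.9$. On the reference panel,
36 of the 49 colicin × reporter combinations are called induced; the mild
ColE6 extract induces only the divergent Lum-Ib reporter.

A command-line interface mirrors the library:

```bash
colicomp simulate-well-mixed --params params.json --init "uA=0.3,uB=0.3" --horizon 200 --out traj.csv
colicomp critical-frequency --params params.json --tol 1e-3
colicomp phase-diagram --params params.json --axis1 kill_BonA:0.5:4:6 --axis2 induce_BonA:10:70:6 --out grid.csv
colicomp simulate-spatial --params params.json --pattern droplets:n=24:r=3 --grid 128x128 --horizon 500 --out snapshots/
colicomp assay calls            # induction calls on the built-in panel
colicomp synth panel --seed 1 --out synth/
```

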