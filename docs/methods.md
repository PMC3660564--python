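# Methods

## Model

Two bacteriocin-producing strains share one habitat with carrying capacity
normalized to 1. Strain frequencies `u_A`, `u_B` and toxin densities `c_A`,
`c_B` evolve (for `i` a strain, `j` its competitor) as

```
du_i/dt = beta_i*u_i*(1 - u_A - u_B) - delta*u_i
          - kill_jOni*c_j*u_i - epsilon*(s + induce_jOni*c_j)*u_i
dc_i/dt = (s + induce_jOni*c_j)*u_i - d*c_i
```

This system is a **reconstruction**: it is the minimal ODE model consistent
with the stated biology — logistic growth to a shared carrying capacity,
background death, killing by the competitor's toxin only, a basal (SOS
leakage) production rate `s`, induction of a strain's own production in
proportion to the competitor's toxin, and first-order toxin decay. Toxin
production is proportional to the producing strain's density (`u_i` in the
`c_i` equation) because toxin is released by lysing producer cells; a
production term independent of producer density would have no mechanistic
carrier.

Assumptions worth keeping in mind:

* **No self-induction.** A strain's own toxin neither kills nor induces it
  (immunity gene; the SOS trigger is the damage inflicted by the
  *competitor's* toxin).
* **Time and concentration units are abstract.** No physical rates are
  published for this system; all defaults are dimensionless and chosen so
  that growth is O(1).
* **Lysis cost.** Colicin release kills the producing cell, so production
  should carry a mortality cost. The paper trail for whether the original
  equations charge it is ambiguous; we expose it as `epsilon` (producer
  death proportional to the per-capita production rate) with **default 0**
  (pure-benefit induction). All shipped scenario presets and tests use
  `epsilon = 0`; with `epsilon > 0` strong self-inducibility becomes a
  liability, which reverses some of the monotonicities documented below.

## Parameter conventions: the gamma/l ambiguity

The per-strain symbols `gamma_i` ("toxicity") and `l_i` ("induction rate")
are used in the literature under two incompatible readings: *toxin-attributed*
(`gamma_A` = how lethal toxin A is to strain B) and *strain-attributed*
(`gamma_A` = how sensitive strain A is to toxin B; `l_A` = how strongly
strain A's production responds to toxin B). The core model therefore uses
unambiguous per-ordered-pair fields (`kill_AonB`, `induce_BonA`, ...), and
`make_params` maps `gamma_i`/`l_i` onto them under an explicit `semantics`
flag. The default is `strain_attributed`. Both mappings are tested; neither
is guessed silently.

## Well-mixed dynamics

* **Integrator**: SciPy's explicit adaptive RK45 with a user-fixed maximum
  step (default 1.0), `rtol = 1e-8`, `atol = 1e-13`. The exact flow
  preserves nonnegativity (every loss term is proportional to the variable
  it depletes), so negative undershoots are pure discretization noise:
  values in `(-1e-12, 0)` are clipped to zero and counted; anything below
  `-1e-12` aborts the run. The tight `atol` keeps genuine undershoots below
  that bound even in stiff strong-induction regimes.
* **Outcome classification**: a strain wins when it ends above the
  persistence threshold (default `1e-2` of carrying capacity) with the
  competitor below the extinction threshold (default `1e-6`). The two
  defaults are separated by four orders of magnitude and results are
  insensitive to either within an order of magnitude. A run whose terminal
  derivative norm exceeds `1e-5` is `undecided`; `run_competition` doubles
  the horizon up to four times before accepting that label. `crash_depth`
  (the minimum of `u_A + u_B` over the run) records the transient community
  collapse characteristic of strong mutual induction.
* **Critical frequency rho_c**: the initial state is
  `u_A = rho*u_total, u_B = (1-rho)*u_total` with no initial toxin (the
  assays start from washed cultures; initial toxin is configurable). A
  5-point coarse scan checks that outcomes pass from B-wins to A-wins once
  (the knife-edge point may classify as coexistence; that is allowed inside
  the transition zone), then bisection shrinks the bracket to `tol`,
  returning the midpoint. Endpoints that do not resolve to opposite winners
  give a `no_crossing` result rather than an exception. Default
  `u_total = 0.1`; no initial total density is published for the
  frequency-scan experiments, so it is configurable everywhere.
* **Phase diagrams** sweep any two named parameters cell-by-cell from the
  same base; cells are independent and order-free by construction.

## Non-degradable-reporter readout

Bench competitions follow one strain through a constitutive GFP label that
survives cell death, so the plate-reader signal approximates *all cells ever
produced*, not the standing density. `cumulative_growth` implements that
readout: initial density plus the time-integral of gross growth
`beta*u*(1 - u_A - u_B)`. It is the right quantity for comparisons with
fluorescence trajectories; the standing density of every winning strain ends
at the same fixed point `1 - delta/beta` regardless of history.

One documented consequence: in the weak-vs-strong regime, adding more of the
strongly inducing challenger to a fixed inoculum of the weak inducer
*increases* the weak inducer's final cumulative signal (each extra unit of
challenger drives extra rounds of killing and regrowth that the label
accumulates). This correspondence holds in the near-matched-potency,
strong-asymmetric-induction regime in which the shipped `weak_vs_strong`
preset lives; if the challenger's potency advantage is made much larger the
community crash deepens but the correspondence inverts. The two behaviors —
a crash below *half* the initial community density, and the monotone
initial-to-final correspondence — are mutually exclusive in this model with
`epsilon = 0`; the preset prioritizes the correspondence and exhibits a
crash to ~54% of the initial total.

## Scenario presets

All presets start from equal frequencies `u_A = u_B = 0.3` (a dense mixed
inoculum; from dilute starts the toxin catastrophe never outruns growth and
no crash is visible) with no initial toxin, and share `beta = 1`,
`delta = 0.1`:

| preset | kill A→B / B→A | induce A→B / B→A | s | d | outcome |
|---|---|---|---|---|---|
| `weak_vs_weak` | 1.0 / 1.3 | 2 / 2 | 0.05 | 1.0 | more potent B wins |
| `strong_vs_strong` | 2.0 / 2.4 | 40 / 40 | 0.05 | 1.0 | deep crash, then B wins |
| `weak_vs_strong` | 5.0 / 6.0 | 1 / 100 | 0.2 | 0.25 | crash, then weak inducer A wins |
| `symmetric` | 1.5 / 1.5 | 10 / 10 | 0.05 | 1.0 | rho_c = 1/2 |

The `weak_vs_strong` pairing uses a leakier, more persistent toxin
background (`s = 0.2`, `d = 0.25`) so that the stand-off phase (A's growth
halted while toxins accumulate) is long enough to resolve numerically.

## Spatial model

Reaction terms are the well-mixed right-hand side applied per lattice site;
bacteria spread with `D_u` (default 0.1) and toxins diffuse with `D_c`
(default 1.0; small molecules diffuse much faster than colonies spread —
the ratio 10 is a declared default, not a measured value). The scheme is
forward-time centered-space with no-flux boundaries (plate walls; periodic
available behind a flag), and refuses to step unless
`dt <= h^2 / (2*ndim*max(D_u, D_c))`, reporting the maximal admissible step.
A fourth-order (`rk4`) time integrator on the same method-of-lines system is
available for checks that need site-level agreement with the ODE solution
(the diffusion-free decoupled-sites limit matches the well-mixed integrator
to better than 1e-10 per site); production runs use the cheaper Euler
stepping, whose first-order time error is immaterial for front positions
and coverage fractions.

Front positions are linearly interpolated zero crossings of `u_A - u_B`
restricted to occupied sites; front velocity is the least-squares slope of
position vs time after discarding an initial transient (default 20%), with
positive velocity directed into strain B's territory. Coverage assigns each
site to the strain with the larger local density above a threshold (default
`1e-2`); ties and sub-threshold sites count as unoccupied.

Droplet initial conditions emulate inoculating a plate with `n` droplets of
pure culture (default 24, radius 3 length units, inoculum 0.5): centers are
uniform within the walls, strains alternate A,B,... in seeded-shuffled
order so each strain receives half of the droplets, and overlaps are
allowed. None of grid size, droplet radius, or inoculum density is published
for the spatial simulations; the defaults here are declared choices at desk
scale (1D N = 400, 2D 128×128 in the shipped analyses).

### Spatial findings and limitations

* The classic front phenomenology is reproduced: territories separated by
  fronts that retreat from the more potent strain at near-constant speed,
  toxin concentrating in the "no man's land" at the front, and a 1D winner
  independent of the initial territory split.
* **Curvature penalty**: a mildly dominant strain (planar front velocity
  +0.014 per time) is locally eliminated when confined to a convex island
  of radius below roughly `D_u / v`; its boundary cells sit in a bath of
  the surrounding competitor's toxin. This is the mechanism by which
  convex territories are disadvantaged in 2D.
* **Per-area fixation in 2D is not slower than 1D in droplet geometry.**
  With matched parameters, a 24-droplet 2D run reaches 90% dominant
  coverage *faster* than the 1D half-split (fragmentation gives the
  dominant strain more total front length per unit area, outweighing the
  curvature penalty). The "structured environments resolve slowly" effect
  is real but is carried by near-matched opponents: with a 2% potency gap,
  droplet-plate coverage drifts by only a few percent absolute over the
  whole horizon in which a clearly uneven (3× potency) 1D contest resolves
  completely. The package's tests assert the latter two verified
  properties, not the matched-geometry timing claim.

## Assay computations

* **Titer**: `1 / min(flagged dilution factor)`; zero-titer sentinel when
  nothing inhibits; a clear zone reappearing after disappearing warns but
  the greatest-dilution rule still applies.
* **Response ratio**: replicates are averaged, then induced/control per
  hour. The published tables report a single value per combination without
  stating how the hourly ratios collapse; we take the **maximum over
  time** (peak induction, robust to onset lag) and expose the per-hour
  vector.
* **Induction calls**: ratio > 2 (the conventional threshold). Counts
  exclude the toxin-free control column and the promoterless reporter row.
  Raising the threshold can only remove calls.
* **Potency–induction correlation**: Pearson r between log10 titer and
  log10 mean response across genuine reporter rows (titers span orders of
  magnitude; the log scale is the field's convention, and the result is
  invariant to rescaling either axis). The published titers behind the
  measured correlation of 0.84 are not tabulated anywhere, so the
  correlation is exercised through synthetic round trips; the reference
  panel contributes only fixture means (e.g. the ColE7 column mean of
  107.0).

## Synthetic generators

The generators emulate the *structure* of the bench data, not its
biophysics — what passing tests show is that the analysis pipeline is
correct and calibrated, not that real plate-reader data will be this clean.

* **Reporter time series**: 6 hourly points over 0–5 h; the non-induced
  control follows a logistic luminescence rise (10 → 1000 RLU, midpoint
  2.5 h); the induced wells multiply the control by a fold factor ramping
  linearly to its programmed value by hour 2; multiplicative log-normal
  noise (default sigma 0.05) per well and hour. Noiseless mode makes the
  peak response ratio exactly the programmed fold. Real data add growth
  differences between wells, autoluminescence and detector saturation.
* **Dilution series**: 28 two-fold steps (the screening design); flags set
  exactly while concentration ≥ 1/titer; optional flag flips confined to
  the boundary step (scoring faint clear zones is only ambiguous there).
  Titers beyond `2^27` are censored with a warning.
* **Assay panel**: log10 titers uniform over 5 decades; each colicin's
  log10 response is `0.4 * log10(titer) + 0.15` plus a per-colicin
  deviation (sd 0.36 log10 units) and small per-cell scatter (sd 0.05);
  a control column and promoterless row near ratio 1 complete the table.
  The slope and intercept place responses between ~1.4 and ~140, matching
  the published response range. The per-colicin deviation was calibrated by
  Monte-Carlo (500 seeds) so the recovered mean Pearson r is 0.84, the
  published potency–induction correlation strength; the calibrated value
  is frozen in `CALIBRATED_COUPLING_NOISE`.
* **Determinism**: every generator draws from `numpy.random.default_rng`
  seeded from its spec; identical spec + seed reproduces identical output.

## Problem sizes in the shipped analyses

The test suite and the acceptance script run the well-mixed analyses at
horizon 100–200 (with doubling), the rho_c grid at 6×6 cells with bisection
tolerance 1/64, the 1D front analyses at N = 400, the droplet-plate analysis
at 128×128 with 24 droplets, and the statistical round trips at 200–500
seeds. These sizes resolve every documented effect with comfortable margins
(e.g. front-fit residual three orders of magnitude below the displacement)
while keeping a full run at desk scale.

## Known limitations

* Two strains only; no evolution of parameters; no demographic noise.
* The reconstruction fixes one of several defensible c-equation forms
  (production strictly proportional to producer density).
* Abstract units: quantitative comparison with wall-clock experiments
  requires calibrating beta, delta and d against growth and decay data that
  are not available here.
* The spatial scheme is first-order in time by default; front *positions*
  converge under grid refinement (fitted velocity changes by a few percent
  when the resolution doubles) but sharp-interface quantities at coarse h
  carry O(h) wobble.
* The published fluorescence competition curves are emulated only
  qualitatively (halt-then-resume, crash-then-recover shapes); no attempt
  is made to reproduce instrument units.
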