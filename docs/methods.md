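# Methods

This note records the model equations as implemented, the parameter
defaults and their units, the synthetic forcing generator and what it does
and does not emulate, the numerical scheme, and the design choices made
where the formulation was genuinely open. Nothing here states an empirical
result that the test-suite or `scripts/acceptance.py` does not itself
compute.

## Model structure

One fully expanded leaf is simulated over a 15-h photoperiod (06:00–21:00
by default). The dynamic state is (W_m, N_m, g_sw, T_l): mesophyll water
content (mol H₂O m⁻²), mesophyll solute amount (mol m⁻²), stomatal
conductance to water vapour (mol m⁻² s⁻¹), and leaf temperature (K). All
photosynthetic and hydraulic parameters are held constant over the day (no
temperature response of V_cmax, J_max, K_m, Γ*; no Rubisco
activation kinetics; no leaf ageing; no canopy scaling).

### Stomatal kinetics (`stomata`)

dg_sw/dt = α_g ln((1.6G − r₀)/(g_sw − r₀)) (g_sw − r₀). The law integrates
to a Gompertz curve at constant target, which is what `fit_induction` fits
to measured induction curves by nonlinear least squares
(`scipy.optimize.least_squares`, asymptote as a third free parameter,
initial conductance from the first sample). Both the state and the target
are floored at r₀ + 1e-6 before the logarithm; the floor realises the
initial-lag behaviour r₀ encodes and keeps the law defined when a leaf
starts from darkness. Convergence toward 1.6·G is monotone without
overshoot (sign structure of the law; property-tested).

### Steady-state target (`stomata` + `photosynthesis`)

G = g₀ + (1 + g₁/√δe)(A/C_a) f(ψ_m), with
f(ψ_m) = (1 + exp(s_f ψ_r)) / (1 + exp(s_f(ψ_r − ψ_m))). The printed form
of this target in the underlying formulation is typographically ambiguous;
it is resolved here to the unified (Medlyn-type) optimal form above, which
matches the linear-in-A factorisation the solver relies on. f gates only
the A-coupled slope, not g₀ (residual conductance persists under stress).
δe is floored at 0.01 kPa inside the target to bound the 1/√δe singularity
at vapour saturation — see "Saturated-air regime" below.

### Photosynthesis (`photosynthesis`)

FvCB with mesophyll conductance: A_c = V_cmax(C_c − Γ*)/(C_c + K_m),
A_j = J(C_c − Γ*)/(4C_c + 8Γ*), J the smaller root of the non-rectangular
hyperbola θJ² − (κ₂LL·I + J_max)J + κ₂LL·I·J_max = 0, and
C_c = C_a − A(G + g_m)/(G·g_m). Γ* is treated as a mole fraction
(μmol mol⁻¹), the only unit reading under which the drawdown chain is
consistent. Substituting G = g₀ + gscb·A turns each branch into a cubic in
A whose coefficients are formed explicitly; with gscb = 0 the system
degenerates to the standard conductance-limited quadratic, handled in
closed form. Among the real roots, the admissible one satisfies A ≥ 0,
C_c ∈ (0, C_a], G ≥ g₀; if several qualify the smallest is returned, and if
none does a solver error carrying all roots is raised rather than a silent
pick. This selection coincides with an independent bracketed fixed-point
solve on every random draw tested (200-draw acceptance check, |ΔA| < 1e-6).
A = min(A_c, A_j). Day respiration R_d is parsed but not subtracted by
default (`subtract_rd` flag; when set, R_d is subtracted from the reported
minimum — a post-hoc net adjustment, not re-entering the cubic closure).

The assimilation realised at the *current* stomatal conductance uses the
total drawdown resistance r_t = 1/g_sc + 1/g_m, reducing each branch to a
quadratic in A (smaller root). The two routes agree when the current
conductance equals the steady-state target (tested).

### Energy balance and transpiration (`microclimate`)

Molar unit system throughout: ρ_a = 28.9645 g mol⁻¹ (molar mass of air),
c_p = 1.012 J g⁻¹ K⁻¹, so ρ_a c_p ≈ 29.3 J mol⁻¹ K⁻¹; λ = 44172 J mol⁻¹;
conductances in mol m⁻² s⁻¹. δe = (1 − h_r/100)·a₁ exp(a₂T_c/(a₃ + T_c)).
Leaf temperature is the closed form of R_n − G_i = H + λE with
H = ρ_a c_p (T_l − T_a) g_aH, g_aH = g_bw/1.15, and the latent term
linearised with slope s; transpiration is
E = g_tw ρ_a c_p (δe + s(T_l − T_a))/(λγ) with
g_tw = g_bw g_sw/(g_sw + g_bw). The closed form matches a bisection root of
the raw balance to < 1e-9 K (1000-draw acceptance check), and E ≥ 0
whenever R_n ≥ 0 and δe ≥ 0 (analytic identity, property-tested).

Two open choices are exposed as flags recorded in run metadata:

- `slope_mode` (default `literal`): the saturation-slope expression is
  proportional to the *deficit* δe, hence to (1 − h_r/100); the
  thermodynamically standard alternative (`saturation`) substitutes the
  saturation pressure. The literal mode makes s → 0 in saturated air, which
  zeroes transpiration regardless of radiative load.
- `k_rad` (default 0.4376 J μmol⁻¹): net radiation is not part of the
  forcing files, so R_n = k_rad·PPFD; the default converts PPFD to PAR
  energy (4.57 μmol J⁻¹) doubled to approximate total absorbed shortwave.

### Leaf water balance (`hydraulics`)

dW_m/dt = F_i − F_o with F_i = k_x(ψ_x − ψ_m), ψ_x = −0.08 MPa constant;
dN_m/dt = c_i N_xy F_i. ψ_m = ψ_s + ψ_p with
ψ_s = −cv_f2 R T_l N_m/W_m and ψ_p = α exp(−β(1 − W_m/W_max)). The
hydraulic conductance combines a light response a + b·min(PPFD/PPFD_lim, 1)
with an endogenous oscillation τ_C cos(−π t/60 + 5π/2)(ψ_x − ψ_m,r),
converted g→mol by cv_f1 and floored at 0 (the oscillation can drive the
sum negative at low light, which is unphysical). The oscillation's time
argument is `osc_time_unit` (default `minutes`, giving a 120-min cycle;
`hours` is the alternative reading — both are exercised in tests). The
parameter c_e (Na⁺ exclusion) is parsed for completeness but enters no
equation; c_i = 2 is the loading factor used.

Note an internal inconsistency of the source calibration: the nominal
initial potentials (ψ_s = −1.28, ψ_p = 1.2 MPa) do not follow from the
initial state (W_m = 16 = W_max, N_m = 0.121), which gives (−1.031, +2.4).
The simulator initialises from (W_m, N_m) and derives the potentials, so
the first hour contains a relaxation transient from ψ_m ≈ +1.37 MPa toward
hydraulic equilibrium.

## Parameter defaults

Grouped dataclasses in `leafwue.params`; every run's metadata embeds the
resolved set and its hash. Key defaults (cucumber calibration):

| group | parameter | default | units |
|---|---|---|---|
| stomata | g₀, g₁ | 0.009, 3.51 | mol m⁻² s⁻¹, – |
| stomata | α_g, r₀ | 4.0516e-3, 2.674e-3 | s⁻¹, mol m⁻² s⁻¹ |
| stomata | s_f, ψ_r | 4.9, −0.9 | MPa⁻¹, MPa |
| photosynthesis | V_cmax, J_max, θ, κ₂LL | 102, 140, 0.75, 0.425 | μmol-based |
| photosynthesis | Γ*, K_m, g_m, C_a, R_d | 43.02, 711, 0.3, 380, 1.08 | μmol mol⁻¹ ×2, mol m⁻² s⁻¹, μmol mol⁻¹, μmol m⁻² s⁻¹ |
| aerodynamics | g_bw, γ, λ | 2.7, 0.0665, 44172 | mol m⁻² s⁻¹, kPa K⁻¹, J mol⁻¹ |
| hydraulics | a, b, PPFD_lim, τ_C | 0.0259, 0.2268, 1000, 0.0216 | g m⁻² s⁻¹ MPa⁻¹(²) |
| hydraulics | α, β, W_max, ψ_x, ψ_m,r | 2.4, 10.6, 16, −0.08, −0.9 | MPa, –, mol m⁻², MPa |

Initial state: W_m = 16, N_m = 0.121, g_sw = 0.02, T_l = 295.15.

## Synthetic forcing: the ideal day

`make_ideal_day` emulates a greenhouse day with rhythmic cloud-driven
fluctuations: I(t) = I_m + I_a cos(π(t − t₀)/p − π) over a 15-h
photoperiod, starting at the minimum; temperature has the same shape
(mean T_m, amplitude T_amp) lagged 30 min; relative humidity follows the
fitted hyperbola h_r = 1173.613/(T_c − 6.3458), clamped at 100 %
(exceeded below 18.08 °C). The default half-cycle parameter p = 3600 s (a
2-h fluctuation cycle) divides the photoperiod into whole half-cycles, so
the photoperiod-mean light is exactly I_m — the matched-integral property
that makes scenarios with different fluctuation periods carry the same
daily light integral. Scenario presets: sunny I_m/I_a = 237/137.02, cloudy
139/133.435 μmol m⁻² s⁻¹. T_m = 295.15 K and T_amp = 4 K are explicit
scenario choices, shared by both presets (per-day temperature calibrations
were never published), and are reported in every output's metadata.

What the generator does *not* emulate: independent humidity (h_r is a
deterministic function of temperature); weather fronts or trends
(temperature and light share one period and phase, minus the lag);
multi-day carry-over; and any within-canopy light heterogeneity. Passing
tests on these scenarios therefore demonstrate internal consistency and
directional behaviour of the model, not fidelity to any particular
recorded day.

### Saturated-air regime

With T_m = 295.15 K and T_amp = 4 K the scenario minimum (18.0 °C) lies
just below the 18.08 °C saturation point of the humidity hyperbola, so
every temperature trough drives h_r to the 100 % clamp and δe to ~0. Two
consequences follow from the model equations: the stomatal target grows
toward its δe-floor bound (G ≈ 0.67 mol m⁻² s⁻¹ at δe = 0.01 kPa), and
transpiration vanishes (in the literal slope mode s ∝ δe, so even the
radiative term of E disappears). The leaf then assimilates at nearly zero
water cost during every trough — a recurring "free-carbon" window. This
regime dominates several whole-day outcomes on the default scenarios, all
computed by the acceptance tests:

- daily WUE is *higher* on the ideal sunny day than the ideal cloudy day
  (8.46 vs 7.87 mmol mol⁻¹ at dt = 1 s): with identical temperature/VPD
  courses, the sunnier day exploits the free-carbon troughs harder and
  dilutes the g₀ leak more;
- daily WUE is markedly sensitive to stomatal speed (≈17 % spread across
  the α_g scan), because exploiting the short troughs requires fast
  opening; away from the saturated regime (T_m ≥ 297 K) the spread
  collapses below 1 %, while the *instantaneous* WUE difference between
  slow and fast stomata during transients exceeds 100 % in either regime;
- the WUE gain from mesophyll conductance beyond 0.8 mol m⁻² s⁻¹ is about
  a third of the 0.3→0.8 gain (not under a fifth), though in absolute
  terms it is only ~0.4 % of daily WUE.

These are properties of the chosen scenario family interacting with the
humidity hyperbola, and are documented rather than tuned away: T_m, T_amp,
the δe floor and the slope mode are all explicit configuration with their
defaults stated above.

Directional results that hold on the default scenarios (also computed by
the acceptance suite): daily WUE decreases strictly along the g₁ scan
(−40 % to +90 %); it is non-decreasing in g_m; and it has an interior
maximum over the fluctuation-period scan, at p = 1800 s (a 60-min cycle)
on the default grid.

## Numerical scheme

Fixed time step, dt = 1 s reference. Per step: (1) δe and s from the
linearly interpolated forcing; (2) ψ components from (W_m, N_m) with T_l
lagged one step (avoiding an implicit loop; the lag error is below the
dt-halving sensitivity); (3) steady-state target (A, G) via the cubic
system; (4) explicit-Euler update of g_sw; (5) instantaneous A at
g_sw/1.6; (6) g_tw, T_l, E; (7) k_x and F_i; (8) update of (W_m, N_m).

Step (8) uses the trapezoidal rule closed by a short fixed-point iteration
over the step (the water-potential feedback on the fluxes is weak;
convergence to 1e-13 typically takes 2–3 sweeps). This makes the recorded
state increments exactly consistent with trapezoidal integrals of the
recorded fluxes: water and solute closure hold to ~1e-16 relative, rather
than the ~1e-5 first-order bias a rectangle-rule update would leave.
Stomatal conductance stays explicit Euler (its closure is not an invariant
of interest and dt·α_g ≪ 1). Halving dt from 1 s moves the W_m trajectory
by < 1e-5 of full scale; the sensitivity scans run at dt = 5 s under a
guard asserting that halving to 2.5 s moves daily WUE by < 0.5 %.

Cubic roots are computed by the depressed-cubic (Cardano/trigonometric)
formulas with a two-step Newton polish, cross-checked against the
companion-matrix route to 4e-15 in the tests. W_m is clipped to
(0, W_max] with a counter (`wm_clip`) recorded in metadata; clamp events
in the stomatal law are counted likewise. Daily WUE uses trapezoidal
integrals over the 06:00–20:00 window (the simulation runs to 21:00; both
bounds are configuration); a zero transpiration integral raises an
explicit undefined-WUE error, never NaN.

Determinism: identical configuration and forcing give bit-identical
traces; the only randomness in the package is the noise injected by the
fixture generator and the acceptance script, both seeded.

## Known limitations

- Single leaf, single day, constant photosynthetic parameters; no TPU
  limitation branch; no longwave radiation budget or boundary-layer
  stability corrections.
- The humidity–temperature hyperbola is a greenhouse fit; outdoor data
  need their own h_r column in the climate CSV.
- The saturated-air regime described above makes whole-day sensitivity
  magnitudes on the default scenarios scenario-dependent; conclusions
  about stomatal-speed effects in particular should be drawn from the
  instantaneous (transient) comparisons or from scenarios away from the
  saturation clamp.
- The admissible-root selection is validated against the fixed-point
  oracle over physiological parameter ranges (see `tests/oracles.py`);
  far outside those ranges the solver raises rather than guesses.
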