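# Methods

`rumensim` simulates rumen fermentation under methanogenic inhibition
with four dynamic mechanistic models sharing one fermentation core.
This note describes the science the code implements, the choices made
where the design was open, and what the tests do and do not establish.

## 1. The fermentation core

State pools (per whole rumen): degradable fiber, starch, soluble sugars
and protein [g]; hexose [mol]; fermentative microbes and methanogens
[g]; acetate, propionate, butyrate [mol]; dissolved and headspace H₂
[mol]; reduced NAD [mol].  Concentrations are `C_i = Q_i / V_Fl` with
`V_Fl` the rumen fluid volume.  The core is a *reconstruction*: the
inhibition extensions were designed against an extant fermentation model
whose equations are not part of this package, so the core reproduces the
causal structure that the extensions rely on — rising p_H₂ throttles
NADH reoxidation, the NAD⁺/NADH ratio steers the VFA pathway split, and
methanogenesis saturates in dissolved H₂ — with its own, documented
constants.

**Hydrolysis.**  First order in each carbohydrate pool; fiber and starch
rates are diet properties, soluble sugars hydrolyze at a fast common
rate.  Mass is converted to hexose at 162 g/mol (anhydro-glucose in
polymers) or 180 g/mol (free sugars).  Degradable protein is carried as
an inert mass stream (hydrolysis and passage only); preformed feed acids
enter the corresponding VFA pools directly at intake, lactate into
propionate.

**Hexose fermentation.**  Uptake is Michaelis–Menten in the hexose
concentration and proportional to microbial biomass.  A fraction
`f_anab` of the uptake is anabolized to biomass (162 g per mol); the
catabolized remainder is split over three pathways, per mol hexose:

| pathway | products            | H₂  | net NADH |
|---------|---------------------|-----|----------|
| A       | 2 Ac⁻               | +2  | +2       |
| AP      | ⅔ Ac⁻ + 4⁄3 Pr⁻    | 0   | −⅔       |
| B       | 1 Bu⁻               | +2  | 0        |

With `g = r/(K_r + r)` and `r` the NAD⁺/NADH ratio, the butyrate share
is `f_B = f_bu_min + f_bu_amp·(1 − g)` and the rest is split `g : 1−g`
between A and AP.  Pathway A needs NAD⁺ as electron acceptor and is
promoted at high `r`; AP reoxidizes NADH and is promoted when NADH
accumulates; butyrate acts as an additional electron sink at low `r`.
This allocation has a built-in safety: if thermodynamics block the
hydrogenase entirely, NADH production and consumption balance at
`r = K_r/3`, strictly inside the pool bounds.

**Redox control.**  NADH is reoxidized to H₂ by a hydrogenase flux
`k_hyd·Q_NADH·F_T` with the thermodynamic potential factor

    ΔG = ΔG⁰ + RT·ln(p_H₂ / r),   F_T = max(0, 1 − exp(ΔG/(χ·R·T))).

`F_T = 1` far from equilibrium, `F_T = 0` at or beyond it (complete
thermodynamic inhibition).  F_T is non-increasing in p_H₂ and
non-decreasing in `r`.  NAD⁺ is defined as `nad_pool·Q_Mi − Q_NADH`, so
NAD conservation is exact by construction; NADH leaves with microbial
passage/decay in proportion to its content.

**Methanogenesis.**  `U = v·Q_Me/(1 + M/C_H₂)` mol H₂/h; CH₄ emission is
`U/4`.  Methanogens grow in proportion to this flux (yield `y_me`) —
H₂ is not incorporated, but its conversion powers growth — and leave
with the solid-associated passage stream `0.4·(k_Fl,Ex + k_So,Ex)`,
which the nitrite pool formed inside archaea also follows.

**Gas exchange.**  The fluid exchanges H₂ with a dynamic headspace pool
through a two-film flux `k_h2_em·(Q_H₂ − henry·p_head·V_Fl)`; the
headspace is washed out (eructation) at `k_vent`, and that washout is
the measured emission rate.  The thermodynamic control reads the
headspace partial pressure (`p = Q_H₂g·R·T/V_head`), which low-pass
filters the very fast dissolved pool with the ~0.2 h vent time constant;
an instant-Henry's-law mode (`gas_mode="equilibrium"`) is available.
This choice is as much numerical as physical: with F_T sensing the
dissolved pool directly, the NADH–H₂ couple forms a weakly damped fast
oscillator that forces the stiff solver to ~10⁻⁵ h steps; the headspace
filter removes it without changing any equilibrium.

## 2. The inhibition extensions

* **3-NOP**: intake `D_DM(t)·c_3NOP`; absorption (0.30 h⁻¹) and fluid
  passage; inhibition term `C_3NOP/J_MCR` added to the Michaelis–Menten
  denominator.
* **3-NOP+nitrite**: additionally `k·Q_Me·Q_3NOP` conversions to
  intracellular nitrate (a terminal bookkeeping pool: no further
  reactions, no transport) and nitrite (inhibits through the same
  `J_MCR` term, aggregated `C_3NOP + C_NO₂`; leaves only with the
  methanogen passage stream).
* **nitrate**: intake, absorption (0.30 h⁻¹), fluid passage, and
  reduction to NH₃ `k·Q_Mi·Q_NO₃·Q_H₂` consuming 4 H₂ per NO₃⁻.
* **nitrate+nitrite**: the reduction splits into NO₃⁻→NO₂⁻ (1 H₂) and
  NO₂⁻→NH₃ (3 H₂); nitrite is also absorbed and passed, and inhibits
  methanogenesis through `C_NO₂/J_NO₂`.

Reduction products (NH₃) leave the model; there is no nitrogen economy
beyond the supplement moiety itself.  Two printed-sign choices are
implemented deliberately: both pathway H₂ productions enter dQ_H₂/dt
with positive sign in every variant (butyrate formation produces H₂),
and the H₂-to-methanogen flux referenced by the H₂ balances is the
single methanogenesis flux defined above.

## 3. Parameters

Supplement-specific constants (defaults from the packaged table
`data/inhibitor_params.csv`; units as shipped): absorption rates
`k_3nop_ab = k_nox_ab = 0.30 h⁻¹`; reductions `k_no3_nh3 = 6.99`,
`k_no3_no2 = 1.5`, `k_no2_nh3 = 0.113` mol⁻¹g⁻¹h⁻¹; archaeal 3-NOP
conversions `k_3nop_no3 = 1.55`, `k_3nop_no2 = 0.44` g⁻¹h⁻¹; inhibition
constants `J_MCR = 1.93·10⁻⁵ M` (3-NOP) or `2.10·10⁻⁵ M`
(3-NOP+nitrite) and `J_NO₂ = 1.17·10⁻³ M`.

Core constants are reconstruction choices for a lactating dairy cow
(90 L rumen fluid, 312 K, twice-daily feeding of 20 kg DM/d).  The ones
that matter most, with the reasoning behind their defaults:

* `k_fl_ex = 0.10`, `k_so_ex = 0.035 h⁻¹` — standard fluid/solid
  passage; they also fix the methanogen-associated passage 0.054 h⁻¹.
* `v_h2_ch4 = 5 mol g⁻¹h⁻¹`, `m_h2_ch4 = 2·10⁻⁶ M`, `y_me = 0.054
  g mol⁻¹` — chosen jointly so that (i) the methanogen pool's growth
  margin `y·v/k_pass = 5` leaves a wide, strongly stabilizing C_H₂
  feedback (the pool settles well within the 240-h protocol even under
  chronic inhibition), (ii) baseline dissolved H₂ sits at
  `C* = M/(y·v/k − 1) = 5·10⁻⁷ M`, and (iii) methanogenesis outcompetes
  the nitrate reduction for H₂ at the scenario doses (slope ratio
  `v·Q_Me/M` vs `4·k·Q_Mi·Q_NO₃`), which is what makes the
  nitrate-simple model *lower* p_H₂ rather than raise it.
* `f_anab = 0.20` — microbial biomass ≈ 800 g, placing `Q_Mi·Q_H₂` where
  the printed mass-action constants act at their intended strength: the
  NO₂⁻→NH₃ route carries a meaningful share of nitrite disposal, which
  is exactly what makes `k_no2_nh3` identifiable from diurnal emission
  data.
* `nad_pool = 5·10⁻⁴ mol g⁻¹`, `k_hyd = 300 h⁻¹` — an *effective*
  redox-carrier pool.  Only the product `k_hyd·nad_pool` enters any
  steady state; the split is chosen to slow the (physically
  sub-second) NADH relaxation to a solver-friendly ~10 s without moving
  equilibria.  The pool is larger than literal NAD(H) contents; read it
  as all soluble electron carriers lumped together.
* `ft_chi = 1`, `ΔG⁰ = +18.1 kJ/mol` (NADH → NAD⁺ + H₂ from standard
  redox potentials), `K_r = 16`, `f_bu_min/amp = 0.10/0.15` — together
  these put the control regime at F_T ≈ 0.95 and Ac/Pr/Bu ≈ 68/24/8 with
  diurnal F_T dips toward 0 after feeding.
* Gas handling: `henry = 7.8·10⁻⁴ M atm⁻¹`, `k_h2_em = 500 h⁻¹` (fast
  two-film transfer), `k_vent = 5 h⁻¹`, `V_head = 20 L`,
  `k_h2_ab = 0.10 h⁻¹`.

With these defaults the control run yields ≈ 25 mol CH₄/d (≈ 400 g/d)
and ≈ 0.06–0.17 mol H₂/d on the packaged diets — typical magnitudes for
a lactating cow — and every directional response to supplementation
(CH₄ ↓ in all four models; H₂ emission and p_H₂ ↑ except in the
nitrate-simple model; acetate ↓ / propionate ↑ / butyrate ↑ where the
thermodynamic control engages) emerges monotonically across the scenario
dose grids (0/0.5/1.0 mmol·kg⁻¹ 3-NOP; 0/0.16/0.32 mol·kg⁻¹ nitrate).

## 4. Simulation protocol and numerics

Runs integrate 240 h of a 12-h feeding cycle (rectangular meals, two of
0.5 of daily intake over 1 h at 0 h and 12 h by default; arbitrary meal
patterns and 24-hourly-fraction profiles are supported) and report the
final 24 h.  Initial conditions are the quasi-steady pools of a 360-h
control spin-up from a fixed cold start; spin-ups are cached per (base
parameters, diet, feeding pattern) since the control regime does not
involve the inhibition constants.  Control runs repeat to <0.1% per pool
between 216 h and 240 h; dosed runs to <2% (the methanogen pool adapts
to chronic inhibition through a slow feedback loop and can still drift
~1%/day in the strongest 3-NOP+nitrite scenario).

The solver is LSODA (stiff/non-stiff switching) applied piecewise
between meal discontinuities, `rtol = 10⁻⁷`, `atol = 10⁻¹²` by default.
Output grids: a dense reporting grid (2.5·10⁻³ h steps in the first
0.5 h of each 12-h cycle, 10⁻² h elsewhere), a uniform 0.05-h grid, a
"final-day" grid (dense only over the reporting window) and arbitrary
time arrays — these control output sampling only; the integrator remains
adaptive.  Two numerical regularizations apply inside the ODE path only:
the F_T clamp at zero is smoothed quadratically (half-width 0.03) so
trajectories riding the hydrogenase equilibrium manifold do not chatter,
and rate laws read pools clipped at zero.  Pools more negative than
`max(10⁻¹⁰, 100·atol)` abort the run as a solver failure; smaller
excursions are roundoff and are clipped.  Halving both tolerances moves
daily CH₄ by well under 0.01%.  A numba-compiled kernel evaluates the
right-hand side; a pure-Python implementation assembled from the public
flux operations is the reference against which the kernel is tested to
10⁻¹² and is also used to name the offending flux when a state goes
non-finite.

Cumulative-flux *audit states* (H₂ production and every H₂ sink; the
supplement influx and every disposal route) are integrated alongside the
physical pools.  Because each audit derivative is a linear combination
of terms of dQ/dt, conservation identities (H₂ bookkeeping, supplement
moiety closure) hold to solver precision rather than quadrature
precision, and the nitrate fate budget is exact with respect to the
integrator.  Fate-budget route fractions are normalized over total
disposal, so they sum to one exactly; total disposal equals the daily
influx up to the periodicity residual, which is reported as
`closure_residual`.

## 5. Calibration

Observations are daily-mean CH₄ emissions per treatment and/or hourly
diurnal CH₄/H₂ emission series over the quasi-steady day, each paired
with a zero-dose control observation.  Before fitting, treatment
observations are multiplied by (predicted control)/(observed control)
per study and variable — the control run is then residual-free by
construction and the fit targets the supplement *response*.  Control
predictions do not involve the inhibition constants, so this scaling is
fixed during optimization.  The objective is the unweighted sum of
squared residuals; diurnal series are compared at hourly points.
Optimization is BFGS on log-parameters (positivity for free), with an
explicit finite-difference step of 10⁻³ on the log scale — small enough
for curvature, large enough that objective differences dominate the ODE
solver's noise floor — and a three-start strategy (×1, ×3, ×⅓ around
the initial guess) against local minima.  Solver failures inside the
objective return a large penalty instead of raising.

Free parameters follow the original estimation design: `j_mcr` (and
`k_no3_nh3`) against daily CH₄ means; `k_no2_nh3` and `j_no2` against
diurnal series; the weakly identifiable conversion constants
`k_3nop_no3`, `k_3nop_no2`, `k_no3_no2` are excluded from fitting by
default.

## 6. Synthetic observations

The in-vivo emission records behind the original estimates are not
redistributable, so `generate_observations` emulates them: it runs the
model at the study conditions (packaged diets, scenario doses, 20 kg
DM/d, 240 h), extracts daily means and/or hourly diurnal series from the
final 24 h, and applies multiplicative Gaussian noise at a configurable
coefficient of variation (5% by default — the scale of day-to-day
variation in respiration-chamber emission data), with the paired control
observation generated the same way.  What this emulates: measurement and
animal-day noise around a smooth diurnal signal.  What it does not:
between-animal variation, diet-history effects, drift within the
measurement period, digitization error of graph-extracted series, or any
model-structure mismatch — the synthetic truth is the model itself.
Passing recovery tests therefore demonstrate that the estimation
machinery works and that the parameters are identifiable from data of
this shape and noise level, not that the printed parameter values are
correct for real animals.

Recovery experiments mirror the original study sets: `j_mcr` from daily
CH₄ across the five 3-NOP study diets at two inclusion rates, and
(`k_no2_nh3`, `j_no2`) jointly from diurnal CH₄+H₂ series across the
three nitrate study diets at the top dose.

## 7. Global sensitivity analysis

The inhibition-related constants of the two nitrite-bearing variants
(`j_mcr`, `k_3nop_no3`, `k_3nop_no2`, `k_3nop_ab`; `j_no2`,
`k_no3_no2`, `k_no2_nh3`, `k_nox_ab`) are drawn jointly from 0.75–1.25
times their reference values by Latin hypercube sampling (each column
stratified, seeded).  Each sample is one 240-h run at the highest
inclusion rate on the evaluation diet; the CH₄ emission rate is read at
0, 0.5, 1, 2, 4, 6 and 10 h from the last meal, and Pearson (optionally
Spearman) correlations between sampled values and the rate are reported
per parameter and time.  The full design uses 1,000 samples; the package
default of 200 reproduces the sign structure and approximate magnitudes
in a few minutes on one core (GSA runs use `rtol = 10⁻⁵`, far below the
parameter-induced output variation).  Raw rates are correlated, without
transformation.

In this reconstruction the inhibition constants correlate positively
with the CH₄ rate through the post-feeding window (weaker inhibition or
faster nitrite removal → more CH₄), and the NO₃⁻→NO₂⁻ rate negatively
through 0.5–4 h.  One caveat is documented rather than hidden: because
nitrite's ruminal half-life is short (absorption + passage ≈ 0.4 h⁻¹), a
faster NO₃⁻→NO₂⁻ conversion compresses the whole inhibition episode, and
by 6 h from the meal the higher-rate runs have already rebounded — the
correlation there is slightly *positive* (a ~1% timing effect), not
uniformly non-positive.

## 8. Known limitations

* The fermentation core is a reconstruction; quantitative trajectories
  (pool sizes, peak concentrations, absolute emission levels) are not
  comparable to any specific published simulation, only the causal and
  directional structure is.
* No pH dynamics, protozoal kinetics, lactate pool, ammonia economy,
  reductive acetogenesis or formate; nitrous-oxide/NO chemistry of
  nitrite disproportionation is out of scope.
* The nitrate fate budget routes less of the dose to complete reduction
  (~7–20% at the top dose) than the behavior the inhibition constants
  were originally tuned to, a consequence of the reconstruction's
  biomass/H₂ scale; the H₂-sink utilization arithmetic itself is exact.
* Degradable-protein contents are not part of the packaged diet table
  (only the hydrolysis rate is printed), so the inert protein stream is
  inactive for the nine shipped diets.
* Under strong inhibition the model can transiently predict headspace
  H₂ partial pressures approaching the physical ceiling of 1 atm; gas
  composition is not modeled.
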