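# Methods

## Scope and structure

`rcdsim` models cholesterol (Ch) fluxes in the human outer retina as three
loosely coupled steady-state modules — rod outer segment (ROS) turnover,
lipoprotein delivery from the choriocapillaris (CC), and basal efflux with
drusen growth/clearance in Bruch's membrane (BrM) — plus a
hindered-diffusion calculator for the fenestral pore pathway. The modules
share a canonical unit system (mass pg, length mm, time min; areal fluxes
pg/mm²/min) and a parameter registry. Apart from the link between the
turnover flux and the drusen growth rate, the modules do not interact: each
is analysed at steady state and the fluxes are compared. Only drusen growth
and regression are treated as time-dependent.

Calendar conventions: 1 year = 365 days = 525,600 min; 1 month = 1/12 year
= 43,800 min. These matter because growth rates are reported in µm/year and
clearance benchmarks in months.

## ROS transit chain

Discs enter compartment 1 of an `n = 10` chain with a total Ch formation
flux `j0` and advance with first-order rate `k_t = 0.85/day`
(= 85 discs/day ÷ 100 discs per compartment). Ch is removed from discs in
transit compartments 2..n only, with rate `k_out`; compartment 1 defines
the composition of newly formed discs. The steady state is geometric with
step ratio `k_t/(k_t+k_out)`, so an `F`-fold drop over the chain fixes
`k_out = k_t·(F^(1/(n−1)) − 1)`.

Two `k_out` conventions are exposed: `"table"` uses the rounded 0.19/day;
`"calibrated"` (the default) solves the 6-fold drop exactly, giving
0.18724/day. The calibrated mode is the default because it makes the two
turnover anchors mutually consistent (`Kin_Ch(f=1) = j0/6` exactly) and
puts the terminal disc Ch/PL ratio at 0.3/6 = 0.05; the table mode
reproduces the same quantities to within ~2.5%.

Removed Ch enters a recyclable pool that returns a fraction
`f_recycling = k2/(k1+k2)` to disc formation and passes the rest to the
RPE. Only the ratio `f` is identifiable at steady state — the individual
pool rate constants, and hence the pool size and residence time, are not —
so the pool is modelled as an instantaneous flux split with no state. The
chain ODEs (`scipy.integrate.solve_ivp`, BDF, rtol 1e-10) are provided to
verify convergence to the closed form and to produce time courses of the
compartments themselves; time courses *of the pool* would require an
arbitrary pool rate constant and are deliberately not offered.

`j0 = 5.84 pg/mm²/min` is a primitive anchor (the no-recycling turnover
flux) rather than being rebuilt from disc Ch content × rod density; the
registry records its provenance. External turnover is
`Kin_Ch = j0·(1 − f·(1 − r))` with `r` the fraction surviving to
phagocytosis — affine and decreasing in `f`, spanning 5.84 → 0.97.

## CC → BrM → RPE delivery

Concentrations are LDL cholesterol in mg/dl. Transcytosis is an effective
permeability: a flux coefficient `a = 6·10⁶·P` pg/mm²/min per mg/dl
converts `P` (cm/s) through the exact unit identities
(1 cm/s = 600 mm/min, 1 mg/dl = 10⁴ pg/mm³). The BrM free-LDL pool is
well mixed, with no binding or degradation; its balance

    a·C_CC = b·C_BrM + Vmax·C_BrM/(Km + C_BrM),  b = pout_ratio·a

is a quadratic in `C_BrM` solved in the cancellation-free closed form (the
naive root loses ~10 digits when `b·C ≪ Vmax`). With `pout_ratio = 0`, a
steady state exists only while `a·C_CC < Vmax`; beyond that the pool grows
without bound and the solver raises.

Defaults: `P_in = 1.2×10⁻⁷ cm/s`, `Vmax = 13.1 pg/mm²/min` (already the
LDLR-downregulated capacity; no receptor dynamics are modelled),
`Km = 5.4 mg/dl`, back-flux ratio scenarios 0.1/0.5/1. The 90%-saturation
threshold follows from `C_BrM = 9·Km`:
`C90 = (b·9Km + 0.9·Vmax)/a` → 21.2, 40.7 and 65.0 mg/dl. The commonly
quoted approximations are ~24/43/67 mg/dl, 3–12% above the dimensional
closed form; the closed form is authoritative here, and all thresholds stay
below the ~100 mg/dl of normal serum — the qualitative conclusion (uptake
saturates at sub-physiological LDL) is insensitive to the difference.

Apical ABCA1 delivery into the rod layer is a constant flux
(6.73 pg/mm²/min); its upstream derivation is out of scope and enters as a
registry value with provenance.

## Basal efflux, drusen growth, macrophage clearance

Basal ABCA1 efflux scales the apical flux by the measured apical:basal
expression ratio: 6.73/6.37 ≈ 1.06 pg/mm²/min. ApoB-Ch secretion scales a
liver-equivalent flux by relative ApoB and MTP expression:
967 × 0.075 × 0.04 ≈ 2.90 pg/mm²/min. No competition or switching between
the two pathways is modelled.

The steady-state ApoA-I-Ch concentration in BrM sustained by an efflux
`J` cleared through the CC at `P = 1.2×10⁻⁴ cm/s` is `J/(6·10⁶·P)`:
0.0014–0.0083 mg Ch/dl for `J` = 1–6. The Ch:ApoA-I mass ratio 0.14
converting this to protein concentration is a calibration (consistent with
a two-ApoA-I, ~6.3 nm particle), not a derivation.

Trapped ApoB-Ch flux converts to deposit thickness through a volumetric
deposit Ch density ρ calibrated from the growth relation itself: 1
pg/mm²/min ↔ 0.7 µm/year gives ρ = 525,600/0.0007 ≈ 7.51×10⁸ pg/mm³
(≈0.75 g/cm³, a physically sensible lipid-deposit density). The same ρ is
used for clearance, which is the internal-consistency argument for the
calibration. Growth is exactly linear: 0.7–4.2 µm/year for fluxes 1–6,
i.e. 35–210 µm over 50 years.

Macrophages clear deposit Ch at
`density × vmax_per_cell × s`, `s = C_ApoAI/(Km + C_ApoAI)` (or `s = 1`
with the saturating flag). Clearance simulations are clearance-only by
default (no concurrent deposition; an `include_deposition` option adds the
2.90 pg/mm²/min ApoB flux). Height is piecewise linear and floored at
zero; the time to clear `h0` is `h0·ρ / clearance flux`. Baselines:
1,000 cells/mm², vmax 5.79×10⁻² pg/cell/min, ApoA-I 25 µg/ml (s = 5/6),
initial height 120 µm. The headline "density required for a 10-month
clearance" uses the saturating limit `s = 1` (≈3,553 cells/mm²); under the
baseline 25 µg/ml factor it would be ≈4,263. Both conventions are exposed;
the saturating one is the operation's default because the benchmark it
reproduces is stated as a limiting value.

## Fenestral pore permeability

Free diffusivity from Stokes–Einstein, `D = k_B·T/(3π·η·d)`; hindrance
from the Renkin centerline factor
`H(λ) = (1−λ)²(1 − 2.104λ + 2.09λ³ − 0.95λ⁵)`, zero at λ ≥ 1. The
effective permeability is `P = D·H·ε/L` with ε the open-pore area
fraction. The geometry defaults — pore diameter 12 nm (upper end of the
observed 6–12 nm), path length 40 nm, 12 pores per fenestra, 10 fenestrae
per µm² — are a calibration set that places the 6.3 nm ApoA-I-Ch particle
at 1.28×10⁻⁴ cm/s, inside the 41% uncertainty band of the 1.2×10⁻⁴ cm/s
constant the transport model uses. This module is explanatory/validation:
the downstream model always uses the registry constant. 21 nm LDL and
~70 nm ApoB-Ch particles give λ > 1 and are excluded (P = 0), which is the
mechanistic basis for modelling LDL entry as transcytosis and ApoB-Ch
entrapment as drusen. No electrostatic or diaphragm sterics are modelled.

## Uncertainty propagation

Printed percent uncertainties are interpreted as coefficients of variation
of lognormal distributions with median at the point value (all quantities
are positive; the convention preserves medians under the multiplicative
arithmetic that dominates this model). Whether they were meant as SDs, CVs
or ranges is not stated in the source data; CV-of-lognormal is this
package's documented choice. `k_t` and the disc formation rate are drawn
with a common deviate since they are the same measurement. The CV of the
ApoB-Ch flux rides on the liver-equivalent source flux so that the
computed product inherits it. Monte-Carlo summaries report median and
2.5/97.5 percentiles; medians recover the point estimates by construction
(verified at n = 2,000 within 5%).

## Numerical choices and degenerate inputs

- Chain ODE: implicit BDF with analytic Jacobian, rtol 1e-10; steady state
  cross-checked against the geometric closed form at 1e-6 relative.
- Quadratic steady state: closed form with the stable root expression;
  residual of the flux balance ≤ 1e-10 relative, cross-checked against a
  bracketing root-finder.
- `k_out = 0` gives a flat profile, fold decrease 1, zero pool efflux;
  macrophage density 0 gives no clearance and an undefined (None) clearing
  time; `fold_decrease < 1` and `f ∉ [0,1]` are rejected.
- Unit conversions are exact factor products; cycles return the input to
  1e-12 relative.

## What the defaults do and do not represent

The shipped defaults are the model's published operating point for a human
eye, not fits to any dataset distributed here. Scenario tables emulate the
model's standard figures (profile, turnover line, uptake curves, growth
band, clearance families) as CSV. Passing tests demonstrate internal
consistency of the flux bookkeeping and reproduction of the model's own
benchmark numbers; they do not validate the biology — most module-3
constants descend from hepatic data scaled by geometry, the recycling
mechanism is hypothesised, and spatial drusen geometry, pathway
competition, LDLR regulation, macrophage recruitment and cone/foveal
dynamics are all outside the model.
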