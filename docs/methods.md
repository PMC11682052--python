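# Methods

## Scope and intent

`tipsnet` is a reduced-order (lumped-parameter, "0D") surrogate for
steady-state CFD of the portal venous system after TIPS placement. The
spatially resolved quantities of a 3D solve — wall-area statistics
(ALWSS/AHWSS), streamlines, swirling secondary flow, grid-convergence
figures — are out of scope by construction: a network of cylindrical edges
has no wall field. What the surrogate does deliver are the planning-level
scalars: nodal static pressures (hence the portal pressure gradient, PPG),
edge flows (hence shunt velocity, flow fraction and Reynolds number), and
segment-mean wall shear stress with threshold classification. The
relative-error comparator `(x − x_ref)/x_ref × 100%` is exposed generically
and is also exercised against published 3D wall-area statistics as fixtures.

## Network topology

SV and SMV inflow edges merge at the MPV inlet; the MPV trunk is split at
its midpoint by the pressure probe node and ends at the LPV/RPV bifurcation;
each intrahepatic branch drains through a lumped resistance to the IVC sink
(0 Pa). The stent (8 mm × 60 mm) tees off 10 mm upstream of the bifurcation
on the MPV, or 10 mm downstream of it on the named branch, and discharges
directly into the IVC. The stent is carried as a two-edge chain so that the
inlet probe plane (10 mm from the entrance, i.e. 50 mm from the outlet) is a
real node; structurally it is validated as exactly one shunt conduit.

Default segment lengths — SV/SMV 80/100 mm (Type A), 30/40 mm (Type B),
absent (Type C, combined inflow at an MPV stub); MPV trunk 40 mm;
intrahepatic branches 30 mm — are plausible adult anatomy. Because the
inflows are prescribed, downstream results are insensitive to the upstream
lengths: friction in those slow segments is below 1% of the PPG, and the
Type A/B/C networks are *identical* downstream of the MPV inlet, which is
why the simplification-invariance properties hold exactly in 0D (the 3D
study finds ≤3.15% on MPV pressure and ~1% on shunt velocity).

## Boundary conditions

* Preoperative MPV flow `Q_pre = V_pre · πd²/4`; postoperative flow doubled.
* Murray's-law splits (diameter cubed) for the SV/SMV inlets and for the
  hepatic outflow weighting. The second component of every split is computed
  by difference and the first re-derived until the pair sums to the total
  bitwise, so conservation assertions are exact.
* Outlet resistances `R_i = P_pv / (Q_pre · w_i)` with `w_i` the cubic
  weight and `P_pv = 25 mmHg`, converted at 133.322 Pa/mmHg. With that
  constant, Patient #1's LPV resistance computes to 1.5377e8 Pa s m⁻³ where
  the reference table prints 1.53e8 (0.5%); the source's conversion constant
  or pre-rounding is unstated, so the computed value is reported and that
  one fixture is held to 1% relative. All other printed cells reproduce to
  3 significant figures.
* Constant (non-pulsatile) flows and pure resistances; no Windkessel
  compliance. The parabolic inlet velocity profile of a 3D model has no 0D
  analogue — only mean flows enter the network.

## Edge loss laws

For flow q in a segment of diameter d, length L (velocity `V = q/A`):

* friction: `f (L/d) ρV²/2`, with `f = 64/Re` for `Re ≤ 2300` (identically
  the Poiseuille drop `128 μ L q / (π d⁴)`) and Blasius `0.316 Re^(−1/4)`
  above. The transitional band (2300 < Re < 4000), where the stent operates,
  uses the turbulent correlation without blending — the discrete analogue of
  applying a turbulence model to transitional flow. The jump in f at the
  threshold keeps the loss law monotone (it jumps upward), which is what the
  solver needs.
* minor losses: `K ρV²/2` per declared coefficient; the stent entrance
  carries K = 0.45 (sudden contraction) + 0.25 (bend), handbook values. No
  exit-recovery term: the jet's kinetic energy is assumed dissipated in the
  IVC, so the stent outlet static pressure equals the sink pressure.
* static-pressure correction: `ρ(V_down² − V_up²)/2` where an edge's lumen
  differs from its parent conduit, both velocities evaluated at the *edge's
  own* flow. This is the dominant term of the MPV-to-stent-inlet drop
  (~700 Pa at the headline flow) and, applied at the branch entrances, is
  what makes MPV placement the lowest-PPG position: a stent on the LPV/RPV
  sits behind the bifurcation's own acceleration loss.

All losses are written as odd functions of signed flow (magnitude laws with
the sign restored), so reversed flow is representable even though the study
conditions never produce it. Static pressure, not total, is reported at all
probes, matching what CFD pressure contours show.

The measured decomposition of the headline case's ~10 mmHg drop from the
MPV midsection to the stent inlet probe (acceleration ≈ 5.5 mmHg, entrance
minor losses ≈ 4.1 mmHg, entrance friction ≈ 0.3 mmHg) is a modelling
choice, not a fitted match; the remaining ~1.6 mmHg over the stent body is
pure friction, consistent with the reported "about 2 mmHg".

## Solver

Unknowns: static pressures of all non-sink nodes plus flows of all
non-prescribed edges. Equations: one pressure-drop relation per edge
(`P = Rq` for the resistance outlets) and mass balance at every interior
node; inflow edges carry their boundary flows exactly. The damped Newton
iteration uses analytic loss derivatives, row/column nondimensionalisation
(pressure scale 25 mmHg, flow scale the total inflow), a backtracking line
search, and starts from the all-laminar linear solution, which lands within
the Newton basin in all studied cases (3–6 iterations). Convergence demands
max nodal imbalance ≤ 1e-12 m³/s (≈1e-8 of total inflow) and edge residuals
≤ 1e-6 Pa. Zero total inflow returns the zero solution without iterating.
The solve is fully deterministic.

An independent route, `solve_path_reduction`, exploits the tree-plus-shunt
topology: the pressure a subtree needs to discharge a given flow is strictly
increasing in that flow (all loss laws are monotone), so each two-way
junction reduces to one bracketed scalar root-find (`scipy.optimize.brentq`
at machine-precision tolerances), nested through the tee and the
bifurcation. The two routes agree to better than 1e-8 relative on all 18
cases, and the path route doubles as the fallback if Newton ever fails.

## Synthetic cohorts

The generator draws patient records uniformly inside closed boxes anchored
to the printed patients: diameters MPV 14–18, SV 8–15, SMV 10–17, LPV 9–13,
RPV 8–10 mm; preoperative MPV velocity 0.1–0.3 m/s; portal pressure
20–30 mmHg. Uniform boxes make bound assertions exact; no distributional
claim beyond the ranges is made. One integer seed governs a cohort, with
per-record substreams keyed by (seed, index) so records are
order-independent.

What the generator emulates is the *scalar* clinical record the pipeline
consumes — it does not emulate lumen shapes, measurement noise structure, or
correlations between vessel calibres (real anatomy correlates MPV size with
inflow calibres; the box treats them independently). Passing cohort tests
therefore demonstrates numerical robustness over the declared parameter
region, not population realism.

One scoping note: a plausibility envelope of PPG ∈ (5, 20) mmHg around the
printed 10–12 mmHg band cannot hold over the *entire* default box, because
every shunt-path loss scales with flow squared while the outlet-resistance
closure keeps the hepatic fraction modest — at the low-flow corner
(`Q_pre ≈ 1.5e-5 m³/s`) the PPG falls to ~3–4 mmHg for any loss model
consistent with the calibration anchors above, and the high-flow corner
exceeds 20 mmHg. The envelope is therefore asserted for records whose
preoperative MPV flow lies in the patient-like band 2.5e-5–6e-5 m³/s (both
printed patients sit near 4e-5); over the full box the asserted invariants
are convergence, conservation, positive PPG and shunt fraction in (0.5,
0.95). A 5%-jitter perturbation harness additionally checks that the
solver remains convergent and the PPG response bounded.

## Numerical and design choices

* mmHg ↔ Pa conversion fixed at 133.322 Pa/mmHg, declared once.
* Diameters are carried in mm in patient records (directly checkable against
  clinical tables) and converted to SI at network build.
* WSS thresholds (6/10/15 Pa) are config-exposed with the study's values as
  defaults; classification is a pure threshold function (strictly below the
  low threshold → "low", strictly above 15 Pa → "high").
* Report writers emit byte-deterministic CSV (stable column order, units in
  headers) and nested JSON that round-trips to an equal study table.
* Problem sizes: the full 18-case study solves in well under a second; the
  property suites use 25-record cohorts and 20-draw perturbation sets, which
  keep the whole test run at a few seconds while exercising every branch of
  the loss laws.

## Known limitations

* No 3D fields: wall-area statistics, WSS maps, streamlines and secondary
  (swirling) flow are unavailable; segment-mean WSS understates local
  extrema near the tee, so "high"-WSS classifications are conservative.
* The transition-regime friction (Blasius without blending) and the minor
  loss coefficients are handbook-level approximations; the absolute
  stent-path decomposition carries ~10–20% model-form uncertainty even
  though the headline scalars land inside the reported 3D ranges.
* Rigid walls, Newtonian blood, steady flow, and a zero-pressure IVC are
  inherited assumptions of the study design.
* The nodal pressure is the 0D analogue of an area-averaged 3D cross-section
  pressure; no further averaging is defined.
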