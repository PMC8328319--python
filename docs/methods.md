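# Methods

This note documents the models inside `cvwaves`, the reasoning behind the
defaults, the numerics, and what the synthetic fixtures do and do not
represent. Units throughout: pressure mmHg, volume mL, flow mL/s, length
cm, time s; the solver works internally in CGS (1 mmHg = 1333.22 dyn/cm²),
blood density ρ = 1.05 g/mL, kinematic viscosity ν = 0.0333 cm²/s.

## Ventricle

The left ventricle is a time-varying elastance chamber:

    P_LV(V, t) = ε(t) · E_es (V − V_d) + (1 − ε(t)) · P_0 exp(β V)

* `E_es` — end-systolic elastance, mmHg/mL. The contractility index; the
  study pair uses 3 (high) and 1 (low).
* `V_d` — ESPVR volume intercept, mL (−2 and −60 for the pair; the pairing
  is a modelling choice that makes the EF span 65 → 55 % across scenarios).
* `P_0 = 2.3` mmHg, `β = 0.013` 1/mL — exponential end-diastolic relation,
  shared by both hearts (EDPVR(97) ≈ 8.1 mmHg, EDPVR(120) ≈ 11.0 mmHg).
* Heart rate 70 bpm.

The activation ε(t) is the canonical double-hill,
ε ∝ [x₁/(1+x₁)]·[1/(1+x₂)] with x₁ = (t/0.269T)^1.32, x₂ = (t/0.452T)^27.4,
normalized to max 1. The exponents/time constants are the standard
literature values; they are exposed on `LVParameters` but not varied here.
The curve is precomputed once per cycle on the solver's time grid.

**Preload.** A scenario's preload is an (EDV, EDP) pair linked by the
EDPVR; either may be given, and a supplied pair must agree through the
EDPVR within 0.2 mmHg or it is rejected. During diastole the ventricle
refills from a constant-pressure venous source at the scenario's EDP
through a small resistance (`R_fill` = 0.01 mmHg·s/mL), which lets the
volume equilibrate to the scenario EDV by end-diastole without a venous
return model; the isovolumic phases emerge from the valve logic alone.

## Valve

A Bernoulli-inertance orifice with first-order leaflet dynamics:

    L dQ/dt = P_LV − P_root − (B/ζ²) Q |Q|,
    dζ/dt = K (1−ζ) ΔP   (ΔP > 0),   K ζ ΔP   (ΔP ≤ 0)

with B = 4.5·10⁻⁵ mmHg·s²/mL² (effective orifice ≈ 3 cm², a normal valve),
L = 1.0·10⁻³ mmHg·s²/mL (≈ 5 cm of blood column over a 4 cm² outflow
tract) and K = 4 /(mmHg·s) (≈ 50 ms opening). These place the peak of
aortic flow 0.05–0.07 s after ejection onset and the LV upstroke dP/dt in
the low-10³ mmHg/s range — standard healthy values. The valve seals on
flow reversal; regurgitation is not modelled.

## Arterial network

Tapered 1D segments with a *linear* elastic wall: constant area compliance
C′ (cm²/mmHg per cm) per segment, P = P_ref + (A − A0(x))/C′ with the
resting geometry A0(x) defined at P_ref = 90 mmHg. Local wave speed
c = √(A/ρC′); characteristic impedance Zc = √(ρ/(A C′)) = ρc/A. The
momentum sink is the boundary-layer friction −22πν·Q/A; the same law gives
each segment's "Poiseuille" resistance for the aggregate calculations, so
steady pressure drops, total vascular resistance (TVR) and the mean
pressure balance MAP = CO·TVR + P_out are mutually consistent.

Leaves carry three-element Windkessels (R1–C–R2, outflow pressure P_out).
R1 is set to the leaf's characteristic impedance, which makes the
termination transparent at high frequency; reflections come from R2/C (low
frequency) and from the tree's geometric and stiffness taper.

Aggregates (`tree_aggregates`): TVR by series/parallel reduction of segment
friction resistances and terminal (R1+R2); arterial compliance C_A = Σ C′·L;
terminal compliance C_T = Σ C; TVC = C_A + C_T; Zc at the root inlet.

## Numerics

* Two-step (MacCormack) Lax–Wendroff per segment, in conservative flux form
  F = [Q, Q²/A + A²/(2ρC′)] with the geometric taper source (A/ρC′)·dA0/dx.
  The conservative form is exactly balanced at rest; the non-conservative
  pressure-gradient form produces a first-order spurious mean flow on
  tapered segments and is not used.
* Boundaries couple through the linear-wall Riemann invariants W± = u ± 2c.
  On a tapered, frictional segment W± are not exactly invariant; the
  extrapolation to each boundary foot carries the source term
  (dA0/dx)/(ρC′) − friction, without which steady flows through tapered
  trees lose O(10%) of their mass at boundaries.
* The characteristic boundary overwrite is still not flux-consistent with
  the interior stencil at O(Δx); a per-segment volume-balance correction
  (trapezoidal boundary fluxes; residual spread uniformly over interior
  nodes) restores exact conservation. The correction is a few 10⁻⁴ of
  segment volume per step at the default resolution.
* Bifurcations: Newton solve per junction per step for (A, u) of the
  parent end and every child start — parent/child invariants, exact mass
  conservation, and continuity of total pressure P + ρu²/2. Converges in
  2–4 iterations; the 6–8 unknown systems are solved by direct elimination.
* Time step: global, from the worst-case CFL over all cells with safety
  0.8 evaluated at a generous pressure/velocity margin (150 mmHg, 250
  cm/s), and audited against the actual local speeds every step (a
  violation raises an error naming the segment). With the default grids
  (Δx ≈ 1–3 cm) dt ≈ 0.5–0.8 ms.
* Cycles repeat (from a uniform 80 mmHg, zero-flow start) until the
  cycle-to-cycle RMS difference of root pressure is < 0.5 % of its pulse
  pressure — typically 6–8 cycles; non-convergence is flagged on the
  result, never silent. The final cycle is resampled to 1 kHz.
* Everything is double precision and deterministic: identical inputs give
  bit-identical waveforms. The kernel is JIT-compiled with numba.

## The fixture tree

`build_fixture_tree` constructs a 12-segment reduced network — ascending
aorta → arch → thoracic → abdominal → infrarenal aorta, a head trunk, one
arm path (subclavian → brachial → radial ∥ ulnar, radial measurement site
at the wrist), lumped visceral and leg trunks — tuned to the aggregate
afterload of a healthy middle-aged adult: TVR 1.22 mmHg·s/mL, TVC 0.88
mL/mmHg (C_A 0.62 + C_T 0.26), aortic root Zc 0.04 mmHg·s/mL. Tuning is
deterministic and staged so the three targets decouple:

1. root segment compliance from the Zc target (Zc = √(ρ/(A C′)));
2. branch compliances from textbook wave speeds (750–950 cm/s);
3. remaining aortic compliances scaled by a common factor (root-found) to
   land C_A, with the arch geometrically blended toward the root compliance
   (weight 0.65) so the proximal aorta stiffens gradually rather than in
   one jump;
4. terminal R1 = leaf characteristic impedance; terminal R2 scaled by a
   common factor (root-found) so the full series/parallel reduction equals
   the TVR target. Flow fractions: viscera 42 %, legs 37.6 %, head 16 %,
   each forearm vessel 2.2 %.

Terminal compliances are distributed as (bed conductance)^1.5 rather than
proportionally: small distal beds (hand) are relatively stiff. This choice
reproduces the textbook aorta→radial pulse pressure amplification (≈
1.3–1.7); proportional distribution leaves the radial pulse essentially
unamplified. Terminal P_out = 0, consistent with defining TVR = MAP/CO.

A consequence of forcing a compliant root (Zc 0.04 at a 3.5 cm diameter)
inside a total compliance budget of 0.88 mL/mmHg is a stiff distal aorta
(wave speeds 8–12 m/s, as in an older adult) and hence somewhat stronger
and earlier reflection than a full anatomical tree distributes; the Zc
recovered from harmonics 3–9 of the simulated input impedance is ≈ 0.045.

**What the fixture does not emulate.** No coronary or cerebral circulation,
no anatomical side-branch detail, no nonlinear or viscoelastic wall
behaviour, no venous return. Passing tests on this tree show that the
*mechanism* — contractility reshaping the forward wave and with it the
pulse phenotypes — survives a drastic network reduction; they do not
certify absolute waveform accuracy against in vivo data.

**Synthetic waveforms** (`synth_waveform`) are sums of compactly-supported
raised-cosine bumps on a baseline, so systolic/diastolic values, peak
amplitudes, the peripheral peak ratio, and the inflection time (half a
half-width past the early-bump center) are known in closed form; they are
exactly periodic. These ground-truth the analysis detectors independently
of the solver.

## Pulse wave analysis choices

* Derivatives are taken on a Savitzky–Golay smoothed copy (window 30 ms,
  order 3, periodic wrap; both configurable). Every detected landmark's
  timing is therefore resolved to about one window.
* Ejection onset for a lone pressure wave: intersecting-tangent foot
  (tangent at max dP/dt intersected with the diastolic minimum). Simulated
  results carry the exact valve-opening time instead; reported timings are
  "since beginning of ejection".
* The shoulder is the first falling→rising zero crossing of the smoothed
  second derivative after the upstroke, within a systolic window of 45 %
  of the period. A crossing counts only if pressure at the end of its
  positive-curvature stretch still exceeds DBP + 25 % PP; the decaying tail
  of a single smooth pulse fails this and the result is an explicit
  "no shoulder" (phenotype Intermediate), not an exception.
* Augmentation sign convention: peak after shoulder → cAP = SBP −
  P(shoulder) > 0; peak before a late shoulder → cAP = P(shoulder) − SBP
  < 0. Type A requires peak-after-shoulder and cAIx > 12 %; Type C requires
  peak-before-inflection and cAIx < 0; everything else (including 0–12 %)
  is reported Intermediate.
* Radial augmentation ratio: late/early systolic peak amplitudes above the
  diastolic minimum; with a single distinct peak the missing feature is
  taken from the shoulder detector, and a single-featured wave returns an
  explicit undefined.
* Wave separation transforms exactly one period (no windowing); the mean
  pressure is split equally between the components, so Pf + Pb = P holds
  pointwise to machine precision. "Amplitude" of a component is its
  max − min over the cycle; "peak" is its absolute maximum.

## The experiment

`match_preload` adjusts EDV (EDP follows through the EDPVR) by bisection
in [60, 200] mL until the simulated stroke volume is within 0.5 mL of
target (the Frank–Starling direction makes SV monotone in EDV, verified on
the bracket). Because SV is nearly linear in EDV, two probe runs and a
linear prediction pre-refine the bracket first; a scenario typically needs
5–7 simulations.

`run_contractility_experiment` runs the high/low pair on one shared tree
(hash recorded), collects the full per-scenario report, and evaluates the
directional signature of raising contractility at constant output and
afterload: higher and earlier aortic flow peak, higher LV and aortic
dP/dt_max, earlier and steeper forward-wave peak, near-invariant forward/
backward amplitudes and reflection coefficient, higher radial SBP/PP and
amplification, lower central and radial augmentation with the Type A → C
phenotype flip, mean pressure within 3 % and cardiac output within 2 %
across the pair. `sensitivity_suite` re-runs the pair under five variants —
fixed preload (EDP 11 mmHg for both, no SV matching) and ±20 % compliance
or resistance — and re-evaluates the checks per variant.

## Known limitations

* The cross-scenario invariance of the forward amplitude and of the
  reflection coefficient comes out at ~11 % and ~14 % on the reduced tree
  (a full anatomical network keeps both within ~5 %): the high-E_es flow
  peak is overestimated (~580 mL/s) because the reduced proximal aorta
  presents too little early wave-trapping, which inflates the forward
  amplitude in that scenario only. The corresponding checks are reported
  honestly as failures by the experiment's check list.
* The linear wall law ignores the pressure dependence of compliance and
  all viscoelasticity; diastolic pressures run ~5–8 mmHg lower than a
  nonlinear-wall model at the same aggregates.
* The Murgo thresholds (0 and 12 %) make the phenotype assignment
  sensitive near cAIx ≈ 0; the high-contractility scenario sits at −1.5 %,
  so small analysis-parameter changes can move it to Intermediate.
* Problem sizes: the default tree has 86 grid nodes and a ~0.6 ms time
  step; a converged beat takes well under a second of CPU and the full
  paired experiment with preload matching runs in seconds, so all tests
  and the acceptance run use the full default resolution.
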