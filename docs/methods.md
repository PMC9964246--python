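# Methods

This note documents the models, the defaults and why they were chosen, the
numerical machinery, and what the synthetic cohort does and does not emulate.

## Synthetic gait cohort

The generator replaces optical motion capture and musculoskeletal simulation
with a statistical emulator of their summary outputs. Each group is described
by means and SDs of body mass (kg), stature (m), walking velocity (m/s),
stride length (m), net peak medial tibiofemoral force (N), the three vasti
peak forces (BW) and knee flexion angle at peak force (deg). Only means and
SDs are specified, so each variable is sampled as a truncated normal (lower
bound 0). Defaults carry the study conditions: n = 20 per group, healthy
weight (mass 63.18 ± 3.55 kg, stature 1.63 ± 0.05 m, velocity 1.45 ± 0.24
m/s, stride 1.61 ± 0.21 m, net peak force 1493.21 ± 370.19 N) and obese
(92.82 ± 5.59 kg, 1.63 ± 0.05 m, 1.38 ± 0.21 m/s, 1.55 ± 0.18 m, 2013.92 ±
570.91 N).

Decisions taken where the design was open:

- **Net force is the sampled force variable.** The published group tables
  report both normalized (BW) and net (N) peak forces, and together with the
  group masses those means are mutually inconsistent under the
  per-participant identity F_BW = F_N/(m·g) (g = 9.81 m/s²), so only one can
  be reproduced exactly. The net value drives the contact solve and the
  printed force contrast, so it is sampled and the BW value derived. The
  vasti forces sample BW and derive N.
- **BMI is derived, never sampled.** BMI = mass/stature² holds per
  participant by construction; pairs outside the group's eligibility bounds
  (healthy < 25, obese > 30 kg/m²) are resampled, capped at 10⁵ draws (the
  cap signals bounds infeasible for the given mean/SD). Because mass and
  stature are sampled independently, the implied BMI spread is somewhat wider
  than a screened empirical sample would show, and the screen slightly biases
  the retained mass/stature means — exactly as BMI-screened recruitment does.
- **Exact-mean mode.** For reproducing printed group contrasts to the digit,
  `enforce_exact_means` recentres each variable's sampled deviations so every
  sample mean equals its specification exactly. Mass is special: with a BMI
  target present, masses receive the smallest adjustment making both the mass
  mean and the BMI mean exact while every BMI stays inside the eligibility
  bounds — alternating projections in BMI space between the two mean
  constraints (an affine subspace) and the BMI box, with mass rebuilt as
  BMI·stature² so the identity survives.
- **Waveform.** Stance-phase (0–100 %, 101 points) medial force is a smooth
  two-bump profile (weight acceptance at 25 %, push-off at 75 %, widths 10 %,
  second bump 0.93 of the first so the global maximum is unique) over a broad
  mid-stance component whose amplitude is solved so the trough sits at 0.65
  of the peak; the curve is normalized and scaled so its maximum equals the
  participant's peak force exactly. Endpoints stay below 5 % of the peak,
  consistent with a force-threshold definition of stance. Only the peak and
  derived summaries of the real waveforms are constrained by published data;
  the shape itself is a modelling choice and fully config-exposed.
- **Flexion at peak force** is not constrained by any published value here;
  the default 15 ± 4° is a typical early-stance flexion during walking and is
  config-exposed.

What passing tests on this cohort do **not** show: the generator has no
kinematic content (no marker trajectories, joint angles beyond the single
flexion scalar, or ground reaction forces), no within-subject trial
variability, and no correlation structure between variables (e.g. mass and
stature are independent). Conclusions about real gait data would need the
upstream measurement chain this package deliberately replaces.

## Elastic-foundation contact model

Cartilage is a bed of independent compressive columns on a rigid substrate;
element stress depends only on local compression. The femoral condyle is two
sagittal arcs — anterior 35.0 mm, posterior 18.9 mm — and one frontal arc;
the tibial plateau is concave (21.0 mm) in the frontal plane and flat
sagittally. The unloaded gap is the sum of the sagittal arc profile and the
frontal femoral-minus-tibial relief (exact circular arcs, additive
composition). Lowering the flexion axis by a penetration δ compresses each
column by max(0, δ − gap); strain is compression over the 5.0 mm unloaded
height, capped at 0.95 to avoid the log singularity, and stress follows
σ = −E_eff ln(1−ε) (natural log — required for consistency with the
nonlinear elastic column law; the total column force then inverts in closed
form, which the single-element oracle test exploits).

- **Grid.** 66 × 111 inclusive nodes at 0.5 mm over a 32.5 mm (frontal) ×
  55.0 mm (sagittal) footprint = 7326 elements; the published model states
  count and spacing, the extents realize them. The meniscus-covered region is
  a peripheral band (outer rectangular rings, partial ring filled in a fixed
  order) holding 46 % of elements to the nearest element.
- **Moduli.** Default composition is springs-in-series through the column
  stack: 1/E_eff is the mean compliance of (femoral, tibial) for uncovered
  and (femoral, covered tibial, meniscus) for covered columns; an
  arithmetic-mean rule is config-exposed. Moduli are converted to
  confined-compression (aggregate) form E(1−ν)/((1+ν)(1−2ν)), ×3.79 at
  ν = 0.45. This correction is on by default: foundation columns are
  laterally confined, and without the factor the model cannot carry the
  study-scale forces (1300–2300 N) at physiological strains — peak strain
  would reach 0.5–0.6, far outside the published 0.19–0.25 group means,
  whereas with it the solver lands at 0.21/0.25 at the two group-mean forces.
- **Frontal femoral radius.** Never published for this model; the default
  21.0 mm, congruent with the tibial frontal arc, follows the near-congruent
  frontal geometry of the foundation model this implementation is patterned
  on. It is config-exposed and is a package default, not a measured value.
- **Flexion.** The anterior arc carries load below the tangency angle
  (default 25°, config-exposed; the two-arc construction fixes only the
  radii, not the transition, so it is a parameter) and the tighter posterior
  arc above it. No translational kinematics: the condyle stays centred on the
  plateau.
- **Solver.** Total force is strictly increasing in penetration, so the
  force-matching solve uses geometric bracket growth plus bisection;
  tolerance max(0.5 N, 10⁻⁴·target), iteration cap 200. A target above the
  force with every reachable element at the strain cap raises a saturation
  error.
- **Stressed volume.** Default is the strain-integrated volume
  V = Σ εᵢ·dA·h = Σ compressionᵢ·dA — the volume-equivalent of the strain
  field. The alternative "every contacted column counts its full unloaded
  volume" is retained (`volume_mode="full_column"`, with a configurable
  strain threshold) but not default: it yields V ≈ 2700 mm³, i.e. V/V_ref ≈
  35, which drives the Weibull model to near-certain failure within the
  first years at study-scale strains, incompatible with the published
  lifetime probabilities; the strain-integrated measure (≈ 350–500 mm³)
  reproduces their scale.

## Failure model

Canonical forms (the printed source equations are typographically garbled;
these reconstructions reproduce the two stated 63.2 % characteristic-point
interpretations and the published orderings):

- cycles to failure N = A(Bε)^−m with A = 1.0, B = 1.03, m = 12.9;
- daily cycles = D/L (one loading cycle per stride of the studied limb;
  D = 6.0 km/day ≈ 7000 steps);
- characteristic life t_fail = N·L/D days, stored in years (365.25 d/y);
- failure CDF P(t) = 1 − exp[−(V/V_ref)(t/t_fail)^(k/m)], V_ref = 78.5 mm³,
  k = 14.3, shape k/m ≈ 1.109; P(t_fail) = 63.2 % when V = V_ref;
- repair CDF P_rep(t) = 1 − exp[−(t/t_rep)^r], t_rep = 5.0 y, r = 5.2;
  P_rep(t_rep) = 63.2 %;
- failure with repair = ∫₀ᵗ f(τ)(1 − P_rep(τ)) dτ with f the failure
  density.

Numerics: the output grid is monthly (dt = 1/12 y, config-exposed) over the
42-year horizon; the quadrature runs on an 8× refined internal grid; the
density carries a weak t^(k/m−1) singularity at zero, so the first internal
cell is integrated analytically as P(dt)·(1 − P_rep(dt/2)). The continuum
integral is bounded above by the no-repair CDF, and the computed series is
truncated against that exact bound so the dominance invariant holds to
machine precision; a convergence check recomputes the endpoint at half the
step and raises if it moves by ≥ 10⁻³. Zero strain returns an infinite-life
sentinel (both curves identically zero) so unloaded cohort members aggregate
cleanly. V is held at its peak-force value over the whole horizon (the model
has no within-stance or ageing variation of the stressed volume).

The one-at-a-time sensitivity sweep re-solves the contact model per swept
value (geometry fields, per-region moduli, flexion, target force), holding
all other parameters at their modelled values; solver failures at extreme
values are recorded as NaN per point rather than aborting.

Known limitation: with shape k/m ≈ 1.109 the failure-time distribution is
nearly exponential, so participants with obese-scale strains (ε ≈ 0.25,
t_fail ≈ 30 y, V/V_ref ≈ 5–7) accumulate a substantial share of their
lifetime failure probability within the first years. Group-averaged curves
therefore rise early for the obese group; a model with a delayed onset would
need a larger shape parameter or an explicit damage-incubation term, neither
of which the published constants provide.

## Statistics

With one observation per participant a participant random intercept is not
identifiable, so the group contrast is the pooled-variance two-sample
estimator: b = difference of group means (obese − healthy), df = n₁+n₂−2,
CI and p from the t distribution. This reproduces published b values exactly
as differences of group means on exact-mean cohorts; printed t/p under other
software's df conventions may differ in trailing digits. Power analysis uses
Cohen's d with pooled SD √((s₁²+s₂²)/2) and exact noncentral-t power,
two-sided α = 0.05 ("β = 80 %" in the source is read as power = 80 %, the
conventional misnotation). Cumulative load is mean stance-phase force over
stride length (note: the published cumulative loads exceed peak-force/stride
for both groups, so they cannot arise from that quotient with the published
peaks; the implementation follows the stated definition). ICC is the two-way
mixed consistency coefficient ICC(3,1) from the ANOVA decomposition; MDC =
1.96·√2·SEM with SEM = SD·√(1−ICC). No multiple-testing correction is
applied (none was used in the study design; α = 0.05 per test).

## Pipeline

A single study seed fans out through `numpy.random.SeedSequence.spawn` into
per-group child seeds; two runs with the same config are byte-identical
(floats serialized at 17 significant digits). Per participant: contact solve
at (net peak force, flexion) → failure curves from (peak strain, stressed
volume, stride length) → outcome row; then group summaries, contrasts for
every outcome in the study's result tables, BMI regressions per group, and
group-averaged failure curves. Problem sizes are the study's own (n = 20 per
group, 7326 elements, monthly grid over 42 years); a full run takes on the
order of a second.
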