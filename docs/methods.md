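# Methods

## System and model

The package models glucose–insulin cross-talk in a microfluidic chip
culturing a hepatic spheroid compartment (HepaRG/HHSteC, total hepatocyte
volume 3.4·10⁻⁶ L) and a pancreatic-islet compartment (10 reaggregated
human islets, ~50% β cells, initial β-cell volume 8.8·10⁻⁹ L from spheres
of 150 µm diameter). Each compartment holds 300 µL of medium, connected in
a closed loop (plus 5 µL of channel volume) with a mean flow of
2.96·10⁻⁴ L/h (4.94 µL/min), i.e. a ~2 h medium turnover. Both
compartments are treated as well mixed; the pulsatile micro-pump is
represented only by its mean flow.

The state vector is (NG_liver, NG_pancreas, NI_liver, NI_pancreas, G_int,
G_slow, V_β): glucose amounts in mmol, insulin amounts in mIU, the running
integral of liver glucose above the 5.5 mM normoglycemic threshold
(mmol·h/L), the long-term average pancreas glucose (mmol/L), and total
β-cell volume (L). Units are fixed package-wide (mmol, mIU, L, h); no
conversions happen inside the core.

Model structure and assumptions:

- **Hepatic glucose uptake** V_hep·(E_G0 + S_I·I_liver)·G_liver: a
  first-order disposal enhanced linearly by insulin. Endogenous glucose
  production is retained as a parameter but zero by default — observed
  chip glucose falls below normoglycemia, which a nonzero EGP would
  prevent.
- **Insulin secretion** V_β·σ(t)·Hill₂(G_pancreas; EC50_I = 7.86 mM): a
  Hill coefficient-2 sigmoid in pancreas glucose. The per-volume
  capacity σ(t) = σ_max·(1 − t²/(α + t²)) decays sigmoidally in absolute
  culture time, shared across regimes.
- **Hepatic insulin elimination** CL_I·V_hep·I_liver. The liver-side
  insulin balance is not uniquely determined by concentration data alone;
  this form is the one consistent with the translation arithmetic in
  which the whole-medium elimination rate is CL·V_hep/V_m (the 4.04 1/h
  human-scale worked example). No hepatic insulin production is modelled.
- **Insulin resistance** S_I(t) = S_I0·(1 − Imax_Si·G_int/(EC50_Si +
  G_int)): sensitivity declines with cumulative *liver-compartment*
  excess-glucose exposure; G_int is non-decreasing, so resistance never
  reverses. The 0/0 corner (EC50_Si = G_int = 0) is defined as no
  reduction.
- **β-cell adaptation** dV_β/dt = k_v·(−d0 + r1·G_slow − r2·G_slow²)·V_β,
  driven by the *pancreas-compartment* daily-average glucose G_slow
  (first-order averaging, τ_slow = 500 h). With d0 = 2.5·10⁻³ 1/h,
  r1 = 6.3·10⁻⁴ L/mmol/h, r2 = 3.24·10⁻⁵ L²/mmol²/h the growth rate is
  positive exactly for G_slow between 5.55 and 13.87 mM: mild
  hyperglycemia expands β-cell mass, normoglycemia and severe
  hyperglycemia shrink it. r1 and r2 are the identifiable sums of the
  replication and apoptosis contributions; the four addends are never
  represented separately.
- **Single-liver cultures** are the same system with V_β(0) = 0 and
  σ_max = 0 (empty but flow-connected pancreas compartment).

## Protocol as discrete events

t = 0 is co-culture start; both compartments are filled at the regime's
dose (hyper 11, normo 5.5, hypo 2.8 mM) with insulin-free medium. Medium
is exchanged after 24 h and then every 48 h to day 15 (t = 24, 72, …,
312 h); every exchange resets concentrations to the fresh-medium values
and volumes to nominal (the 315 µL actually pipetted is modelled as a
reset to the 300 µL nominal volume). The day-13 exchange doses 11 mM for
*every* regime (it starts the day-13 GTT); the day-1 GTT doses the
regime's own level. Pooled 15 µL samples are taken at GTT start +
{0, 8, 24, 48} h; the 0-h sample immediately follows the exchange
(dose offsets applied first), and a sample coinciding with the *next*
exchange precedes it. Sampling-induced volume loss is tracked by default
(concentrations unchanged, amounts and volumes shrink proportionally); a
flag disables it for the constant-volume idealization. The additive
offsets ΔG/ΔI at the two GTT-start exchanges absorb systematic dosing
error and are calibration parameters.

Slow variables are continuous across all events. G_slow(0) is set to the
initial pancreas concentration, avoiding an artificial relaxation
transient at culture start.

## Numerics

Between events the ODEs are non-stiff at realistic parameters (fastest
rate: inter-compartment mixing, 2Q/V ≈ 2 1/h). Two integration paths share
one compiled right-hand side:

- **adaptive** (default contract): scipy RK45, rtol 1e-8, per-component
  absolute floors scaled to each state's magnitude;
- **fixed**: a numba-compiled classical RK4 with dt = 0.02 h, used in the
  calibration hot loop (~5 ms per full 15-day protocol) and, at
  dt = 1e-3 h, as the brute-force oracle against which the adaptive path
  is verified (<0.1% in every state variable over a 48-h GTT; in practice
  they agree to ~1e-8 relative).

Tiny negative excursions (within the solver floors) are clipped to zero;
larger ones raise an error naming the failure time.

## Calibration

Cost: V(p) = Σ series Σ t (y − ŷ)²/SEM², matched by observable,
compartment and time; conditions (culture type × regime) share all
parameters except the glucose offsets, which are condition-specific in
joint fits; insulin offsets are shared. df = number of data points;
the χ² gate is the 95% quantile at that df. SEM correction: points with
SEM below 5% of their mean take the dataset's largest measured SEM; if
every point is below the floor, all SEMs become 10% of their means.

Search: simulated annealing with Gaussian proposals (5% of each
coordinate's width) in log10 space for positive-scale parameters (E_G0,
CL, S_I0, EC50_Si, σ_max, α, k_v) and linear space for Imax_Si ∈ [0, 1]
and offsets ∈ [−3, 3]; default bounds span ±3 decades around the
canonical magnitudes. Default budget 2·10⁴ proposals over 5 restarts with
geometric cooling (×0.95 per 100 proposals, T₀ = initial cost), followed
by a bounded Nelder–Mead polish of the best vector. Every evaluated
vector with V below the χ² bound joins the "acceptable set" (capped by
deterministic thinning at 2000 entries); uncertainty envelopes are the
pointwise extrema of the simulations over that set, for observables and
for the mechanistic variables (S_I, σ, V_β, G_int, G_slow). A failed
simulation maps to infinite cost, so the annealer simply rejects it.
Runs are reproducible per seed.

The insulin-washout helper estimates the hepatic elimination rate
constant as minus the OLS slope of ln(concentration) vs time.

## Synthetic data

The generator emulates the measurement structure of the chip
experiments: per condition it simulates the true parameters over the
standard protocol (GTT day 1 only for hyperglycemic co-cultures, day 13
for all), then draws n replicate platforms per sampled point with
multiplicative Gaussian noise truth·(1 + ε), ε ~ N(0, CV²) truncated at
−90%, and reports mean, sample SEM and n. Defaults: n = 5 replicates
(the typical platform count, range 4–10) and CV = 10% (the magnitude of
the SEM-correction fallback). Zero-concentration samples — insulin
immediately after an insulin-free exchange — fall below the assay range
and are not reported. With n = 5 the sample SEM of a point falls below
the 5% floor unless its sample CV exceeds 0.05·√5 ≈ 11.2%; at CV = 10%
some points clear the floor and the dataset-max correction route is
exercised, while at CV = 5% essentially all points fall below it and the
10% fallback applies.

An alternative `sem_mode="exact"` draws each reported mean directly from
its exact sampling distribution and records the known SEM = CV·truth/√n.
Under that mode the cost at the generating parameters is χ²-distributed
with df = number of points, making the ~95% pass rate of the χ² gate
directly testable; with sample SEMs and n = 5 the weighted residuals are
t₄-distributed and the SEM floor dominates, so the pass rate is higher.

What the generator does *not* emulate: assay chemistry (ELISA
cross-reactivity, absorbance nonlinearity), inter-platform correlation,
and donor-to-donor covariate structure. Passing recovery tests therefore
demonstrate correctness of the inference machinery under the stated noise
model, not robustness to real-world measurement pathologies.

The recovery study (generate → SEM-correct → anneal against known truth)
defaults to freeing the five kinetic parameters (E_G0, CL, S_I0, σ_max,
α) within one decade either side of the canonical magnitudes, a 3000-
proposal schedule with polish, and random (seeded) starting points. On
joint hyper+normo designs at CV 5% it recovers E_G0, S_I0 and σ_max to a
few percent.

## Parameter defaults

Operating conditions and literature constants are the Table-style values
listed in the type docstrings (V_m 3·10⁻⁴ L, V_hep 3.4·10⁻⁶ L,
Q 2.96·10⁻⁴ L/h, V_sample 1.5·10⁻⁵ L, G_normo 5.5 mM, EC50_I 7.86 mM,
d0, r1, r2 as above, τ_slow 500 h, V_β(0) 8.8·10⁻⁹ L). The
experiment-specific parameters default to a representative hyperglycemic
co-culture fit: E_G0 = 1.47 1/h, CL_I = 17.81 1/h, S_I0 = 5·10⁻³
L/mIU/h, σ_max = 6·10⁶ mIU/L/h. The four remaining experiment-specific
parameters have no canonical published value; the package defaults
(Imax_Si = 0.9, EC50_Si = 500 mmol·h/L, α = 3·10⁴ h², k_v = 1) were
chosen once so that a 15-day hyperglycemic culture expresses the
characteristic phenotype — a several-tens-of-percent loss of insulin
sensitivity, a strong (≈80%) secretion-capacity decay by day 13, and a
modest β-cell volume expansion — and are not tuned thereafter.

## Human translation

scale_to_human multiplies V_hep and V_β(0) by the 10⁵ miniaturization
factor; sets each compartment's medium volume to 1.5 L and
Q = 2.958 L × 12 /h = 35.5 L/h (5-min plasma turnover); multiplies E_G0
and S_I0 by 1/0.45 (the liver's share of postprandial glucose uptake);
multiplies CL by 2 (hepatic share of insulin clearance) and by the 4.23
clearance correction; and leaves EGP at zero. Two deliberate rounding
conventions: the per-compartment medium volume uses the rounded 1.5 L
(half of ~3 L plasma) while Q uses the unrounded 2.958 L plasma volume —
this is the unique combination that reproduces both the 35.5 L/h flow and
the 4.04 1/h uncorrected elimination-rate example. The computed human
E_G0 is 1.47/0.45 = 3.267 1/h; a table that rounds the factor to 2.21
would print 3.25 — the package always uses the computed value. The
uptake factor is applied to S_I0 and hence propagates through the whole
S_I(t) trajectory. σ_max scaling is a user flag (default 1; 0.5 gives
physiological insulin peaks).

The human meal response administers the glucose load directly to both
compartments (no intestinal compartment) starting from zero insulin.
Known artefact: with EGP = 0, late-time glucose falls below
normoglycemia; re-enabling EGP would require data the chip cannot
currently provide.

## Problem sizes and known limitations

The shipped tests and examples use full 360-h protocols for simulation
checks, 3000-proposal annealing schedules with 5 recovery trials, and
100-draw χ² coherence checks; these sizes were chosen as the package's
desk-scale defaults and all scale up via explicit settings objects.
Limitations: no glucagon or incretin biology, no intracellular hepatic
metabolism, no spatial gradients or pulsatile flow, no inter-experiment
(mixed-effects) sharing of information, and calibration quality on real
chip data depends on measurement pathologies the synthetic generator
does not emulate.
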