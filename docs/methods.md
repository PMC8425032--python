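# Methods

This note documents the models behind `symportfit`, the ground-truth
parameters of the packaged presets, the assumptions of the synthetic-data
generator, and the numerical choices in the fitting code.

## Units and conventions

All internal quantities use one fixed system: mV, nA, ms, nC, mM (sugars),
nM (protons), K. Inward current is negative, so transport currents and
Imax values are negative nA. The pairing nA/nC makes the turnover ratio
|Imax|/|Qmax| come out directly in s⁻¹, and nA·ms integrates to nC with a
factor 10⁻³. Proton concentration is 10^(9−pH) nM. Physical constants:
F = 96485.332 C·mol⁻¹, R = 8.3145 J·mol⁻¹·K⁻¹; default temperature
293.15 K (recording temperature is rarely reported for oocyte work; it is
configurable on the preset).

## The simulated TEVC sweep

A voltage-step sweep (hold V_h, step to V_t for 200 ms, with 20 ms pre- and
50 ms post-epochs at 0.1 ms sampling by default) is the sum of:

1. **Ohmic leak** g_leak·(V − E_leak). Buffer subtraction removes it from
   I–V curves; the biexponential transient fit absorbs it into the
   steady-state offset.
2. **Capacitive settling**: amplitude C_m·ΔV/τ_cap decaying with τ_cap,
   carrying total charge C_m·ΔV. Defaults C_m = 20 nF, τ_cap = 0.5 ms —
   an effective clamp-settling description, not a literal oocyte membrane
   capacitance (a full oocyte is ~200 nF, but the voltage clamp slews the
   potential so the recorded settling transient is far smaller than the
   ideal-step value; what matters for the analysis is a fast component
   well separated from the carrier relaxation).
3. **Pre-steady-state carrier relaxation**: total charge
   ΔQ = Qmax·[B(V_t) − B(V_h)] with B(V) = 1/(1 + exp(zF(V−V0.5)/RT)),
   relaxing mono-exponentially with the standard two-state bell-shaped
   time constant τ(V) = τ0/cosh(zF(V−V0.5)/(2RT)), τ0 = 20 ms. With sugar
   present the mobile charge is reduced by the factor
   (1 − 0.8·[S]/([S]+Km)) — substrate binding immobilizes the empty-carrier
   charge in proportion to Michaelis–Menten site occupancy; the 0.8
   saturating suppression reflects that the inhibition is strong but not
   complete.
4. **Steady-state symport current**
   Imax_ref · scale(V) · [S]/([S]+Km) · h([H⁺])/h([H⁺]_ref), plus i.i.d.
   Gaussian current noise (sd 5 nA by default).

The proton activation h is a Hill function (K0.5, n). It is normalized to
1 at the reference pH 5.5, so the preset's Imax_ref is exactly the
saturating-sugar current at the reference voltage (−50 mV) and reference
pH — the quantity a Michaelis–Menten fit at pH 5.5 estimates. Proton and
sugar dependences factorize multiplicatively; the two were measured in
separate experiments and no coupling is assumed. The voltage dependence of
Imax is a piecewise-linear lookup table (scale 1 at −50 mV, larger
magnitude at hyperpolarized potentials), since only the qualitative
direction — higher transport rates at more negative voltages — is known.

The sample at exactly t = step_offset belongs to the post-step epoch (the
clamp is back at the holding potential there); all step windows are
half-open on the right.

Perfusion traces hold the clamp fixed and relax the steady-state current
exponentially toward each bath segment's closed form with a bath-exchange
time constant (default 2 s).

## The packaged presets

`trire2_104072` (oocyte) encodes the fitted constants of the *T. reesei*
L-arabinose/H⁺ symporter as simulation ground truth:

| parameter | value | provenance |
|---|---|---|
| Km, Imax_ref (L-arabinose) | 0.207 mM, −355 nA | fitted TEVC constants at −50 mV / pH 5.5 |
| Km, Imax_ref (D-xylose) | 9.16 mM, −72.3 nA | fitted TEVC constants |
| K0.5 (H⁺) | 68.9 nM | fitted Hill constant |
| Hill n (H⁺) | 0.26 | back-computed: with K0.5 = 68.9 nM, n = 0.26 leaves 1/(1+68.9^0.26) ≈ 25% of maximal activity at pH 9, the reported residual activity |
| Qmax | 5.897 nC | back-computed as \|−355\|/60.2 from the published turnover; the xylose pair \|−72.3\|/12.3 = 5.878 nC agrees within 1%, so one value serves both sugars |
| V0.5, z | −20 mV, 1.0 | not published (shown only graphically, oocyte-dependent); representative values for a sugar-porter charge movement |
| τ0, τ_cap, C_m, leak | 20 ms, 0.5 ms, 20 nF, 0.5 µS→−20 mV | unpublished; representative oocyte values, chosen so the fast and slow transients are separable (τ ratio ≥ 6 over the protocol range) |
| d-glucose entry | Km 5 mM, Imax −15 nA | qualitative: glucose currents are small at −50 mV; used only for selectivity-style simulations |

`trire2_104072_yeast` (uptake): Vmax = 1.49 nmol·min⁻¹·mg_CDW⁻¹,
Km = 0.102 mM at pH 6.5, OD→CDW 0.252 mg·OD⁻¹.

These defaults are the study conditions; they are not tuning knobs.

## What the generator emulates — and what it does not

Emulated: voltage-step and perfusion protocols; sugar-, voltage- and
pH-dependent steady-state symport currents; Boltzmann-distributed charge
movements with bell-shaped relaxation kinetics and sugar suppression;
capacitive and leak components; Gaussian current noise; Poisson
scintillation counting with Poisson blanks (unspecific filter binding);
Gaussian Cp noise around reference-gene means.

Not emulated: multi-state kinetic cycles of the carrier (the PSS transient
is mono-exponential per voltage); pH dependence of Qmax and V0.5; series
resistance, space-clamp error, electrode drift, bath-exchange artifacts on
step sweeps; endogenous oocyte conductances; oocyte-to-oocyte expression
variability (replicates differ only by noise realization); quenching or
counting-efficiency drift in scintillation counting. Passing the recovery
suite therefore demonstrates the correctness of the analysis chain on data
satisfying the model's assumptions, not robustness to every artifact of
real recordings.

## Analysis pipeline choices

**Steady-state extraction** averages the final quarter of the step (last
50 ms of a 200 ms step) — far beyond 5·τ_cap and late enough that even the
slowest carrier relaxation (~20 ms) has decayed by ≥ 3 e-folds at window
start; the window is configurable. The sample SD over the window is
reported as a stability diagnostic.

**I–V construction** requires exact voltage matching between sugar and
buffer sweeps (simulated protocols are nominal); replicate sweeps per
voltage are averaged before subtraction. Normalization divides by the most
negative current at the reference voltage within the experiment; fits of
normalized and raw currents give identical Km (scale invariance, asserted
in tests).

**MM/Hill fits** use unweighted Levenberg–Marquardt least squares (lmfit);
the estimate is the least-squares minimum, so any NLS optimizer reaching
it is equivalent. Initialization: Imax₀ = 1.2× the extreme response, K₀ =
concentration nearest the half-extreme response, n₀ = 1; tolerances
xtol = ftol = 1e-8. The Hill model is fitted in log-concentration space
(response = Imax/(1 + exp(n(ln K0.5 − ln S)))) for conditioning across the
four-decade proton range and reported on the linear scale (K0.5 standard
error by the delta method). Standard errors come from the Jacobian-based
covariance at the optimum.

**PSS isolation** (default method) fits
A_f·e^(−t/τ_f) + A_s·e^(−t/τ_s) + I_ss to the ON segment and returns the
fitted slow component, interpreting the fast component as capacitive
settling. The optimizer is a trust-region reflective least-squares solver
with log-parametrized time constants (τ_s = τ_f·ratio, ratio > 1, which
enforces the ordering) and multi-start over initial time-constant splits —
the two amplitudes can differ by an order of magnitude, which leaves
shallow local minima around merged time constants. A τ_s/τ_f ratio below 3
is flagged as poorly separable. The charge is the trapezoidal integral of
the reconstructed slow component from the step onset to
min(step end, 8·τ_s): because the reconstruction is free of the fast
component there is no need to blank the first few τ_f, and starting later
would discard up to half the charge at voltages where τ_s approaches τ_f
(truncation at 8·τ_s costs e^(−8) ≈ 0.03%). A sweep whose step voltage
equals the holding potential moves no charge by definition and contributes
Q = 0 exactly rather than a meaningless fit to baseline noise. Template
subtraction (sweep minus saturating-sugar sweep at the same voltage, after
steady-state alignment) is available when such a sweep exists; it isolates
the sugar-suppressible fraction of the transient.

**Boltzmann fits** estimate (Qhyp, Qmax, z, V0.5) from Q(V) points by
Levenberg–Marquardt with multi-start over orientation (±z), steepness and
midpoint, keeping the best minimum; |z| is bounded by 25 and the midpoint
by the data range ± 100 mV. Charges referenced to any holding potential
are handled — the constant offset lands in Qhyp. The sigmoid is invariant
under (Qhyp, Qmax, z) → (Qhyp+Qmax, −Qmax, −z), so results are
canonicalized to Qmax > 0, with the sign of z reporting the orientation
found. A fitted midpoint outside the sampled voltage range raises an
ill-conditioned-fit error (all data on one side of V0.5 cannot constrain
the saturating levels).

**Turnover** pairs each replicate's Imax with the same replicate's Qmax,
then averages across replicates, mirroring per-oocyte pairing.

**Uptake** clamps negative net counts (sample below blank) to zero with a
warning — uptake is physically non-negative and blanks measure unspecific
surface binding. Technical replicates are averaged per concentration
before fitting. Inhibition percentages are computed on raw rates unless a
control series is supplied (both modes exist; whether published inhibition
values are control-subtracted is not stated). The two-timepoint linearity
check flags concentrations where the rate ratio deviates from 1 by more
than 20%.

**qPCR** averages reference genes by arithmetic mean of Cp (as specified
for the assay, not geometric mean of relative quantities), computes
expression level 2^−ΔCp, and log₂ fold-changes as ΔCp differences;
replicate pairs are analyzed individually and summarized as mean ± SD.

## Replication and problem sizes

The recovery suite (`symportfit reproduce`, `scripts/acceptance.py`,
`tests/test_acceptance.py`) uses three independently seeded replicates per
experiment — matching the three-oocyte / three-assay replication of a
typical characterization — with the concentration designs: L-arabinose
{0.02…5} mM (8 points), D-xylose {0.5…40} mM (7 points), pH 5.0–9.0 in 0.5
steps, uptake {0.02…1} mM × 3 technical replicates (2 min, 1.6 OD,
300 cpm/nmol, blank 100 cpm), and the full −150…+50 mV step protocol for
charge movements. Each concentration series brackets its Km by at least an
order of magnitude on both sides. The whole suite simulates and analyzes
~200 sweeps in a few seconds.

## Known limitations

* The biexponential isolation assumes a single carrier relaxation mode;
  transporters with genuinely multi-exponential charge movements need the
  template-subtraction path and a saturating substrate.
* Qmax, V0.5 and z of the packaged preset are back-computed or
  representative (see table); simulated charge movements are
  self-consistent with the published turnover numbers but should not be
  read as measured values.
* The uptake simulator draws an independent Poisson blank per sample;
  correlated blank errors (one shared blank per assay day) are not
  modeled.
* No amplification-efficiency correction in the qPCR module (ΔΔCp/Livak
  only).
* ABF or other proprietary acquisition formats are not parsed; the trace
  dialect is plain CSV.
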