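# Methods

## Cell model

The base cell is the O'Hara–Rudy dynamic (ORd) human *endocardial*
ventricular action-potential model: 41 ODE states covering membrane
voltage, the gating variables of I_Na, I_NaL, I_to, I_CaL (with its Na/K
components), I_Kr, I_Ks and I_K1, CaMKII trapping, and Na/K/Ca in
myoplasm, subspace, NSR and JSR compartments, with SERCA uptake and
calcium-induced calcium release. The equations follow the original ORd
publication and its reference code conventions; the published rounded
resting state is used as the initial condition, and 150 pre-pacing beats
wash out its residual drift (at that rounded state dV/dt ≈ −0.08 mV/ms;
at the paced diastolic state it is < 0.01 mV/ms).

The original ORd fast sodium current is used. Some population studies
substitute an alternative I_Na formulation; since no single substitution
is canonical, `simulate(..., ina_formulation=...)` is the documented swap
point and only `"ord"` ships. Cell type is fixed to endocardial;
epicardial/mid-myocardial variants are out of scope.

Nine maximal conductances/permeabilities (G_Na, G_NaL, G_to, G_Kr, G_Ks,
G_K1, P_Ca — which also scales the Na and K fluxes through the L-type
channel — P_NaK, G_NaCa) accept multiplicative scale factors. Drug block
multiplies the member's scaled conductance, so population variability and
pharmacology compose multiplicatively.

### Pacing and stimulus

1 Hz (cycle length 1000 ms) for 150 beats by default; the last beat is
resampled to a uniform 0.5 ms grid for analysis, and its pre-stimulus
state is kept in the trace metadata. The stimulus is −80 µA/µF for
0.5 ms at each cycle start (the ORd convention; configurable). Every run
starts from the published resting state — no steady-state caching across
scalings — so runs are independent and order-insensitive.

### Integration

Two deterministic integrators:

* **`lsoda`** (default for single simulations) and **`bdf`**: scipy
  adaptive stiff solvers at rtol 1e-5 / atol 1e-7, with a compiled
  forward-difference Jacobian. LSODA switches to BDF in stiff regions and
  serves as the reference.
* **`rl`** (used for population trials): a numba-compiled adaptive hybrid
  stepper — exponential (Rush–Larsen) updates for the 31 gate-like states
  using their analytic (steady-state, time-constant) pairs, forward Euler
  for voltage, concentrations and CaMKII trapping. The step size tracks
  the voltage increment (target 0.1 mV per step, bounds 0.004–0.25 ms)
  and never crosses the stimulus edge or cycle boundary. With these
  controls the last-beat APD90 agrees with tight-tolerance LSODA to
  ~0.5 ms and the peak voltage to <1 mV, at ~5 ms per beat; the test
  suite asserts the cross-validation. Runs abort with a hard error if the
  state becomes non-finite or |V| exceeds 200 mV.

## Population

Candidates scale the nine conductances, sampled by Latin hypercube
(default) or independent uniform draws. Default ranges realize the
low-repolarization-reserve design: I_Kr, I_Ks, I_NaK ∈ [0.1, 1.0];
I_NaL, I_CaL, I_NaCa ∈ [1.0, 2.0]; I_Na, I_to, I_K1 ∈ [0.5, 1.5]. A
degenerate range (low = high) pins the factor. This skew emulates
remodelling seen in long-QT syndrome, hypertrophic cardiomyopathy and
heart failure, making the ensemble a sensitized substrate for drug-induced
abnormalities rather than a representative healthy cohort.

Calibration simulates each candidate drug-free and accepts it only if all
biomarkers fall inside standard human ventricular bands — APD90
∈ [180, 440] ms, APD50 ∈ [110, 350] ms, resting potential ∈ [−95, −80] mV,
peak ∈ [10, 55] mV, triangulation APD90−APD40 ∈ [50, 150] ms — and no EAD
or repolarization failure occurs at baseline. Calibration preserves
candidate order, is idempotent, and raises (suggesting range widening)
when no candidate survives. Populations persist as CSV
(`model_id` + nine `scale_*` columns, fixed 6-decimal formatting so
save→load→save is byte-identical); an externally supplied population
table in the same format drops in directly.

## Drug model and trial

Pore block: the remaining conductance fraction at concentration C is
1/(1 + (C/IC50)^h). Missing potency means no block (multiplier 1.0),
which is also how 3-channel datasets run against the 7-current model.
IC50 and EFTPC_max are both free concentrations in µM; no protein-binding
correction is applied. A helper inverts a single-point block measurement
at h = 1 (IC50 = C·(1−b)/b) for potency tables reporting only percent
block at the highest tested concentration.

Channel subsets restrict which measured blocks are applied: `ALL7`,
`FOUR` (I_Na+I_NaL+I_Kr+I_CaL), `THREE` (I_Na+I_Kr+I_CaL), `HERG_ONLY`.
Default concentration multiples are 1, 3, 10, 30, 100 × EFTPC_max.

`run_trial` simulates every (member, concentration) pair, analyzes the
last beat, and tallies abnormal members per concentration. A failed
simulation is recorded and excluded from both numerator and denominator
for that compound (with a warning) rather than biasing the score; the
result flags such incomplete cells.

## Abnormality detection

* **EAD**: finite-difference dV/dt on the uniform grid exceeds
  0.01 mV/ms over ≥ 2 consecutive samples, at any time later than 150 ms
  after the AP peak and before cycle end. The threshold-plus-persistence
  rule replaces a bare "dV/dt > 0" test, which is fragile on numerical
  output; both constants are module-level and configurable.
* **RF**: the final sample of the cycle is strictly above −40 mV.
* **Delayed-peak guard**: a peak later than 150 ms after stimulus onset
  flags the trace for review. Very weak upstrokes at extreme
  concentrations can delay the voltage maximum, shifting the EAD search
  window and producing spurious calls; the automated call is preserved,
  and "corrected" tallies/scores treat EAD-only calls on flagged traces
  as clean. Both raw and corrected metrics are always reported; raw is
  the default for classification.

The AP peak is the voltage maximum after the stimulus offset; resting
voltage is the sample at stimulus onset; APDx is measured from stimulus
onset to the first post-peak crossing of peak − x%·(peak − rest), and is
reported absent when never crossed (differences vs a dV/dt-max reference
are < 2 ms for captured beats).

## Scoring and evaluation

score = Σ_c(W_c·nRA_c)/(N·Σ_c W_c) with W_c = EFTPC_max/c, evaluated in
exact rational arithmetic so the boundary values 0 and 1 are exact. Risky
⇔ score > 0. Concentration capping drops multiples above the cap and
re-normalizes ΣW_c over the retained ones, keeping the [0, 1]
interpretation (an all-RA compound still scores 1 under a cap); because
of re-normalization individual scores may rise under a cap, but the risky
*set* can only shrink. The 1e-16 floor exists purely for log-scale
plotting and never feeds classification.

ΔAPD90 per compound (for the score–ΔAPD correlation at 1×) aggregates
APD90_drug − APD90_control by the median (configurable to mean) over
members that are abnormality-free with defined APD90 in both conditions;
the correlation is the squared Pearson r, reported absent under zero
variance. Confusion percentages are rounded to integers for table output;
raw fractions are retained.

## Synthetic data

The generator emulates the *structure* of real potency datasets, not
their statistics: archetypes `inactive` (all IC50 ≥ 1000× EFTPC_max),
`pure_herg` (IKr IC50 sweeping margins 0.03–30 × EFTPC_max, h = 1 on the
swept channel so the margin is directly interpretable),
`pure_calcium`, `balanced_multichannel` (matched IKr and ICaL potency
plus weaker I_Na block) and `late_sodium_offset` (IKr plus matched
I_NaL block). EFTPC_max is log-uniform on [0.001, 10] µM; free Hill
coefficients are uniform on [0.5, 2.0] to exercise steepness
sensitivity. Ground truth is by construction: margins ≤ 0.1 make hERG
block near-total at therapeutic dose, inactive compounds never block more
than ~9% anywhere in the tested range.

Analytic trace fixtures (`normal`, `ead_bump`, `rf_plateau`,
`delayed_peak`) are closed-form voltage series so detector unit tests run
in milliseconds with exactly known morphology.

What passing on synthetic data does *not* show: real compounds mix
potencies continuously rather than by archetype, real populations carry
correlated conductance changes, and clinical labels are noisier than
constructed ground truth — so the archetype-level 100% recovery is a
pipeline correctness check, not a clinical accuracy claim. Likewise the
desk-scale score–ΔAPD r² is diluted by APD-shortening calcium-blocker
archetypes at zero score; large real compound panels, which are dominated
by repolarization-prolonging drugs, correlate far more tightly.

## Problem sizes

The fast test suite paces 50 beats and uses a 6-member fixture
population; `scripts/acceptance.py` uses the full 150-beat protocol, an
8-member population, and a 10-compound panel (two per archetype, hERG
margins 0.03 and 0.1), chosen as the package's desk-scale defaults. The
population size and panel breadth are the main knobs for scaling up; a
107-member population with an 85-compound table reproduces a full
study-scale screen at proportional cost (hours, embarrassingly parallel
per compound).

## Known limitations

Single-cell only — no tissue coupling, no electromechanical window, no
β-adrenergic stimulation. Pore block only — no Markov/state-dependent
drug binding, trapping kinetics, or temperature/voltage-dependent IC50.
No metabolite pharmacology. The EAD/RF constants are pragmatic detector
choices, not physiological absolutes; traces near the thresholds warrant
the same visual review the delayed-peak guard formalizes.
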