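# torsim

In-silico drug-trial pipeline for Torsades de Pointes (TdP) risk
assessment on a population of human ventricular cell models.

Drug-induced TdP is a polymorphic ventricular tachycardia and a leading
cause of drug withdrawal. Screening historically focused on hERG (I_Kr)
block alone, which is sensitive but unspecific: block of depolarizing
currents (Cav1.2 / I_CaL, Nav1.5 / I_Na) can offset hERG block and
suppress the cellular trigger. `torsim` implements the CiPA-style
multi-channel alternative for safety pharmacologists and modelers:
simulate each compound's measured channel blocks on a population of cells
that is deliberately prone to repolarization abnormalities, look for those
abnormalities directly, and aggregate them into a single risk score.

## What it computes

**Cell model.** The O'Hara–Rudy dynamic (ORd) human endocardial
action-potential model (41 state variables), with nine maximal
conductances (G_Na, G_NaL, G_to, G_Kr, G_Ks, G_K1, P_Ca, P_NaK, G_NaCa)
exposed as scaling factors. Cells are paced at 1 Hz for 150 beats and the
last beat is analyzed.

**Population.** Members are sampled by Latin-hypercube scaling of the nine
conductances with skewed ranges (weaker I_Kr, I_Ks, I_NaK; stronger
I_NaL, I_CaL, I_NaCa) to lower the repolarization reserve, then calibrated
against human AP biomarker ranges and required to be abnormality-free at
baseline.

**Drug action.** The conductance of each channel with a measured potency
is multiplied by the pore-block factor

    b(C) = 1 / (1 + (C / IC50)^h)

at concentrations C of 1, 3, 10, 30 and 100 × EFTPC_max (the maximal
effective free therapeutic plasma concentration).

**Risk metric.** A repolarization abnormality (RA) is an early
afterdepolarization (sustained dV/dt > 0 later than 150 ms after the AP
peak) or repolarization failure (V_m > −40 mV at the end of the cycle).
With nRA_c members abnormal at concentration c out of N, the TdP risk
score is

    score = Σ_c (W_c · nRA_c) / (N · Σ_c W_c),   W_c = EFTPC_max / c

which lies in [0, 1]; a compound is *risky* exactly when any RA occurred.
Confusion metrics (sensitivity, specificity, PPV, NPV, accuracy) against
clinical labels, concentration-cap comparisons (30× vs 100×), channel
subset comparisons (7 / 4 / 3 / hERG-only channels), and the score vs
ΔAPD90 correlation are provided on top.

## Worked example

```python
from torsim import (PacingProtocol, generate_drug_panel,
                    generate_fixture_population, run_trial)

protocol = PacingProtocol(cycle_length=1000.0, n_beats=150)   # 1 Hz
population = generate_fixture_population(size=4, seed=3, protocol=protocol)

drugs, archetypes = generate_drug_panel(n_per_archetype=1, seed=1)
herg_blocker = next(d for d in drugs if d.compound_name == "pure_herg_m0.1")

result = run_trial(herg_blocker, population, protocol=protocol)
print("compound:       ", result.compound)
print("nRA by multiple:", dict(zip(result.multiples, result.n_ra)))
print("TdP risk score: ", round(result.tdp_score, 4))
print("classification: ", "risky" if result.risky else "safe")
```

prints

```
compound:        pure_herg_m0.1
nRA by multiple: {1.0: 4, 3.0: 4, 10.0: 4, 30.0: 4, 100.0: 4}
TdP risk score:  1.0
classification:  risky
```

The compound is a synthetic pure hERG blocker whose IC50 is one tenth of
its therapeutic concentration, so it blocks ~91% of I_Kr already at 1×:
every member of the abnormality-prone population develops an EAD or fails
to repolarize at every tested dose, giving the maximal score of 1. An
`inactive_*` compound from the same panel scores exactly 0.

The same pipeline runs from the shell (`torsim synth`, `torsim trial`,
`torsim evaluate`, `torsim run --config cfg.yaml`); real potency tables
drop in as CSV (`compound,dataset,EFTPCmax_uM,{channel}_IC50_uM,
{channel}_hill`, blank = unmeasured), populations as
`model_id,scale_INa,...,scale_INaCa`.

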