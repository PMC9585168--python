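# zfcardio

Quantitative cardiac phenotyping of larval zebrafish from fluorescence
time-lapse microscopy, and composite scoring of candidate anti-heart-failure
treatments.

In `Tg(cmlc2:eGFP)` zebrafish larvae the beating heart is fluorescent, so a
short single-channel movie of an anaesthetised fish carries enough
information to quantify cardiac function: the chamber area oscillates once
per beat between end diastole (ED, maximal filling) and end systole (ES,
maximal contraction). `zfcardio` segments the heart in every frame, detects
the cardiac cycles, and computes the standard indicator panel

- heart rate `HR` (beats/min),
- fractional area change `FAC = (EDA − ESA) / EDA`,
- fractional shortening `FS = (Dd − Ds) / Dd` (short axis),
- end-diastolic / end-systolic volumes `EDV`, `ESV` from the
  prolate-spheroid model `V = π a b² / 6` (`a`, `b` = full long/short axis),
- stroke volume `SV = EDV − ESV`,
- ejection fraction `EF = SV / EDV`,
- cardiac output `CO = SV · HR`.

For drug screens against a chemically induced heart-failure model
(verapamil-style depression of rate and contractility), treatment groups are
scored with the **Anti-Heart-Failure Index**. Each indicator is normalized
to the control-group mean, `B = mean_group / mean_control`; the recovery
score per indicator is

```
RCF = (B_treatment − B_model) / (1 − B_model)
```

(0 = no recovery, 1 = fully restored to control), and the composite is the
sum over the four relatively independent components

```
AHFI = RCF_HR + RCF_EF + RCF_CO + RCF_FAC
```

classified as *excellent* (AHFI ≥ 1.0), *active* (≥ 0.6), *atypical*
(< −0.5) or *inactive*.

Because no public recordings accompany this kind of assay, the package
includes a synthetic beating-heart simulator — a periodically contracting
fluorescent ellipse with PSF blur and noise, plus cohort designs with known
ground truth — so the entire measurement chain is validated against
closed-form answers.

## Worked example

```python
from zfcardio import *

# simulate a small screen: control, verapamil-like model, one treatment
# that restores 70% of the induced deficit
spec = CohortSpec(
    n_per_group=5,
    groups={
        "control": GroupEffectSpec(),
        "model": DEFAULT_MODEL_EFFECT,           # HR x0.6, contraction x0.4
        "drug_A": GroupEffectSpec(recovery=0.7),
    },
    seed=42, inter_fish_cv=0.05)
write_cohort(generate_cohort(spec), "demo/data")

tables = run_pipeline(PipelineConfig(input_dir="demo/data",
                                     output_dir="demo/out"))
print(tables["group_summary"][["group", "n", "hr_bpm_mean", "hr_bpm_sd",
                               "ef_mean", "fac_mean"]].round(3).to_string(index=False))
print(tables["ahfi"].round(3).to_string(index=False))
```

prints

```
  group  n  hr_bpm_mean  hr_bpm_sd  ef_mean  fac_mean
control  5      150.270      7.966    0.591     0.409
  model  5       91.539      4.331    0.274     0.174
 drug_A  5      131.075      8.445    0.504     0.340

 group  ahfi     class  valid  rcf_hr  rcf_ef  rcf_co  rcf_fac
drug_A 2.812 excellent   True   0.673   0.726   0.708    0.704
```

The model group shows the induced phenotype (HR 150 → 92 bpm, EF 0.59 →
0.27); the treatment recovers roughly 70% of each deficit — matching the
simulated recovery fraction — and sums to AHFI ≈ 2.8, class *excellent*.
Fractions are stored dimensionless; multiply by 100 for percent display.

The same workflow is available from the shell:

```
zfcardio simulate --out data --n-per-group 5 --seed 42 --recovery-grid 0.7
zfcardio validate --input-dir data
zfcardio run --input-dir data --out results
```

`run` writes per-fish geometry, cycle and indicator tables, group summaries
with mean ± SD, pairwise t-tests and one-way ANOVA, the AHFI report
(CSV + JSON) and a run log with the configuration hash.

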