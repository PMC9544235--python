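# lungdce

Quantitative DCE-MRI measurement of pulmonary congestion — extravascular
lung water is a central, hard-to-measure quantity in heart failure, and this
package implements a full measurement chain for it: variable-flip-angle
(VFA) T1/S0 mapping, voxel-wise extended Tofts pharmacokinetic modeling
with a hematocrit-corrected pulmonary-artery input function, the
muscle-normalized lung-water indices qS0 and qS0·ve, regional endpoint
extraction, and the repeated-measures statistics for group comparison and
scan-rescan repeatability. A synthetic digital lung phantom with known
ground truth makes every stage verifiable without patient data.

It is written for imaging scientists and methodologists who need a tested,
reproducible reference implementation of this pipeline — to validate
processing choices, power simulations, or teach the method.

## Model

Signal follows the spoiled gradient echo steady state
`S = S0 sinα (1−E1)/(1−E1 cosα)`, `E1 = exp(−TR/T1)`; T1 and S0 come from a
DESPOT1-seeded bounded fit over the VFA angles. Dynamic signal is inverted
to concentration via `1/T1(t) = 1/T10 + r1 C(t)`, and tissue concentration
follows the extended Tofts model

    Ct(t) = vp Cp(t) + Ktrans ∫₀ᵗ Cp(τ) e^(−Ktrans (t−τ)/ve) dτ

with the plasma input `Cp = Cb/(1−Hct)` measured in the pulmonary artery.
`qS0` is lung S0 normalized per slice to a skeletal-muscle reference;
`qS0·ve` indexes extravascular extracellular water. Repeatability is the
within-subject `CV% = 100·√(exp(MSE)−1)` from a mixed model on log values.
See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

Simulate a two-group phantom study (3 healthy-volunteer-like and 3
heart-failure-like subjects, 3 sessions each) and run the whole chain:

```python
from lungdce import PipelineConfig, run_pipeline

cfg = PipelineConfig(shape=(20, 20, 10), n_hv=3, n_hf=3, n_sessions=3, seed=8,
                     regime_overrides={"hf": {"ktrans_median": 0.25}})
results = run_pipeline(cfg, out_dir="phantom_run")
print(results["report"])
```

The report (excerpt, seed 8) shows the measured group contrasts:

```
== ve contrasts (total lung) ==
  HF-HV @ session 1: +0.1624 (95% CI +0.1584, +0.1664), p=0.000, n=6
  HF-HV @ session 2: +0.1625 (95% CI +0.1585, +0.1665), p=0.000, n=6
  HF-HV @ session 3: +0.1609 (95% CI +0.1569, +0.1649), p=0.000, n=6
== ktrans contrasts (total lung) ==
  HF-HV @ session 1: -0.0000 (95% CI -0.0046, +0.0046), p=0.988, n=6
  HF-HV @ session 2: -0.0009 (95% CI -0.0055, +0.0037), p=0.616, n=6
```

The HF-like group was generated with interstitial volume fraction
ve ≈ 0.49 vs 0.33 for the HV-like group and identical Ktrans regimes: the
pipeline recovers a ve separation close to the configured 0.16 at every
session while the Ktrans contrast is statistically indistinguishable from
zero — the behavior a congestion-sensitive, perfusion-insensitive endpoint
should show. `phantom_run/` also contains the tidy endpoint table
(`endpoints.csv`), per-endpoint contrast tables and within-subject CVs.

The same stages are scriptable from the shell:

```bash
lungdce simulate --group hf --shape 32,32,16 --seed 1 --out sim/
lungdce fit-t1  --vfa sim/vfa.nii.gz --protocol sim/protocol.yaml --out t1/
lungdce fit-dce --dyn sim/dyn.nii.gz --t1 t1/ --aif-roi sim/mask_vessel.nii.gz \
                --hct 0.42 --protocol sim/protocol.yaml --out dce/
lungdce run-all --seed 8 --out study/
```

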