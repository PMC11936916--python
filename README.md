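# pccvr

Whole-brain cerebral blood flow (CBF) from phase-contrast (PC) MRI velocity
data, and cerebrovascular reactivity (CVR) to hypoxia and hypercapnia — with
a seeded synthetic cohort generator so the entire pipeline is testable
end-to-end without any imaging data.

## Who this is for

Physiological-MRI groups quantifying whole-brain blood flow from cine PC
acquisitions of the internal carotid (ICA) and vertebral (VA) arteries while
a computer-controlled gas blender drives a 4-phase respiratory protocol
(baseline → hypoxia → recovery baseline → hypercapnia), and asking how
reliable the resulting reactivity metrics are across repeat sessions.

## The model

Per acquisition, each vessel's flow is mean velocity × cross-sectional area,
averaged over 8 cardiac bins after background phase correction against
static tissue. The four vessels sum to total CBF (mL/min), normalized by
brain mass (volume × 1.06 g/mL) to nCBF in mL/100 g/min. Reactivity per
session:

    CVR_HC        = 100 · (CBF_HC − CBF_BL) / CBF_BL / (PETCO2_HC − PETCO2_BL)   [%/mmHg]
    CVR_HX,PETO2  = −100 · (CBF_HX − CBF_BL) / CBF_BL / (PETO2_HX − PETO2_BL)    [%/−mmHg]
    CVR_HX,SpO2   = −100 · (CBF_HX − CBF_BL) / CBF_BL / (SpO2_HX − SpO2_BL)      [%/−%]

Because CO2 clamping during hypoxia is imperfect, the hypoxic nCBF change is
additionally re-computed with the CO2-attributable part removed, using the
same session's hypercapnic CVR:

    Δcorrected = Δ − nCBF_BL · (CVR_HC/100) · ΔPETCO2(HX−BL)

Two further rules from the acquisition design: vertebral flows measured at
the carotid-optimized slice placement are replaced by the second placement's
values whenever placement 2 exceeds the group-regression prediction by more
than 1.96 residual SDs (a non-orthogonal slice under-reads flow); and nCBF
changes smaller than the median absolute difference between back-to-back
scans (~2 mL/100 g/min) are classified as *minimal* rather than real.

Reliability is summarized by one-way random-effects ICCs (single- and
average-measures), inter-subject vs inter-session variance components,
exact paired Wilcoxon tests, and random-intercept mixed-model R² between
the hypercapnic and hypoxic metrics.

## Worked example

```
$ python analysis/01_simulate.py
wrote 21 subjects x 3 sessions (882 acquisitions) to .../scratch/study
  typical responders: 14
  minimal responders: 5
  paradoxical responders: 2
$ python analysis/02_quantify.py
$ python analysis/03_cvr_analysis.py
analyzed 63 sessions; meaningful-change threshold 2.09 mL/100 g/min; 12 vertebral substitutions
mean nCBF change: hypercapnia +26.1%, hypoxia +3.5%
hypoxic response classes: {'increase': 32, 'decrease': 16, 'minimal': 15}
$ python analysis/04_reliability.py
ICC (average-measures, published style):
  cvr_hc: 0.49
  ...
P_ET_CO2 vs hypoxic dnCBF (uncorrected): r = 0.33, p = 0.009
P_ET_CO2 vs hypoxic dnCBF (corrected): r = 0.02, p = 0.897
```

Reading this: the back-to-back threshold (2.09) matches its calibration
target of ~2 mL/100 g/min; hypercapnia raises nCBF strongly and hypoxia
weakly, with a sizeable minority of sessions showing minimal or paradoxical
(negative) hypoxic responses; the unintentional CO2 changes during hypoxia
correlate with hypoxic flow changes (r = 0.33) until the CVR_HC-based
correction removes that confound (r = 0.02, non-significant).

The same pipeline runs from a shell via the `pccvr` console script
(`simulate | quantify | analyze | report`), e.g.

```
pccvr simulate --seed 1 --out study/ && pccvr analyze study/
```

Real data can be analyzed by laying out the same CSV tables the simulator
writes (`physio_<subject>_<session>.csv`, `acquisitions.csv`, `anatomy.csv`)
or NIfTI cines plus label masks for image-level input.

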