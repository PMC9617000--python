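# neurovasc

Quantitative neurovascular MRI analysis for ageing-cohort studies: how
well does the brain's vasculature respond when it is asked to — by
neuronal activity, and by CO₂?

Cerebrovascular dysfunction appears early in neurodegeneration, so a
cohort study of older adults typically measures, per subject:

- **ΔCBF_VisAct / ΔBOLD_VisAct** — the percent cerebral-blood-flow and
  BOLD response in the maximally activated visual cortex during a block
  visual-stimulation paradigm, from a dual-echo pseudo-continuous
  arterial spin labelling (pCASL) series;
- **gCBF** — resting global CBF from phase-contrast velocity maps of the
  feeding arteries, normalized to brain weight (density 1.05 g/ml);
- **SvO₂ and gCMRO₂** — venous oxygen saturation in the sagittal sinus
  from susceptibility-based oximetry, and the global metabolic rate of
  oxygen via the Fick principle,
  `gCMRO₂ = [Hgb] · gCBF · (SaO₂ − SvO₂)`;
- **ΔCBF_BH / ΔCMRO₂_BH** — cerebrovascular reactivity to a breath-hold
  challenge (two 36-s holds), from simultaneous sagittal-sinus flow and
  oximetry series;
- **ΔLac** — the activation-induced lactate change from long-TE MR
  spectra of the visual cortex;
- cohort statistics: robust (Tukey-bisquare IRLS) regressions of
  cognition on the physiology estimates, Benjamini–Hochberg FDR at
  q = 0.05, stepwise health-covariate models, and attrition accounting.

`neurovasc` implements this whole chain as a tested library plus CLI,
together with a **synthetic cohort generator**: phantom imaging series,
vessel maps, phase maps, spectra and cognition tables with known ground
truth, drawn from realistic population distributions. Every estimator is
validated by round trip against that generator — exactly in the
noise-free limit, statistically under study-like noise.

## The activation estimator in brief

The pCASL series (TR 4550 ms, 54 label/control pairs) is split into a
perfusion-weighted series (pairwise control − label, effective TR 9.1 s)
and a BOLD series (non-labelled second-echo volumes). After 5-mm Gaussian
smoothing and 90-s high-pass filtering, each voxel's percent-normalized
BOLD series is regressed on the block paradigm convolved with a gamma
HRF (mean lag 6 s, SD 3 s). The ROI is the upper 10th z-percentile of the
largest 26-connected cluster above z = 3.1; ΔBOLD is the mean β there and
ΔCBF the GLM coefficient of the ROI-median percent CBF series. Subjects
with no cluster, no significant CBF response (p ≥ 0.05), or a response
above 400 % are excluded, mirroring the attrition rules of such studies.

## Worked example

```python
from neurovasc.synthetic import CohortConfig, generate_cohort
from neurovasc import asl

cohort = generate_cohort(CohortConfig(n_subjects=1, random_seed=7))
truth = cohort.subject_truth(0)
series = cohort.pcasl_series(0)          # dual-echo pCASL, study-like noise
result = asl.analyze_subject(series)     # full GLM + ROI + response chain
included, reason = asl.qc_filter(result)
print(f"true dCBF  = {truth.true_dcbf_visact:.1f} %")
print(f"est. dCBF  = {result.delta_cbf:.1f} %   (p = {result.cbf_p_value:.2e})")
print(f"est. dBOLD = {result.delta_bold:.2f} %")
print(f"ROI size   = {result.cluster_size} voxels, QC = {reason}")
```

prints

```
true dCBF  = 77.1 %
est. dCBF  = 65.7 %   (p = 1.40e-18)
est. dBOLD = 2.19 %
ROI size   = 55 voxels, QC = ok
```

This subject's true visual-activation CBF response happens to be 77.1 %;
the single-subject estimate (65.7 %) is within the per-subject noise of
the method, is highly significant, and passes QC. Cohort means are
unbiased — see the acceptance script below.

A full run (simulate → per-subject quantification → cohort statistics)
is one call:

```bash
neurovasc run-all --out runs/demo --seed 1
```

which writes the resolved configuration, per-subject estimates with QC
status, the attrition ledger, the robust correlation table with FDR, a
truth-vs-estimate recovery report, and a checksummed manifest. The other
subcommands (`simulate`, `asl`, `flow`, `oximetry`, `bh`, `mrs`,
`stats`) operate on NIfTI/CSV files for stage-by-stage use.

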