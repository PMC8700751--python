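# dopplerquant

Quantification of color-Doppler cine loops for differentiating solid
pancreatic lesions: malignant tumors are hypovascular and show lower,
more pulsatile flow than inflammatory masses.  The package implements the
two complementary measurement families used in endoscopic-ultrasound
Doppler studies, the statistics that turn them into a diagnostic test,
and a calibrated synthetic cine generator so that the whole pipeline is
testable without patient data.

**Dynamic tissue perfusion measurement (DTPM)** reduces every frame of a
color-Doppler cine to the perfused pixels inside a region of interest
(ROI) and averages over complete cardiac cycles:

- TFV (tissue flow velocity, cm/s) — time average of the mean velocity
  magnitude over perfused ROI pixels,
- TRI (tissue resistive index) — (v_max − v_min)/v_max of the mean-velocity
  trace per cardiac cycle; TRI = 1 means diastolic no-flow,
- TPI (tissue perfusion intensity, cm/s) — time average of
  mean velocity × vascular area / ROI area.

**Single vessel flow measurement (SVFM)** segments the largest vessel with
a consistent flow direction, estimates its axis by principal components,
and corrects the per-frame envelope velocity by 1/cos θ of the Doppler
angle (flagged invalid above 60°, where the correction falsifies results):

- FV (cm/s) — time-averaged corrected velocity,
- RI — (PSV − EDV)/PSV over cardiac cycles,
- VolF (mL/s) — FV × π(d/2)² with d the lumen diameter.

**Cohort statistics**: Shapiro–Wilk-gated Welch t-test / Mann–Whitney U
group comparisons, ROC analysis with the concordance (Mann–Whitney) AUC,
Youden-optimal "nadir" cut-offs with sensitivity/specificity/accuracy,
and DeLong's paired test for comparing the AUCs of two parameters
measured on the same cases.

## Worked example

```sh
python examples/04_cohort_statistics.py
```

draws a cohort of 40 malignant / 29 inflammatory cases from the
calibrated parameter distributions and prints, among others:

```
parameter  nadir  sensitivity  specificity   acc   auc          direction
      tfv  1.512        0.700        0.897 0.783 0.863  lower-is-malignant
      tpi  0.007        0.825        0.897 0.855 0.930  lower-is-malignant
       fv  2.018        0.775        0.931 0.841 0.839  lower-is-malignant
```

Reading: a lesion with TPI below ~0.007 cm/s is classified malignant; at
that cut-off 82.5% of malignant and 89.7% of inflammatory cases are
called correctly, and the AUC of 0.93 summarizes discrimination across
all cut-offs.  Tissue-perfusion parameters (TFV/TPI) discriminate better
than their single-vessel counterparts, which is the clinical message the
pipeline reproduces.

The other examples render single synthetic cines and walk through
decoding, perfusion traces, and vessel geometry; `examples/01_*` writes a
small cohort you can re-read with `read_cine`.

A thin CLI wraps the same functions:

```sh
dopplerquant all --n-malignant 40 --n-inflammatory 29 --seed 1 --workdir run1
```

simulates a cohort, analyzes every case, and writes `dtpm_results.csv`,
`svfm_results.csv`, `table1.csv`, `table2.csv`, `auc_comparisons.csv`,
`roc_curves.json` and a run log.

## Layout

- `src/dopplerquant/cine.py` — cine container and lossless case I/O
- `src/dopplerquant/codec.py` — colorbar LUT, RGB↔velocity codec
- `src/dopplerquant/dtpm.py` — perfusion traces, cardiac cycles, TFV/TRI/TPI
- `src/dopplerquant/svfm.py` — vessel segmentation, angle correction, FV/RI/VolF
- `src/dopplerquant/stats.py` — group tests, ROC, DeLong comparison
- `src/dopplerquant/synthetic.py` — calibrated cohort and cine generator
- `src/dopplerquant/pipeline.py`, `cli.py` — orchestration and CLI
- `docs/methods.md` — model assumptions, parameter choices, limitations
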