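# scmwpls

Moving-window PLS wavelength selection and calibration for NIR monitoring
of fermentations.

## What this is for

A chemometrician monitoring a fruit-wine fermentation by FT-NIR wants to
predict four chemical parameters — ethanol (%), total soluble solids
(°Brix), total acidity (% citric acid) and total volatile acids (% acetic
acid) — from absorbance spectra on the 11,536–3,952 cm⁻¹ axis.  Most of
that axis is water background, detector-noise-dominated third overtones, or
a saturated water band; the analyte information sits in a handful of
overtone and combination windows.  This package finds those windows and
builds validated PLS-1 calibrations on them:

* **MWPLSR** — a 20-channel window slides over the (second-derivative
  pretreated) spectrum; at each position PLS-1 models with k = 1..10 latent
  variables are fitted and log₁₀(SSR) of the calibration residues
  (Eq. SSRᵢ = (y − Xᵢb̂ᵢ)ᵀ(y − Xᵢb̂ᵢ)) is plotted per position.  Valleys of
  these *residue lines* mark informative regions.
* **SCMWPLS** — within each informative region every sub-interval is fitted
  exhaustively; the best one seeds a *base region*, which then greedily
  absorbs the best sub-interval (possibly none) of every further region,
  minimizing RMSEC under a constrained LV count.
* **Validation** — R², RMSEC/RMSEP, SEP, bias, RPD = SD/RMSEP, and the
  ISO-12099-style confidence limits T_b = t₁₋α/₂ · SEP/√n and
  T_UE = SEC·√F_α(ν, M); a model is accepted when SEP < T_UE and
  |bias| < T_b.

Because no public dataset of this kind exists, the package ships a
synthetic fermentation generator (Beer–Lambert Gaussian band mixtures over
tabulated concentration kinetics, with baseline/scatter/detector artefacts
and a saturating water band) that reproduces the full two-batch-calibration
(n = 198) / one-batch-test (n = 99) study design with known ground truth.
See `docs/methods.md` for the model details and its limits.

## Worked example

```python
from scmwpls import make_study_dataset, run_analysis, AnalysisConfig

(cal, cal_refs), (test, test_refs), truth = make_study_dataset(seed=1)
result = run_analysis(cal, cal_refs, test, test_refs, "ethanol",
                      AnalysisConfig())
print("optimized regions:", result.scmwpls.optimized_regions)
print(result.report.to_text())
```

prints

```
optimized regions: 8520-8360, 6920-6600, 6104-5504, 4640-4136
analyte                ethanol
LVs                    2
n (calibration)        198
n (test)               99
n (confidence limits)  33
R^2 (test)             0.9933
RMSEC                  0.275
RMSEP                  0.2958
SEP                    0.2968
bias                   -0.01865
RPD                    12.2
T_b                    +/-0.1052
T_UE                   0.338
SEP verdict            accepted
bias verdict           accepted
```

The four selected regions (202 channels of the 903 usable ones) are the
ethanol C–H second overtone, O–H first overtone, C–H first overtone and
combination windows — they overlap the generator's planted ethanol bands —
and the selected-region model predicts the independent test batch better
than the whole-region model built on the same data (RMSEP 0.296 vs 0.354 %
ethanol, RPD 12.2 vs 10.2).  Both SEP and |bias| fall inside their
confidence limits, so the calibration is accepted.  The confidence limits
use n = 33 because the 99 test spectra are triplicate subsamples of 33
sampling events.

The same workflow is available from the shell:

```sh
scmwpls simulate --seed 1 --out data/
scmwpls mwplsr  --analyte ethanol --spectra data/calibration_spectra.csv \
                --references data/calibration_references.csv --out residues.csv
scmwpls scmwpls --analyte ethanol --spectra data/calibration_spectra.csv \
                --references data/calibration_references.csv --out regions.txt
scmwpls report  --seed 1 --analytes ethanol,tss --out comparison.csv
```

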