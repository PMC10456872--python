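# barogeo

Geometric and statistical characterization of baroreflex-mediated
cardiorespiratory variability, with kernel-SVM classification of subject
groups.

## The problem

The baroreflex couples blood pressure, heart period and respiration:
when arterial pressure changes, heart period and breathing adapt.  In
cardiomyopathies this regulation degrades in etiology-specific ways —
dilated-cardiomyopathy (DCM) patients show an altered respiratory
response when systolic pressure falls, while ischemic-cardiomyopathy
(ICM) patients keep a more stable cardiorespiratory pattern.  `barogeo`
quantifies these interactions from noninvasive recordings (ECG,
continuous blood pressure, respiratory flow) and asks whether the
resulting indices separate patient groups.

The method:

1. **Event series.**  Beat-to-beat intervals BBI (ms, from R peaks),
   per-beat systolic/diastolic pressures SBP/DBP (mmHg), and breath
   cycle times TT (s) are extracted, edited with a 3·SD outlier rule,
   interpolated to a common 1 Hz grid and decimated to 0.25 Hz.
2. **Δ-series and sub-spaces.**  First differences ΔX_n = X_{n+1} − X_n
   are z-scored per subject.  A vascular driver (ΔSBP or ΔDBP) is split
   at the threshold `Th = α·(max ΔXv − min ΔXv)/2` (α = 0.15) into
   *up* (ΔXv > Th), *no change* (|ΔXv| ≤ Th) and *down* (ΔXv < −Th)
   sub-spaces — rising, stable and falling pressure.
3. **Indices.**  For each driver × sub-space, the (ΔBBI, ΔTT)
   scatterplot is summarised by a 95%-containment convex polygon: its
   shoelace area and centroid

   ```
   A  = ½ |Σᵢ (V_{x,i} V_{y,i+1} − V_{x,i+1} V_{y,i})|
   Cx = 1/(6A) Σᵢ (V_{x,i} + V_{x,i+1})(V_{x,i} V_{y,i+1} − V_{x,i+1} V_{y,i})
   ```

   plus the centroid-fan triangles (areas Ar, occupancies pr, angles β
   at the centroid and θ at the vertices), together with descriptive
   statistics (mean, SD, kurtosis, skewness, IQR, CV), occupancy
   probability and mean deviation of ΔBBI and ΔTT.  The fixed inventory
   is **168 named indices per subject**.
4. **Screening + classification.**  Indices are screened by a two-sided
   Mann–Whitney U test (p ≤ 0.05); low-correlation significant pairs
   feed soft-margin SVMs with Gaussian `exp(−‖x−y‖²/2σ²)`, Laplace
   `exp(−‖x−y‖/σ)` and ANOVA `[Σₖ exp(−σ(xₖ−yₖ)²)]^d` kernels,
   validated by leave-one-out cross-validation (LOOCV) and reported as
   accuracy / sensitivity / specificity.

Because clinical recordings of this kind are access-restricted, the
package ships a first-class synthetic generator
(`barogeo.simulate`) producing coupled beat/breath/pressure series —
and optionally raw waveforms — with known ground truth and
group-specific effect sizes, so the whole pipeline is testable end to
end.

## Worked example

`examples/synthetic_cohort.yaml` defines a 12 + 12 cohort in which the
"DCM" group has a 2-SD depressed respiratory response to falling SBP
and 2-SD altered baroreflex coupling:

```sh
barogeo run --config examples/synthetic_cohort.yaml --out run/
```

prints (abridged):

```
Comparison DCM vs. CON   (positive class: DCM, mode: honest)
  feature pair : DBP-∆BBICV-d  +  DBP-∆BBId-nc
  kernel       : gaussian  (C=10, sigma=2)
  LOOCV        : Acc 91.7%  Sn 91.7%  Sp 91.7%
  confusion    : TP 11  FN 1  TN 11  FP 1

Significant indices (Mann-Whitney p <= 0.05):
                  mean_DCM   sd_DCM  mean_CON   sd_CON  p_value  significant
index
SBP-∆BBIm-u         0.6927   0.0776    0.3919   0.0629   0.0000         True
...
DBP-∆TTm-d         -0.1808   0.1034   -0.0063   0.0948   0.0006         True
SBP-∆TTm-d         -0.1631   0.1128   -0.0030   0.0963   0.0017         True
...
```

Reading it: the injected contrasts surface exactly where the method
looks for them — `SBP-∆TTm-d` (mean normalized ΔTT while systolic
pressure falls) is clearly negative in the DCM-like group and near zero
in controls, and the conditional cardiac-variability indices in the
no-change band separate the groups.  The honest-mode LOOCV (screening
and model selection repeated inside every training fold) classifies 22
of 24 subjects correctly.

Index names follow `{driver}-∆{series}{stat}-{subspace}`:
`SBP-∆TTm-d` = mean of ΔTT in the *down* sub-space of the ΔSBP
partition; joint polygon indices use `∆BBI_TT`, e.g. `SBP-∆BBI_TTA-u`
is the polygon area in the *up* sub-space.

The same stages are available as `barogeo simulate`, `barogeo extract`,
`barogeo features` and `barogeo classify`, and as library calls
(`SubspaceClassifier(...).fit().summary()`, `PolygonModel.fit(points)`).

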