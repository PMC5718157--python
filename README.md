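# dopplerwss

Quantitative wall shear stress (WSS) analysis of color Doppler ultrasound,
with the cohort statistics used to relate low WSS to early atherosclerosis.

## The problem

Atherosclerosis preferentially develops where the blood exerts low or
disturbed shear on the endothelium, and the drop in wall shear stress
precedes the wall thickening (intima-media thickness, IMT) that clinical
ultrasound usually measures. Estimating WSS directly from routine color
Doppler frames therefore offers an earlier, noninvasive disease marker.
`dopplerwss` implements that estimation chain for longitudinal vessel
scans, plus the group-comparison and ROC-threshold statistics of a
diet-induced rabbit atherosclerosis study design.

## The estimator

A color Doppler frame renders the lumen as chromatic pixels (brightness
increasing with speed), the vessel wall as grayscale pixels (velocity zero
by definition), and the rest as dark background. The pipeline:

1. **Classify** pixels into flow / wall-gray / background with two 8-bit
   thresholds (chroma > 20 → flow; else max channel ≥ 40 → wall).
2. **Decode** each flow pixel by nearest-neighbor inversion of the color
   lookup table, scaled by the Nyquist velocity (the scanner's Doppler
   speed range), into signed axial velocity in cm/s.
3. **Rotate** the decoded velocity field (not the colors) so the vessel is
   horizontal, using the principal axis of the flow-pixel cloud or a fixed
   angle, and optionally crop a region of interest.
4. **Segment** per image column the grayscale wall pixels bounding the
   longest contiguous flow run.
5. **Differentiate** near the wall: with V_slow the speed at the
   wall-adjacent flow pixel, V_fast the speed one radial layer (d cm)
   inward,

       γ_w = du/dr ≈ (V_fast − V_slow) / d        [1/s]
       τ_w = μ γ_w                                [dyne/cm²]

   with μ the dynamic viscosity (default 0.03 poise = 3 cP, whole blood).
6. **Aggregate** into per-column WSS maps, a column × frame surface, and
   spatial/temporal means.

For steady laminar (Hagen–Poiseuille) tube flow with parabolic profile
u(r) = u_M (1 − r²/R²), the analytic references

    τ_w = 4 μ Q / (π R³) = 2 μ u_M / R

are provided and used as ground truth: a built-in phantom generator renders
Poiseuille flow through any color LUT with known wall rows and known
analytic stress, so the entire pipeline is verifiable against a closed form.

The statistics layer provides Welch's unequal-variance t-test, empirical
ROC curves whose AUC is exactly the Mann–Whitney statistic, fixed-threshold
sensitivity/specificity (low score = diseased by default, since WSS falls
with disease), and Youden-index threshold selection. A cohort simulator
draws per-animal weekly WSS/IMT/lipid measurements from published per-week
group summaries with a biweekly sacrifice schedule and histology stage
labels (fatty streaks from week 6, fibrous plaques from week 8, dense
fibrous plaques at week 10).

## Worked example

```python
import dopplerwss as dw

cmap = dw.load_colormap("red-blue-fine")
spec = dw.PhantomSpec()          # u_M=20 cm/s, R=0.3 cm, 30 um pixels
frame, truth = dw.generate_poiseuille_frame(spec, cmap)

res = dw.WallShearStress(frame, colormap=cmap, mu=0.03).fit(angle=0.0)
print(res.summary())
```

```
Wall Shear Stress Estimation
==============================================
Frames analyzed                              1
Retained columns                           128
Viscosity mu (poise)                    0.0300
----------------------------------------------
Mean WSS (dyne/cm2)                     3.9520
SE of mean                              0.0000
Max WSS (dyne/cm2)                      3.9520
Mean WSS, upper wall                    3.9520
Mean WSS, lower wall                    3.9520
----------------------------------------------
Flow pixels decoded                      25600
Unmatched flow pixels                        0
Aliasing suspected                       False
==============================================
```

The analytic wall stress for this phantom is 2·μ·u_M/R = 4.0 dyne/cm²; the
pipeline recovers 3.952, a 1.2% low bias that is exactly the (1 − d/R)
discretization factor of the one-sided two-layer difference at d = R/100.
The zero standard error and equal upper/lower means reflect the noise-free,
symmetric phantom. Estimates on real frames carry decode quantization,
speckle and segmentation noise on top of this bias (see `docs/methods.md`).

The same analysis is scriptable from a shell:

```sh
dopplerwss simulate phantom --seed 0 --out phantom.png
dopplerwss wss --frame phantom.png --v-nyquist 25 \
    --spacing-axial 0.003 --spacing-lateral 0.003 --angle 0 \
    --out-map map.csv --out-summary summary.json
dopplerwss simulate cohort --seed 1 --out cohort.csv
dopplerwss ttest --cohort cohort.csv --var wss --week 1
dopplerwss roc --cohort cohort.csv --score wss --threshold 1.198
```

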