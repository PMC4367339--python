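# odorblend

Modelling the perceived intensity of binary odor mixtures from chemistry
alone.

Environmental odor assessment relies on human sensory panels: assessors rate
an air sample's odor intensity (OI) against the ASTM odor intensity
referencing scale (OIRS, 1-butanol standards, levels 1–8, half-steps
allowed). Panels are expensive, and mixtures defeat simple additivity —
components suppress or reinforce each other. `odorblend` implements a
partial-quantity treatment of this interaction for two-component mixtures,
aimed at practitioners who have GC-quantified component concentrations and
odor detection thresholds and want a panel-free OI estimate, plus the
simulation tools to test the whole pipeline.

## The model

For component *i* at concentration *Cᵢ* with detection threshold *C*<sub>thr,*i*</sub>,
the odor activity value is OAV*ᵢ* = *Cᵢ*/*C*<sub>thr,*i*</sub>; its natural
log, lnOAV, plays the role mole number plays in partial molar volume
analysis (individual odorants respond linearly in lnOAV on the OIRS scale).
A binary sample with measured intensity OI maps to

- mixing proportion  *x* = lnOAV<sub>a</sub> / (lnOAV<sub>a</sub> + lnOAV<sub>b</sub>),
- per-unit intensity  OI<sub>m</sub> = OI / (lnOAV<sub>a</sub> + lnOAV<sub>b</sub>),

and a quadratic *y* = *f*(*x*) is fitted to the (x, OI_m) points of a
24-sample design. The tangent to *f* at a sample's *x*, evaluated at *x* = 1
and *x* = 0, gives the **partial odor intensities** OI<sub>a,m</sub> and
OI<sub>b,m</sub> — the marginal OI contributed per lnOAV unit of each
component — and the mixture intensity follows the summation rule

OI = OI<sub>a,m</sub>·lnOAV<sub>a</sub> + OI<sub>b,m</sub>·lnOAV<sub>b</sub>.

A pooled "extended" curve for binary aldehyde mixtures,
*y* = 2.20*x*² − 2.20*x* + 1.32, ships with the package together with the
odorant threshold table and a 21-sample validation set. A sensory-panel
simulator (half-step-grid ratings, Gaussian assessor noise, the 24-sample
three-band design) makes every stage testable without assessors.

## Worked example

```python
import odorblend as ob

model = ob.extended_model()              # y = 2.20x² − 2.20x + 1.32
rec = ob.predict_oi(model, 2.18, 0.56)   # component lnOAVs
print(rec.partials.oi_a_m, rec.partials.oi_b_m, rec.oi_pre)
```

prints

```
1.22810378816133 -0.07262613884596947 2.636595620437957
```

The sample sits at x = 2.18/2.74 ≈ 0.796; each lnOAV unit of component *a*
contributes 1.23 OIRS units while component *b*'s contribution is slightly
negative (hypo-additive suppression). The predicted mixture intensity, 2.6
at report precision, compares with a panel-measured 2.3 — a predictive
coefficient of 2.6/2.3 ≈ 1.13. Over the packaged validation set the mean
predictive coefficient is 1.03 on the three calibration aldehyde pairs and
0.93 on four further aldehyde pairs.

The same pipeline from the shell:

```
odorblend extended -o ext.json
odorblend partials ext.json 0.3
# x = 0.3000  OI_a,m = 0.2420  OI_b,m = 1.1220
odorblend simulate --seed 7 -o samples.csv       # synthetic 24-sample panel study
odorblend fit samples.csv -o fitted.json
odorblend evaluate ext.json samples.csv -o eval.csv
```

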