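# petki

Regional Patlak quantification of the FDG influx rate constant
**K<sub>i</sub>** for dynamic PET, including a **short two-acquisition
protocol** that replaces the standard 60-minute dynamic scan with a
0–10-min and a 40–60-min acquisition plus a single 45-min venous blood
sample.

## Who this is for

Nuclear-medicine physicists and kinetic-modelling researchers who want
to quantify tumor glucose influx (e.g. in non-small-cell lung cancer)
without occupying a scanner for a full hour per patient, and who need
the supporting machinery — image-derived input functions (IDIF),
population input-function models, VOI extraction, method-comparison
statistics and a ground-truth simulator — in one tested package.

## The model

For an irreversible tracer like FDG, the Patlak plot

```
C_T(t) / C_p(t)  =  Ki · [ ∫₀ᵗ C_p(u) du / C_p(t) ]  +  V_D
```

becomes linear once the free compartment equilibrates; the slope is
the net influx rate constant **K<sub>i</sub>** (min⁻¹) and the
intercept the distribution volume **V<sub>D</sub>**. `petki` fits this
line by OLS over the tissue frames with mid-times 12.5–57.5 min
(standard protocol) or over five points — the 5–10-min frame plus the
four 40–60-min frames (short protocol, **K<sub>i,s</sub>**).

The short protocol needs the plasma curve it never measured between 10
and 40 min. The aortic input-function tail follows a monoexponential

```
C_p(t) = a + b · e^(−c·t)        (10–60 min)
```

with population coefficients (defaults `a = 9.684`, `b = 16.410`
kBq/ml, `c = 0.068` min⁻¹). The hybrid input is the measured 0–10-min
IDIF continued by this tail, and the whole curve is rescaled by one
factor so it passes through the plasma activity measured in the 45-min
venous sample — also sidestepping partial-volume bias in the aorta
VOI. SUV (`C_T(T)/(A0/bw)`, T = 55 min) is included for comparison.

Everything is validated in silico with a built-in simulator: a
gamma-variate bolus blended into the monoexponential tail, an
irreversible two-tissue compartment tumor model (ground truth
`Ki = K1·k3/(k2+k3)`), exact acquisition framing (24×5 s, 12×15 s,
11×5 min), optional count-statistics noise and 4D voxel phantoms.

## Worked example

```bash
python examples/short_protocol.py
```

```
ground-truth Ki       : 0.08501 1/min
standard-protocol Ki  : 0.08426 1/min (10 Patlak points)
short-protocol Ki,s   : 0.08386 1/min (5 Patlak points)
relative difference   : -0.48 %
```

One simulated patient: the standard 60-min analysis and the short
two-acquisition analysis agree with each other to half a percent and
with the generating kinetics to about 1%, which is the point of the
method — the hybrid input function loses essentially nothing.

Other narrative examples: `examples/standard_patlak.py`,
`examples/population_model_loocv.py` (population tail fit + LOOCV),
`examples/voi_extraction.py` (phantom → hottest-voxel VOI → Ki) and
`examples/method_comparison.py` (the bundled clinical tables).

A thin CLI mirrors the library: `petki simulate | extract | patlak |
short-patlak | suv | compare | loocv | report-tables`.

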