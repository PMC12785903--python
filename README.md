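# starchkin

Quantitative analysis of starch digestion kinetics and supramolecular
structure, built around the workflow used to characterize waxy maize
amylopectin (WMA) pastes and their nanoscale starch–lipid–protein ternary
complexes: in vitro digestible fractions, multi-phase log-of-slope (LOS)
digestion kinetics with estimated glycemic index, SAXS lamellar
correlation-function analysis, and spectral/surface structure descriptors.
Every stage ships with a synthetic-data generator that encodes known ground
truth, so the whole pipeline is testable without laboratory data.

## Who this is for

Carbohydrate and food-structure researchers who have hydrolysis time
series, SAXS curves, FTIR/XRD spectra or AFM height maps and want
reproducible, scriptable versions of the standard desk analyses that are
usually locked inside instrument software.

## The models

**Digestible fractions (Englyst).** With glucose released after 20 and
120 min (G20, G120, mg), free glucose GF and total starch TS:

    RDS = (G20 − GF)·0.9/TS·100        SDS = (G120 − G20)·0.9/TS·100
    RS  = 100 − RDS − SDS

where 0.9 = 162/180 converts glucose to anhydroglucose.

**LOS kinetics.** Starch hydrolysis follows C(t) = C∞(1 − e^(−kt)).
Taking logs of the hydrolysis rate gives ln(dC/dt) = −kt + ln(C∞·k), so
the log difference quotient of the sampled curve,

    y_i = ln((C_{i+1} − C_i)/(t_{i+1} − t_i)),   x_i = (t_{i+1} + t_i)/2,

is piecewise linear when digestion is multi-phase.  Phases are found by
exhaustive piecewise-linear segmentation scored by BIC (slopes must slow
down phase over phase); each segment yields k_i = −slope and
C_i∞ = exp(intercept)/k_i.  The area under the curve,

    AUC = C∞(t_f − t_0) − (C∞/k)(1 − e^(−k(t_f−t_0))),

gives the hydrolysis index HI = 100·AUC_sample/AUC_reference and the
estimated glycemic index EGI = 39.71 + 0.549·HI.

**SAXS lamellae.** The normalized 1-D correlation function

    L(r) = ∫ I(q)q²cos(qr)dq / ∫ I(q)q²dq

locates the lamellar long period d at its first interior maximum; the
linear initial decay intersected with the first-minimum baseline splits d
into crystalline and amorphous layer thicknesses (d = d_c + d_a).  A low-q
power-law fit I ∝ q^α yields the mass fractal dimension D_m = −α, valid
for −3 < α < −1.

**Surface metrics.** RMS roughness Rq, gray-level co-occurrence (GLCM)
energy/contrast/homogeneity/entropy, and differential box-counting fractal
dimension of AFM-style height fields; FTIR 1047/1022 cm⁻¹ short-range
order and XRD relative crystallinity for spectra.

## Worked example

```python
import starchkin as sk

# published two-phase kinetics of the high-SI WMA ternary complex
phases = [sk.PhaseSpec(k=2.43e-2, C_inf=60.21, t_end=200.0),
          sk.PhaseSpec(k=1.44e-2, C_inf=61.06, t_end=540.0)]
curve = sk.gen_digestion_curve(phases, times=sk.UNIFORM_5MIN_GRID)
res = sk.analyze_digestion(curve)
print(len(res.phases), res.breakpoints)
print(f"k1={res.phases[0].k:.4f}  k2={res.phases[1].k:.4f}  "
      f"C1_inf={res.phases[0].C_inf:.2f}")
```

prints

```
2 (200.0,)
k1=0.0243  k2=0.0144  C1_inf=60.25
```

— the pipeline detects both kinetic phases, places the boundary at the
200-min sample, recovers each rate constant exactly (uniform sampling makes
the discrete LOS slope equal −k), and recovers the phase-1 equilibrium
hydrolysis to within the sinh(kΔ/2)/(kΔ/2) discretization bias (+0.06%
at 5-min spacing).

The same workflow is available from the shell:

```bash
starchkin simulate --kind digestion --seed 1 --out curve.csv
starchkin los --input curve.csv --out result.json
```

## Analysis scripts

The `analysis/` directory holds numbered drivers that run the full study
on synthetic data and write tables under `results/`:

1. `01_simulate_digestion.py` — digestion curves for paste and complexes
2. `02_los_kinetics.py` — LOS phase recovery, AUC/HI/EGI
3. `03_fractions.py` — RDS/SDS/RS round trips and self-assembly indices
4. `04_saxs_lamellae.py` — lamellar thicknesses vs the real-space oracle
5. `05_structure_metrics.py` — spectral ratios, crystallinity, texture

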