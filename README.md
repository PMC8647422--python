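# jetflow

Direct quantification of mitral regurgitation (MR) from 4D flow
cardiovascular MR velocity fields, for researchers working on
phase-contrast flow imaging of valvular disease — in particular the
eccentric, mid-to-late-systolic jets of hypertrophic cardiomyopathy,
where the conventional indirect estimate is fragile.

Two quantification routes are implemented side by side:

* **Direct jet tracking.** For every timeframe in which a regurgitant
  jet is present in the atrium, an oblique multiplanar-reformatted (MPR)
  plane is placed at the peak velocity within the jet and oriented
  perpendicular to the local jet direction. The through-plane velocity
  v·n̂ is resampled on the plane, the jet cross-section A is segmented,
  and the regurgitant flow rate is the area integral

      Q(t) = ∫_A v·n̂ dA        [1 cm/s over 1 mm² = 0.01 mL/s]

  The sampled flow-rate curve is cubic-spline interpolated, anchored at
  zero flow half a frame interval outside the jet period, and integrated
  to the regurgitant volume R_vol = ∫ Q(t) dt. Multiple jets are tracked
  independently and summed; no detected jet means R_vol = 0.

* **Indirect volumetric method** (the conventional comparator):
  R_vol = (EDV − ESV) − forward aortic volume, from an LV volume curve
  and a 2D phase-contrast aortic flow curve, with Mosteller BSA indexing.

Volumes are graded none (< 10 mL), mild (10–30 mL), moderate (30–60 mL)
or severe (≥ 60 mL), and an agreement battery — ICC(2,1) (two-way random,
single measures, absolute agreement), Bland–Altman bias ± 1.96·SD limits,
Cohen's kappa on grades, paired Wilcoxon signed-rank — compares methods
or observers with the standard interpretation bands.

Because clinical 4D flow datasets cannot be redistributed, the package
ships a digital jet phantom (`jetflow.phantom`): a seeded velocity field
containing an eccentric jet with a prescribed half-sine orifice flow
curve and exactly known regurgitant volume, plus a matched digital
ventricle/aorta pair, VENC aliasing simulation and additive velocity
noise. Every quantification step is validated against this ground truth.

## Worked example

`python examples/01_simulate_and_track.py` simulates the default phantom
(16 mL jet, 5 cm/s noise, 2.5 mm voxels, 38 ms frames, VENC 150 cm/s)
and quantifies it:

```
phantom: true MR volume 16 mL, jet active in frames 6-13

frame time (ms) peak (cm/s) flow (mL/s)
    6       247        50.8        26.2
    7       285        96.5        48.0
    8       323       116.6        66.4
    9       361       131.4        73.3
   10       399       132.2        75.8
   11       437       116.1        63.7
   12       475        90.6        47.6
   13       513        52.5        25.4

tracked MR volume: 16.0 mL (mild MR)
truth: 16 mL -> relative error +0.0%
```

The per-frame flow rates trace the phantom's half-sine flow program; the
spline integral over the jet period recovers the 16 mL truth, graded
mild. The other examples cover the indirect method (`02`), aliasing
wrap/unwrap (`03`), the agreement battery (`04`) and the full synthetic
study comparing both methods over a severity-spanning cohort (`05`).

A thin CLI wraps the same functions:

```sh
jetflow simulate --out /tmp/ph --seed 1
jetflow track --in /tmp/ph --roi /tmp/ph_roi.nii.gz --out /tmp/track.json
jetflow indirect --lv /tmp/ph_lv.csv --aorta /tmp/ph_ao.csv --out /tmp/ind.json
jetflow agree --csv pairs.csv --out agreement.json
```

## Layout

- `src/jetflow/io.py` — velocity-field container, NIfTI + JSON sidecar
  and CSV curve I/O
- `src/jetflow/phantom.py` — digital jet phantom and ground truth
- `src/jetflow/preprocess.py` — VENC unwrapping, background offset
  correction
- `src/jetflow/tracking.py` — detection, MPR planes, through-plane flow,
  spline integration
- `src/jetflow/volumetric.py` — indirect method, BSA, error-propagation
  demonstration
- `src/jetflow/severity.py` — MR grading
- `src/jetflow/stats.py` — ICC / Bland–Altman / kappa / Wilcoxon battery
- `src/jetflow/pipeline.py`, `cli.py` — batch study orchestration and CLI

See `docs/methods.md` for the model assumptions, parameter choices and
known limitations.
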