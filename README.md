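# mbkit

Analysis toolkit for **micron-scale 2D cardiac muscle bundles (2DMBs)** —
rectangular (nominally 308 × 45 µm, 7:1 aspect ratio) multicellular strips
of purified hPSC-derived cardiomyocytes micropatterned on soft (8 kPa)
PDMS, contracting uniaxially against the compliant substrate.  The
platform turns hPSC-CM contractility, which is notoriously irreproducible
in standard monolayers, into a precise assay; `mbkit` implements the
computational half of that platform for anyone quantifying bundle
structure and function from microscopy:

- **Contraction kinetics from brightfield movies** — ROI templates placed
  at the inner 50% of the bundle length are tracked by zero-normalized
  cross-correlation with subpixel (quadratic-peak) refinement; the
  inter-ROI fractional shortening ΔL/L₀ is segmented into beats, merged
  with 95% confidence bands, and reduced to the standard parameter set:
  maximal fractional shortening, normalized contraction/relaxation
  velocities at 20/50/80% of peak shortening (s⁻¹), peak contraction
  acceleration, deceleration time, relaxation time, beat frequency, with
  per-beat SDs and tracking QC.
- **Sarcomere structure from striation-marker images** — bandpass
  segmentation of striation bands, pairing into sarcomere units with
  per-unit length and orientation, and the per-image Gaussian orientation
  fit whose standard deviation σ is the myofibrillar-alignment metric.
- **Myofibril density from F-actin images** — axially averaged transverse
  intensity profiles, bundle peaks with widths at half height, area
  fraction and across-window heterogeneity.
- **Substrate mechanics** — a linear elastic model of a contracting thin
  tissue coupled to a finite-thickness elastomer layer on rigid glass
  (spectral Green's function `G(k) = 2(1−ν²)tanh(kh)/(Ek)`), used to
  verify mechanical uncoupling of neighbouring bundles, thickness
  decoupling from the glass, modulus sensitivity, and ROI-placement
  robustness.
- **Assay statistics** — coefficient of variation, percent reduction,
  yield fold, and two-group sample size
  `n = 2(z₁₋α/₂ + z₁₋β)²(CV/δ)²` for power planning.
- **Synthetic data with exact ground truth** — seeded generators for
  contracting-bundle movies (strain-exact warps of band-limited texture),
  disorganized multi-domain "monolayer" movies, striation images built
  from myofibril chains with known angle draws, and F-actin stripe
  layouts with known coverage.  Every quantitative claim in the test
  suite is validated against these generators or against closed forms.

See `docs/methods.md` for the models, estimators, defaults and their
rationale.

## Worked example

Simulate a bundle movie with 5% peak fractional shortening beating at
0.4 Hz, then analyze it — from the shell:

```
$ mbk simulate movie --seed 3 --fs-max 0.05 --pixel-size 0.5 --duration 6 --out movie.tif
wrote 300 frames to movie.tif
$ mbk track movie.tif --pixel-size 0.5 --fps 50 --out kinetics.csv
movie: max FS 5.04% over 3 beats at 0.40 Hz -> kinetics.csv
```

or from Python:

```python
from mbkit.io import place_rois_inner50
from mbkit.kinetics import build_waveform, kinetics_from_waveform
from mbkit.synthetic import ContractionGroundTruth, gen_contraction_movie
from mbkit.tracking import TrackingParams, track_roi

truth = ContractionGroundTruth(fs_max=0.05, frequency_hz=0.4)
stack, record = gen_contraction_movie(truth, pixel_size=0.5, duration_s=20.0, seed=1)
prox, dist = place_rois_inner50(record["geometry"], 0.5, 10, stack.frame_shape)
params = TrackingParams(search_radius=14)
wave = build_waveform(track_roi(stack, prox, params), track_roi(stack, dist, params))
summary = kinetics_from_waveform(wave)
print(f"max FS {summary.max_fs_pct:.2f}%  v_con_50 {summary.v_con_50:.4f} 1/s  "
      f"freq {summary.frequency:.2f} Hz  n_beats {summary.n_beats}")
```

```
max FS 5.00%  v_con_50 0.1567 1/s  freq 0.40 Hz  n_beats 8
```

`max FS 5.00%` is the recovered maximal fractional shortening (the
imposed truth was 5% — and 5.0 ± 1.1% is the scale reported for real
bundles); `v_con_50 0.1567 1/s` is the normalized contraction velocity
where shortening first crosses half its peak, matching the raised-cosine
closed form FS·π/(2T_c) = 0.1571 s⁻¹; the beat frequency and count come
from peak detection over the 20 s record.

Structure, density and power numbers follow the same pattern:

```python
from mbkit.sarcomere import fit_orientation_sigma, segment_sarcomere_units
from mbkit.synthetic import StructureGroundTruth, gen_structure_image

truth = StructureGroundTruth(spacing_um=2.2, orientation_sigma_deg=5.0)
img, rec = gen_structure_image(truth, pixel_size=0.2, kind="striation", seed=7)
mask, units = segment_sarcomere_units(img, 0.2)
fit = fit_orientation_sigma(units)
print(f"{len(units)} units, sigma {fit.sigma_theta:.1f} deg")
# -> 966 units, sigma 4.2 deg
```

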