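# exmkit

Quantification toolkit for calibrated 3D expansion microscopy (ExM) of
endosomes and other small compartments.

Expansion microscopy physically inflates a hydrogel-embedded sample by a
linear expansion factor (EF), multiplying the effective optical resolution.
Two problems make the resulting measurements uncertain: the gel can expand
anisotropically (local distortion, especially around small compartments),
and the EF actually experienced by intracellular structures — the
*intrinsic* EF — can differ from the *macroscopic* EF measured from gel
dimensions. `exmkit` provides the analysis chain for both problems, plus
the downstream nanoscale statistics, for anyone quantifying ExM image
volumes:

- **Registration** — pre/post-expansion volumes of the same region are
  related by a similarity transform `x_post = s R x_pre + t`, estimated by
  iterative block matching (normalized cross-correlation, least-squares
  Umeyama fit with MAD outlier rejection).
- **Distortion mapping** — dense Farneback-style optical flow on every
  resectioned x–y and x–z plane; the orthogonal components are fused into a
  3D displacement field `u(x)` (nm). Distortion is summarized as the
  pair-differential error `RMSE(L) = sqrt(E[|u(p) − u(q)|²])` for point
  pairs at separation `L`, and `100·RMSE(L)/L` is the percent measurement
  error at that length scale; a signed radial map shows compartment
  under-expansion.
- **Calibration** — nanocage protein size standards (⌀ ≈ 28 nm) measured
  in TEM-like images via second-moment ellipses (width = (major+minor)/2),
  detected as fluorescence spots with 2D Gaussian FWHM fits; intrinsic EF
  = mean spot width / reference diameter; macroscopic EF = mean post/pre
  gel-dimension ratio; PSF FWHM from averaged bead stacks, with the
  effective PSF = FWHM/EF.
- **Surface tracing** — the endosomal limiting membrane reconstructed from
  membrane-marker puncta by iterated, averaged Delaunay (convex-hull)
  triangulations on an icosphere ray set; marker puncta within ±40 nm of
  the surface are projected onto it and per-channel surface-area occupancy
  is computed.
- **Puncta statistics** — watershed segmentation in physical nm,
  widths, nearest-neighbor distances, volume/count ratios,
  moment-preserving (Tsai) auto-thresholds, Manders colocalization
  percentages and chord-diagram tables.
- **Synthetic scenes** — every estimator is testable without microscope
  data: ellipsoidal shells with clustered membrane puncta, nanocage fields
  of known true diameter, anisotropic Gaussian PSF rendering,
  Poisson+Gaussian noise, and analytic distortion fields with exact ground
  truth.

See `docs/methods.md` for models, defaults and limitations.

## Worked example: intrinsic vs macroscopic expansion factor

```python
import numpy as np
from exmkit import (NanocageFieldSpec, render_tem_nanocages, measure_tem_widths,
                    detect_spots, intrinsic_ef, macroscopic_ef, effective_psf,
                    render_volume, PSFModel)
from exmkit.fixtures import FWHM_PER_SIGMA

# 1) TEM reference: a synthetic micrograph of 138 nanocages (true diameters
#    ~ Normal(28.3, 1.6) nm), measured by automatic ellipse fitting
spec = NanocageFieldSpec(n_cages=138, diameter_mean=28.3, diameter_sd=1.6)
image, truth = render_tem_nanocages(spec, (1024, 1024), pixel_size=0.8, seed=1)
tem = measure_tem_widths(image, pixel_size=0.8)
widths = np.array([m.width_nm for m in tem])
print(f"TEM: n={len(tem)} cages, width = {widths.mean():.1f} +/- {widths.std(ddof=1):.1f} nm")

# 2) post-expansion fluorescence: the same cages appear as supra-resolution
#    spots; their fitted widths divided by the TEM reference give the EF
rng = np.random.default_rng(1)
n = 60
shape, vs = (24, 256, 256), (100.0, 40.0, 40.0)
extent = np.array(shape) * np.array(vs)
centers = np.column_stack([rng.uniform(600, extent[0]-600, n),
                           rng.uniform(500, extent[1]-500, n),
                           rng.uniform(500, extent[2]-500, n)])
spot_widths = np.clip(rng.normal(263.7, 63.1, n), 80, None)
sig = np.column_stack([np.full(n, 600/FWHM_PER_SIGMA),
                       spot_widths/FWHM_PER_SIGMA, spot_widths/FWHM_PER_SIGMA])
vol = render_volume(centers, np.full(n, 2e4), PSFModel(75, 200), shape, vs,
                    point_sigmas=sig, poisson_gain=10.0, seed=2)
spots = detect_spots(vol, detection_fwhm_nm=260.0)
rec = intrinsic_ef(spots, reference_diameter_nm=widths.mean())
print(f"spots: n={rec.n_spots}, intrinsic EF = {rec.intrinsic_ef:.2f} +/- {rec.intrinsic_ef_sd:.2f}")
print(f"macroscopic EF (5 mm -> 47 mm gel): {macroscopic_ef([5.0],[47.0]):.1f}")
print(f"effective lateral PSF at EF {rec.intrinsic_ef:.2f}: "
      f"{effective_psf(170.0, rec.intrinsic_ef):.1f} nm")
```

Output:

```
TEM: n=138 cages, width = 28.5 +/- 1.5 nm
spots: n=51, intrinsic EF = 8.86 +/- 2.11
macroscopic EF (5 mm -> 47 mm gel): 9.4
effective lateral PSF at EF 8.86: 19.2 nm
```

Reading it: the ellipse estimator recovers the 28.3 nm nanocage population
(28.5 ± 1.5 nm over 138 cages); the fluorescence spots average ~252 nm, so
the cell interior expanded 8.86× — less than the 9.4× the gel dimensions
suggest. Calibrating image scale with the intrinsic EF therefore yields
slightly *larger* physical sizes for intracellular objects than the
macroscopic EF would, and a ~170 nm confocal PSF behaves like a ~19 nm PSF
at this expansion.

## Command line

Each stage is also a subcommand operating on TIFF/CSV/JSON/PLY files:

```bash
exmkit simulate --seed 4 --config scene.yaml --out scene/
exmkit register --pre pre.tif --post post.tif --init-scale 9.4 --out t.json
exmkit distort-map --pre pre.tif --post post.tif --transform t.json \
       --scales 50:2500 --out distortion/
exmkit calibrate --tem tem.csv --macro-pre 5 --macro-post 47 --out ef.json
exmkit trace-surface --puncta scene/ground_truth_points.csv --band 40 --out surf/
exmkit puncta-stats --vol calibrated.tif --channels EGF,EGFR1 --out stats/
exmkit report --scene-dir scene/ --out summary.csv
```

Every run writes a config echo and a checksum manifest next to its outputs,
so pipelines are reproducible end to end given the seeds.

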