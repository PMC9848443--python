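# neoscan

Quantitative analysis of neonatal cranial (head) ultrasound frames.

Cranial ultrasound through the anterior fontanelle is the first-line
imaging modality for newborns at risk of intracranial hemorrhage,
hypoxic–ischemic injury or white-matter disease.  Reading such frames is
largely qualitative; `neoscan` implements the two quantitative read-outs
used to put numbers on white-matter echogenicity, for image-analysis
researchers and sonographers who want reproducible measurements instead
of visual impressions:

* **Echo intensity** — the gray mean of a region of interest,
  `M = Σ_r r·p(r)`, normalised by a fixed circular reference region as
  the *relative gray value* `RGV = 100·M_roi / M_ref`.  Hyperechoic
  (abnormally bright) white matter shows a raised RGV.
* **Echo homogeneity** — gray-level co-occurrence matrix (GLCM) texture
  features per compass direction: energy `ENE = Σ P²`, inverse
  difference moment `IDM = Σ P/(1+(i−j)²)`, contrast
  `CON = Σ (i−j)²·P` and entropy `ENT = −Σ P·log₂P`, aggregated into
  E–W, N–S, Cross (mean of E, N, W, S) and Circle (mean of all eight
  directions) columns.  Heterogeneous white matter shows high ENT/CON
  and low ENE/IDM.

Upstream of the measurements, frames pass through the standard
preprocessing chain: black-margin cropping, two-level adaptive median
filtering (impulse-noise suppression that preserves hyperechoic
boundaries), and contrast-limited adaptive histogram equalization
(CLAHE).  A synthetic phantom generator with exact ground truth
(speckle, polygonal lesions, margins, impulse noise) makes every stage
testable without patient data.  See `docs/methods.md` for the full model
description and parameter defaults.

## Worked example

```python
import neoscan as ns

# A 160x200 phantom: speckled parenchyma (mean 100), a heterogeneous
# bright lesion (mean 180), a bright reference structure (mean 250),
# and a 12 px black annotation margin.
lesion = ns.LesionSpec(((40, 40), (40, 90), (90, 90), (90, 40)),
                       mean=180.0, heterogeneity=0.2)
bright = ns.LesionSpec(((100, 60), (100, 130), (140, 130), (140, 60)),
                       mean=250.0)
spec = ns.PhantomSpec(height=160, width=200, background_mean=100.0,
                      speckle_scale=0.05, margin_width=12,
                      lesions=(lesion, bright), seed=100)
image, _ = ns.generate_phantom(spec)

bounds, cropped = ns.crop_black_margins(image, 0.95)
filtered = ns.adaptive_median_filter(cropped, ns.AmfConfig(3, 7))

roi = ns.polygon_mask([(32, 32), (32, 74), (74, 74), (74, 32)], *filtered.shape)
ref = ns.circle_mask((104, 83), 14, *filtered.shape)
report = ns.intensity_report(filtered, [roi], ref)
print(bounds)
print(f"ROI mean        {report.roi_means[0]:.4f}")
print(f"reference mean  {report.reference_mean:.4f}")
print(f"relative gray   {report.relative_values[0]:.4f}")
```

prints

```
CropBounds(row_start=12, row_end=148, col_start=12, col_end=188)
ROI mean        176.6620
reference mean  247.6933
relative gray   71.3229
```

The crop recovered the 12 px margin exactly, and the lesion ROI measures
71.3% of the reference echogenicity — close to the phantom's ground
truth 180/250 = 72%, with the residual gap from speckle and the
filtering stage.  Texture on the CLAHE-enhanced frame separates the
heterogeneous lesion from the smooth background:

```python
enhanced = ns.clahe(filtered, ns.ClaheConfig(8, 8, 4.0))
table = ns.homogeneity_report(enhanced, [roi], ns.GlcmConfig())[0].to_frame()
print(table.round(4).to_string())
```

```
          E     N-E       N     N-W       W     S-W       S     S-E     E-W     N-S   Cross  Circle
ENE  0.0159  0.0143  0.0160  0.0150  0.0159  0.0143  0.0160  0.0150  0.0159  0.0160  0.0160  0.0153
IDM  0.4983  0.4664  0.5027  0.4782  0.4983  0.4664  0.5027  0.4782  0.4983  0.5027  0.5005  0.4864
CON  4.4468  4.9456  4.1993  4.7574  4.4468  4.9456  4.1993  4.7574  4.4468  4.1993  4.3231  4.5873
ENT  6.4181  6.5252  6.4008  6.4903  6.4181  6.5252  6.4008  6.4903  6.4181  6.4008  6.4094  6.4586
```

Opposite directions (E/W, N/S, …) are equal because the four features
are transpose-invariant — the reason reported texture tables repeat
their first four columns.  Note that local equalization deliberately
compresses *regional* intensity differences, so relative gray values are
most interpretable on the filtered frame, while texture is measured on
the enhanced frame the way the clinical workflow does.

## Command line

```sh
neoscan synth      --out demo/ --seed 7            # phantom + ground truth
neoscan preprocess --in frame.png --out stages/ \
                   --crop-threshold 0.95 --amf-init 3 --amf-max 7 \
                   --tiles 8x8 --clip-factor 4.0
neoscan quantify   --in stages/frame_clahe.png --config regions.yaml --out report/
neoscan run        --config pipeline.yaml          # full multi-plane pipeline
```

`neoscan run` processes every plane in a YAML config
(crop → filter → CLAHE → masks → intensity + homogeneity tables),
writing stage images, masks, 4-decimal CSV tables, full-precision JSON
reports and a parameter/checksum log; re-running the same config is
bit-identical, and a failing plane is recorded without stopping the
others.

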