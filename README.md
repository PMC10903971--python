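# topmorph

Top-view animal morphometrics from segmentation masks and depth maps.

Precision-livestock pipelines routinely estimate body dimensions, growth
and condition from overhead cameras: an instance segmenter outlines each
animal, and the outline (plus, with a depth camera, the surface beneath
it) is turned into quantitative body measurements. `topmorph` implements
that measurement stage as a tested library and CLI, independent of any
particular segmentation model:

* **2D features** from a binary mask — the minimum-area *rotated*
  rectangle (pose-invariant, unlike the axis-aligned boxes detectors
  emit) gives dorsal length and abdominal width; the mask gives area and
  centroid. A pixels-per-meter scalar (PPM) converts pixels to meters.
* **3D features** from a depth map — after a cleaning pipeline (mask the
  animal via a Hadamard product, fill missing zeros with the nonzero
  mean, Gaussian-smooth), per-pixel height above the floor is
  `camera_to_ground − depth`, yielding average height, height at the
  centroid, and volume.
* **Evaluation** — average precision of predicted masks against ground
  truth at IoU thresholds (0.5, 0.75), with exact all-point PR
  integration: AP = ∫₀¹ p(r) dr.
* **Synthetic phantoms** — half-ellipsoid "animals" on a flat floor with
  sensor noise and dropout, whose length 2a, width 2b, area πab, volume
  (2/3)πabc, mean height 2c/3 and apex height c are closed-form, so the
  whole pipeline is testable end-to-end with no data downloads.
* A classical height-threshold segmenter, so depth scenes can be
  processed without any trained model; externally produced label images
  plug in through the same interface.

**Coordinate convention** (matches the emitted table schema): 0-based
`(row, col)`, row increasing downward; feature columns ending in `_x`
are ROW coordinates and `_y` COLUMN coordinates. Angles are degrees
counterclockwise from the column axis in `[0, 180)`. Coordinates are
always raw pixels; only lengths/areas/heights/volumes are PPM-converted.

See `docs/methods.md` for the model, conventions, error budget and
limitations.

## Worked example

Generate a noise-free synthetic scene (one 1.0 × 0.5 m, 0.4 m tall
animal at 100 px/m under a camera 2.5 m above the floor), then run the
depth pipeline with the scene's label mask:

```bash
topmorph simulate --seed 7 --noise-sd 0 --dropout 0 --out scene/
topmorph extract3d --depth scene/depth.csv --mask scene/truth_labels.png \
    --ppm 100 --sigma 0 --out run/
```

`run/features.csv` (measurement columns, meters):

```
 Dorsal length  Abdominal width   Area  Height_average  Height_centroid  Volume
        0.9975           0.4987 0.3907          0.2678              0.4  0.1046
```

Read against the closed-form truth: dorsal length 2a = 1.0 m and
abdominal width 2b = 0.5 m are recovered to 0.25% (the residual is
rasterization at 100 px/m); area πab ≈ 0.3927 m²; average height
2c/3 ≈ 0.2667 m; apex height c = 0.4 m exactly; volume
(2/3)πabc ≈ 0.1047 m³ recovered to 0.1%. The same command with
`--classical --min-height 0.05` instead of `--mask` segments the depth
scene itself; `topmorph detect2d --mask labels.png --out out/` runs the
2D-only path on any integer label image, and `topmorph evaluate
--pred-dir P --truth-dir T` scores predictions with AP@0.5/0.75.

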