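# fazseg

Automatic localization and precise segmentation of the **foveal avascular
zone (FAZ)** in en-face OCT angiography (OCT-A) images.

OCT-A maps the perfused retinal vasculature without contrast injection.
At the center of the macula the capillary mesh leaves a capillary-free
region — the FAZ — whose area and contour irregularity are biomarkers
for diabetic retinopathy and retinal vein occlusion.  Manual delineation
is slow and subjective; `fazseg` extracts the region automatically and
reports the two clinical parameters:

* **area** `A = a · mm² / (height · width)` — foreground pixel count
  times the physical area of one pixel (fields of 3×3 or 6×6 mm);
* **circularity** `4πA/P²` ∈ [0, 1] — 1 for a perfect circle,
  decreasing with contour irregularity.

## Method

1. **Vessel enhancement** — grayscale *white top-hat* (image minus its
   opening, disc element): thin bright capillaries keep full contrast,
   broad background is flattened.
2. **Vessel edges** — Canny detector whose hysteresis thresholds are
   multiples of the mean image intensity, so the edge map is invariant
   to global brightness changes between acquisitions.
3. **Candidate extraction** — morphological closure seals the vascular
   edge network; inversion turns avascular holes into foreground; an
   opening removes speckle.
4. **FAZ identification** — peripheral (border-hugging), eccentric and
   disperse (low-solidity) candidates are discarded; of the survivors,
   the candidate with the largest perimeter is the preliminary FAZ.
5. **Precise segmentation** — the preliminary region is eroded into a
   seed guaranteed to lie inside the true FAZ, then refined by region
   growing with **pixel addition and deletion**: each sweep recomputes
   the average region value (ARV) on the enhanced image and accepts
   exactly the pixels in `[ARV − 0.3·ARV, ARV + 0.3·ARV]`.

A synthetic phantom generator (`fazseg.synthetic`) renders OCT-A-like
images — a space-filling capillary mesh, a central avascular region
with a Fourier-perturbed contour, superficial/deep contrast styles,
optional dark border artifact bands — together with ground-truth masks,
so the whole pipeline is testable without any dataset download.

## Worked example

```python
from fazseg import (PhantomSpec, generate_phantom, segment_faz,
                    jaccard_index, localization_success)

spec = PhantomSpec(field_mm=3.0, faz_radius_mm=0.32, irregularity=0.15, seed=11)
img, truth = generate_phantom(spec)

res = segment_faz(img)
print(f"area      : {res.area_mm2:.4f} mm^2 (truth {truth.pixels.sum() * 9 / 320**2:.4f})")
print(f"circ      : {res.circularity:.3f}")
print(f"localized : {localization_success(res.preliminary_mask, truth)}")
print(f"jaccard   : {jaccard_index(res.mask, truth):.3f}")
print(f"converged : {res.converged} after {res.iterations} sweeps")
```

prints

```
area      : 0.3117 mm^2 (truth 0.3227)
circ      : 0.179
localized : True
jaccard   : 0.921
converged : True after 14 sweeps
```

The estimated area is within 3.5% of the ground truth and the masks
overlap with Jaccard 0.92.  `localized` applies the centroid-in-mask
criterion to the *preliminary* extraction: the localization stage is
validated separately from the precise segmentation.  Circularity is
computed on the raw pixelwise mask, whose jagged boundary inflates the
perimeter — compare values only against circularities computed the same
way (as the tertile analysis does).

From the shell:

```sh
faz-seg phantoms --n 12 --seed 0 --out-dir phantoms/
faz-seg segment phantoms/phantom_000.png --field-mm 3 --out-dir out/
faz-seg evaluate phantoms/manifest.csv --out-dir eval/
```

`segment` writes a binary mask PNG and a JSON report (area,
circularity, centroid, full configuration) per image plus a batch CSV;
`evaluate` compares against reference masks listed in a manifest and
writes per-subgroup tables (localization rate, Pearson r of areas, mean
Jaccard) and circularity-tertile summaries.  All knobs live in a YAML
config (`faz-seg segment --config my.yaml`); unknown keys are rejected.

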