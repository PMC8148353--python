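# trace-concord

Agreement and precision analysis for hand-traced optic-disc boundaries
in fundus images.

## The problem

Training segmentation models on retinal images needs reliable
ground-truth disc outlines, but hand tracings are subjective: two
annotators who agree almost perfectly on *where the disc is* can still
disagree badly on *where its border runs* — especially in glaucomatous
eyes, where peripapillary atrophy (PPA) blurs the disc margin.  This
package quantifies that disagreement for studies in which two raters
(e.g. optometrists, labelled `od1` and `od2`) trace the disc in every
image and an expert ground truth (`ground_truth`) is available, and
evaluates whether replacing each tracing by its best-fit ellipse
("ellipse fitting", a standard repair for stylus-calibration
misalignments) helps or hurts.

## The statistics

For each image and each tracing pair the pipeline computes:

* **Cohen's kappa** over the pixels of a bounding box drawn around the
  union of the compared tracings (lowest/highest x and y of the
  foreground),
  `κ = (P_o − P_e) / (1 − P_e)`,
  where `P_o` is the fraction of pixels labelled identically and `P_e`
  the chance agreement from each mask's foreground fraction.  Two
  variants: **region** (filled masks) and **border** (boundary bands
  dilated by a tolerance, default 2 px) — the border variant is far
  stricter and is where raters actually disagree.
* **Dice coefficient** `DC = 2|A∩B| / (|A|+|B|)` over foreground pixels.
* **Average boundary distance**
  `μ_d = (1/n) Σ_k |d_kg − d_kp|`,
  where `d_kg` and `d_kp` are the distances from the ground-truth
  centroid `C_g` to the two boundaries along direction `k`
  (12 directions at 30° spacing by default), in pixels.

Ellipse fitting uses the direct least-squares method: the conic
`Ax² + Bxy + Cy² + Dx + Ey + F = 0` constrained to `B² − 4AC < 0` is
found by splitting the design matrix into quadratic (`D1`) and linear
(`D2`) blocks, forming the scatter blocks `S1, S2, S3`, and solving the
3×3 eigenproblem of `M = C1⁻¹(S1 − S2 S3⁻¹ S2ᵀ)` with
`C1 = [[0,0,2],[0,−1,0],[2,0,0]]`; the eigenvector with
`4 a₁a₃ − a₂² > 0` yields the ellipse.

Because real multi-rater tracing datasets require downloads, the
package ships a **synthetic observer model**: elliptical (optionally
perturbed) true discs, raters with Gaussian radial jitter, occasional
radially displaced stroke arcs (misalignments), and a
condition-dependent outward sector bias that mimics PPA confusion in
glaucomatous images.  The default study mirrors a 159-image two-cohort
composition (69 glaucoma + 37 normal at high resolution, 53 diabetic
retinopathy at low resolution).

## Worked example

```python
from trace_concord import run_study
from trace_concord.synthetic_tracing import default_config, generate_study

cfg = default_config(seed=1, counts={"glaucoma": 10, "dr": 10, "normal": 10})
records = generate_study(cfg)          # ground truth + two simulated raters
report = run_study(records)            # all pairs, before & after ellipse fit

agg = report.by_condition
raw = agg[(agg.pair == "od1-gt") & (~agg.fitted)]
print(raw[["condition", "dice", "kappa_region", "kappa_border", "mu_d",
           "kappa_region_band", "kappa_border_band"]].to_string(index=False))
```

prints

```
condition     dice  kappa_region  kappa_border     mu_d kappa_region_band kappa_border_band
       dr 0.989309      0.956103      0.834567 0.795833    almost perfect    almost perfect
 glaucoma 0.966832      0.875086      0.512228 2.289583    almost perfect          moderate
   normal 0.992101      0.967789      0.871461 0.564583    almost perfect    almost perfect
```

Reading this: rater `od1` agrees almost perfectly with ground truth on
the disc *region* everywhere (kappa ≥ 0.88, dice ≥ 0.97), but on the
disc *border* the glaucoma stratum drops to moderate agreement
(κ ≈ 0.51) and shows a four-fold higher boundary distance
(≈ 2.3 px vs ≈ 0.6 px) — the simulated PPA sector bias produces
exactly the condition-dependent disagreement pattern the metrics are
designed to expose.  The `fitted=True` rows of the same tables give the
after-ellipse-fitting comparison.

The same pipeline runs from a shell on any manifest of PNG masks /
`x,y`-CSV polylines:

```sh
trace-concord simulate --out study/ --seed 1
trace-concord analyze --manifest study/manifest.csv --out report/ --ellipse-fit
trace-concord report --in report/ --format md
```

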