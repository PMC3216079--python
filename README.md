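# myodamage

Quantification of surgical muscle damage from color-stained cross-section
photographs, with the reliability, group-comparison and power analyses that
accompany a cadaveric comparison of hip-replacement approaches.

## The problem

Minimally invasive approaches for total hip arthroplasty are meant to spare
soft tissue, but inside a restricted surgical field the damage they actually
cause is hard to judge. In cadaver studies the muscles are dissected after
surgery, disrupted fibers are stained yellow and intact fibers blue, and each
muscle is cut at its **midsubstance cross-sectional area (MCSA)** — the plane
bisecting the fibers halfway between origin and insertion, perpendicular to
the fiber direction. Because the MCSA cuts every fiber exactly once, the
damaged share of this plane is a pennation-independent measure of the
fraction of disrupted fibers. The primary outcome is damage to the gluteus
medius, the principal hip abductor, whose injury produces a Trendelenburg
gait.

## The model

Each stained slice photograph is segmented by a two-class RGB color model.
For each stain class *c* ∈ {yellow, blue}, per-channel means μ_c and sample
standard deviations σ_c are estimated from ten 10×10-pixel training regions
sampled inside the stain. A pixel **p** inside the segmentation bounding box
belongs to class *c* iff

    |p_j − μ_cj| ≤ k · σ_cj   for every channel j ∈ {R, G, B},   k = 1.7.

Pixels matching both classes are resolved by the smaller SD-normalized
Euclidean distance to the class mean; pixels matching neither are "uncolored"
and excluded. The damage percentage is

    α = 100 · n_yellow / (n_yellow + n_blue).

Around this core the package provides:

* **synthetic slices** with known ground truth (elliptical cross-section, a
  chord-cut damaged sector with an exactly controlled fraction, iid Gaussian
  color noise) so the whole pipeline is testable without photographs;
* **reliability**: ICC(2,1) — two-way random effects, absolute agreement,
  single measure — on a subjects × raters matrix, including a simulation in
  which independent "raters" re-sample their own training regions;
* **group statistics**: medians with ranges, the ties-corrected
  Kruskal–Wallis test (χ² approximation, k − 1 df), Bonferroni thresholds
  (α/m), and frequency tables for dichotomous outcomes;
* **power**: noncentral-t power of the two-sided two-sample pooled t-test and
  the smallest per-group n reaching a target power.

## Worked example

```python
from myodamage import (SimulationParams, generate_slice_image,
                       generate_training_regions, StainSegmentation)

fx = generate_slice_image(SimulationParams(true_fraction=0.35, noise_sd=8.0, seed=42))
regions = generate_training_regions(fx, seed=1)
res = StainSegmentation(fx.image, regions.yellow_regions,
                        regions.blue_regions, fx.bbox).fit()
print(res.summary())
```

```
Stain segmentation results
==========================
bounding box        : x=80 y=60 w=481 h=361
SD multiplier k     : 1.7
yellow model        : mean=(220.2, 200.4, 60.5) sd=(8.03, 7.81, 8.16) n=1000
blue model          : mean=(50.1, 70.3, 180.0) sd=(8.22, 7.93, 7.99) n=1000
yellow pixels       : 35514
blue pixels         : 66885
uncolored pixels    : 71242
both-class pixels   : 0 (ties: 0)
damage percentage   : 34.68% (rounded: 35%)
```

The fitted per-channel SDs recover the generating noise SD of 8, and the
estimated damage (34.68%) sits within a third of a percentage point of the
true 35% despite the noise; the uncolored pixels are the background corners
of the bounding box, correctly excluded from the denominator.

Study-level statistics run on the packaged per-hip damage table:

```python
from myodamage import load_table1, summarize_groups
print(summarize_groups(load_table1()))
```

```
Group summary (median, range)
  lateral_transgluteal: 22 (6-40)
  mis_anterior: 0 (0-35)
  mis_anterolateral: 18 (6-27)
  mis_2incision: 26 (14-40)
  mis_posterior: 18 (0-22)
Kruskal-Wallis: H=7.436, df=4, p=0.115
```

No approach separates from the conventional lateral transgluteal approach at
the 0.05 level, even though the MIS anterior approach preserved the muscle
completely in 4 of 5 hips. The a-priori design calculation
(`t_test_power(PowerSpec(5, 18, 8.5, 0.05))` → 0.834) confirms that 5 hips
per group give just over 80% power to detect an 18-point difference at a
common SD of 8.5.

A `myodamage` console script exposes the same stages
(`simulate`, `segment`, `reliability`, `analyze`, `power`, `run`); try
`myodamage run --seed 0 --out results/` for the full demo pipeline.

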