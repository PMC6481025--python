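# ocutort — quantitative tortuosity of ocular vessels

Increased tortuosity of retinal and conjunctival vessels is a clinical
marker of Fabry disease and other vasculopathies, but grading it by eye is
subjective. `ocutort` implements an objective, semi-automatic measurement
pipeline for ocular photographs and the case-control statistics built on
top of it, together with a fully synthetic data generator (parametric
vessels with known ground truth) so every stage can be validated without
patient images.

The package is aimed at image-analysis researchers and biostatisticians
working with fundus / bulbar-conjunctiva photography: it provides the
tracing and measurement primitives as a library, a small CLI, and a set of
numbered analysis drivers that reproduce a complete simulated study.

## The three tortuosity indexes

All indexes operate on a vessel centerline polyline resampled to uniform
arc-length spacing Δs (default 5 px), with chord vectors
v_k = p_{k+1} − p_k, turning angles θ_k = ∠(v_{k−1}, v_k) ∈ [0, π] and arc
length L = Σ|v_k|:

* **SOAM** (sum of angles metric) = (Σ_k θ_k) / L — total absolute turning
  per pixel of vessel (rad/px). Straight line → 0; circular arc of radius
  r → 1/r.
* **PAD** (product of angle distance) = (Σ_k θ_k · d_k) / L with
  d_k = (|v_{k−1}| + |v_k|)/2 — turning weighted by local inter-sample
  distance. Under exactly uniform spacing PAD = Δs · SOAM.
* **I2e** (triangular index, step e = 2) = mean_k of
  (|p_{k−e} − p_k| + |p_k − p_{k+e}|) / |p_{k−e} − p_{k+e}| — a sliding
  arc-to-chord ratio; ≥ 1 with equality exactly on straight lines. For a
  circle sampled at arc step Δs it equals 1/cos(eΔs/2r).

## Semi-automatic tracing

An operator supplies three points along a vessel's course. Each click is
snapped to the darkest nearby pixel, a minimal-cost path (Dijkstra over a
multiscale Hessian-ridge "vesselness" cost field) connects the seeds
through the vessel, and the path is refined to subpixel accuracy on the
vessel's intensity profile. On noiseless synthetic images the traced
centerline lies within 0.1 px of the true curve on average, and the three
indexes agree with ground-truth values to well under 1%.

## Worked example

The numbered drivers under `analysis/` run a complete simulated study:
a cohort of 11 affected (FD) and 11 control subjects, both eyes, five
ocular sites, with a 2× vessel-amplitude effect injected at the retina
and nasal conjunctiva only. After

```
python analysis/01_simulate.py
python analysis/03_metrics.py
python analysis/04_compare.py
```

the group comparison prints:

```
FD vs control (Mann-Whitney, two-sided):
          retina soam: p = 0.0356 *
          retina  pad: p = 0.0356 *
          retina  i2e: p = 0.0356 *
   conj_inferior soam: p = 0.8438
   conj_inferior  pad: p = 0.7928
   conj_inferior  i2e: p = 0.7928
      conj_nasal soam: p = 0.0356 *
      conj_nasal  pad: p = 0.0356 *
      conj_nasal  i2e: p = 0.0356 *
   conj_superior soam: p = 0.8438
   conj_superior  pad: p = 0.8438
   conj_superior  i2e: p = 0.8955
   conj_temporal soam: p = 0.8955
   conj_temporal  pad: p = 0.8955
   conj_temporal  i2e: p = 0.8438

significant group differences at: conj_nasal, retina
```

Detection is concentrated exactly at the two sites where the effect was
injected — the same qualitative pattern the measurement is designed to
reveal in real cohorts. `analysis/02_trace_fidelity.py`,
`analysis/05_reproducibility.py` and `analysis/06_power.py` validate the
tracer against ground truth (worst index error 0.59%), quantify
seed-jitter reproducibility (CV ≤ 0.56% across 10 vessels × 20 repeated
tracings), and sweep the design's power (type-I error 0.058 at α = 0.05;
power 0.41 / 0.85 / 1.00 at effect sizes 1.5× / 2× / 3×).

A `ocutort` console command exposes the same pipeline
(`simulate`, `trace`, `metrics`, `compare`, `report`, `run`) for use on
individual images and CSV tables.

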