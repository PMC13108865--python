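# wormcal

Quantification of intestinal Ca²⁺ oscillations in freely moving
*C. elegans* from paired brightfield + GCaMP time-lapse recordings.

The *C. elegans* intestine fires a Ca²⁺ wave roughly every 50 s, pacing
the defecation motor program (DMP): in healthy animals the wave initiates
in a posterior intestinal cell and propagates anteriorly along the organ,
and the cycle is strikingly regular (inter-cycle variability under a few
seconds). Dietary and genetic perturbations show up as lengthened or
irregular intervals, complete loss of oscillations, or *ectopic* events
that start in medial cells and fail to spread. `wormcal` is for
researchers who record this physiology at low magnification in
unrestrained worms and need per-animal numbers — wave times, intervals,
regularity, absence calls, initiation sites, propagation extents — plus
cohort-level comparisons.

## What it computes

Given a brightfield stack and a simultaneously acquired GCaMP stack
(multi-page TIFF, default 15 frames/s):

1. **Segmentation** — per-frame Otsu threshold on brightfield (worm dark
   on bright background), largest 8-connected component, morphological
   closing (2 px disks) and hole filling.
2. **Bulk trace** — F̄(t) = ⟨F⟩_inside − ⟨F⟩_outside, the
   background-subtracted mean intestinal fluorescence.
3. **Wave detection** — peaks of the 1 s-smoothed trace with prominence
   ≥ 4·MAD(ΔF̄) and spacing ≥ 10 s; intervals, mean, sample SD, CV, and
   an oscillation-absent call (no waves in ≥ 240 s of recording).
4. **Kymograph** — skeleton midline per frame, 100 equal arc-length
   segments, fluorescence sampled along each segment-midpoint normal,
   per-segment maxima resampled to 200 axial positions; anterior at
   column 0, identified by the GCaMP-free pharynx; coiled frames left as
   missing rows.
5. **Wave geometry** — per detected wave: initiation position (axis
   fraction, 0 = anterior), propagation extent (fraction of responding
   columns), and the propagated/ectopic classification (ectopic =
   initiates in the medial third, extent < 0.7).
6. **Cohort statistics** — Welch t-tests with step-down Holm–Šídák
   correction, adj p = 1 − (1 − p)^(m−k+1), on interval length or CV.

A synthetic recording generator (`wormcal.simulate`) produces dual-channel
videos of an undulating, drifting worm with a configurable wave schedule,
pharynx band, ectopic events, coiled postures, and sensor noise, plus the
full ground truth — the entire pipeline is developed and verified against
it. See `docs/methods.md` for models, defaults, and limitations.

## Worked example

Simulate a 5-minute wild-type-like recording and analyze it:

```sh
wormcal simulate --out demo --seed 4
wormcal analyze --bf demo/sim_seed4_bf.tif --gcamp demo/sim_seed4_gcamp.tif \
        --fps 15 --out demo/out
```

which prints

```
sim_seed4_bf: 5 waves, mean interval 50.6 s, SD 2.55 s, absent=False
```

and writes `trace.csv`, `peaks.csv`, `summary.json`, `kymograph.csv`,
`kymograph.png`, `wave_geometry.csv`, and a `manifest.json` that captures
the exact configuration. For this seed the summary is

```
n_waves=5  mean_interval_s=50.65  sd_interval_s=2.55  cv=0.050
peak times (s): 55.5, 104.0, 153.9, 203.8, 258.1
```

— five waves at the generator's ~50 s period, with a regularity (SD
2.55 s) inside the healthy-DMP range, and every wave's geometry confirms
posterior initiation with full propagation:

```
wave_geometry.csv: initiation_axfrac 0.97-1.00, propagated=true for 5/5
```

The same `analyze` command runs unchanged on recorded TIFF pairs;
`wormcal compare --table cohort.csv --metric cv --pairs wt:mutant` performs
the group tests.

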