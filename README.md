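# ductokym

Kymograph-based quantification of duct contractility in time-lapse movies.

Smooth-muscle contractions of small tubular organs — here, the epididymal
duct imaged ex vivo under transmitted light — are too slow and subtle to
score reliably by watching the movie. The standard trick is the
*kymograph* ("virtual section"): fix a line across the duct, resample
every frame along it, and stack the profiles side by side. Each phasic
contraction then appears as a small spike, so frequency becomes a counting
problem, propagation becomes a latency problem, and drug effects become a
paired pre/post statistics problem. `ductokym` automates that whole chain
for physiologists who record tubular-organ motility as multi-page TIFF
stacks, and ships a movie simulator with exact ground truth so every stage
can be validated end to end.

## What it computes

* **Kymographs** — bilinear resampling of each frame along an analysis
  line (1 px steps, optional width averaging); lines can be given in a
  YAML/JSON config or auto-placed perpendicular to the estimated duct
  axis.
* **Diameter traces** — per time point, the two deepest intensity minima
  (the dark duct walls) with subpixel parabolic refinement; diameter
  `D(t)` is their distance. Baseline `B(t)` is a 60 s running median and
  the noise level a sigma-clipped `1.4826 · MAD` of `D − B`.
* **Contraction events** — local minima of the smoothed diameter with
  prominence `B − D ≥ max(3 σ_noise, 0.03 · B)` and spacing
  `≥ 3 s`; frequency in a window `[a, b)` is `60 · N / (b − a)` beats/min.
* **Peristaltic waves** — rank-matched event times regressed on axial
  station; speed = 1/slope, with a "global" classification when the
  latency is below what half a frame interval across the span can
  resolve.
* **Luminal flow** — frame-to-frame cross-correlation of the centerline
  intensity profile; the cumulative displacement splits into a net drift
  (Theil–Sen fit) and a pendular oscillation amplitude.
* **Drug-epoch statistics** — frequency in paired 2-minute windows
  (pre-window ending at each addition, post-window starting 10 s after),
  compared across duct segments with a tie-corrected Friedman test
  (`Q = [12/(nk(k+1)) Σ R_j² − 3n(k+1)] / C`) and Dunn's post hoc
  (`z = ΔR̄ / √(k(k+1)/6n)`), Bonferroni- or Holm-adjusted, with an
  exact-permutation p-value available for small tables.

## Worked example

```sh
ductokym demo --out demo/
```

simulates the `fig1` preset — 240 s at 1 frame/s, global contractions
every 8.0 s (amplitude 0.2, seed 42) — and runs the full analysis. It
prints:

```
line T1 (col 48): 7.50 beats/min
line T2 (col 96): 7.50 beats/min
line T3 (col 143): 7.50 beats/min
ground truth: 7.50 beats/min
```

Three virtual sections at different axial positions all report
60/8 = 7.50 beats/min: because the contractions encompass the whole
segment, the placement of the section does not matter. `demo/` also
contains the kymograph images, the event CSV (one row per contraction:
`line_id, time_s, prominence_px, width_s, axial_station_col`), the
per-line frequency table, wave/flow JSON, and a diameter-trace plot per
line with the detected spikes marked.

### Simulator presets

| preset | contents |
| --- | --- |
| `fig1` | 240 s, 1 frame/s, global pulses every 8.0 s (7.5 beats/min), amplitude 0.2, seed 42 |
| `peristaltic` | 120 s, 7 frames/s, wave speed 50 px/s from the left edge |
| `pendular_flow` | 12 luminal particles oscillating 5 px (10 s period), zero net drift |
| `net_flow` | 12 particles drifting at 2 px/s |
| `drug_response` | 600 s; interval 8 s → 20 s at t = 300 s ("sildenafil 5 uM"), i.e. 7.5 → 3.0 beats/min |

Every preset writes a 16-bit multi-page TIFF plus a JSON sidecar holding
the frame interval and the full ground truth (per-station contraction
onsets, per-epoch frequencies, wave speed, net flow):

```sh
ductokym simulate --preset fig1 --out movies/ [--seed N] [--param k=v]
```

The other subcommands (`kymo`, `detect`, `wave`, `flow`, `stats`, `run`)
mirror the library stages one to one; `ductokym --help` lists them.

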