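# lcrtrack

Detection, classification and tracking of **Local Ca Releases (LCRs)** in
time series of 2D submembrane [Ca²⁺] frames.

Sinoatrial-node pacemaker cells discharge Ca²⁺ from the sarcoplasmic
reticulum in spatially localized events under the cell membrane during
diastole. These releases activate the electrogenic Na⁺/Ca²⁺ exchanger and
thereby accelerate diastolic depolarization — they are part of the cell's
pacemaking machinery. Unlike the stereotyped Ca²⁺ sparks of ventricular
myocytes, LCRs propagate, **merge**, **separate**, and carry **multiple
release peaks**, so classic single-threshold spark detectors cannot
characterize them. `lcrtrack` implements a hierarchical intensity-binning
detector and an overlap-based tracker designed for exactly this phenomenology,
together with the per-event and ensemble statistics needed to compare release
behaviour across conditions (e.g. SR Ca²⁺ pumping rates).

## The method

**Single-frame segmentation.** For each frame *f* (a 2D matrix of [Ca] per
100 nm voxel, in μM) an intensity increment

&nbsp;&nbsp;&nbsp;&nbsp;Δ = (max f − mean f) / n_bins&nbsp;&nbsp;&nbsp;(n_bins = 50)

slices the frame into nested Boolean *intensity bins*: Bin *i* contains the
voxels with [Ca] > mean + Δ·(i−1). The lowest bin (level = frame mean)
separates releases from background; each of its connected components
(4-connectivity) is one **LCR image**. Local intensity maxima inside an image
(8-neighbourhood, equal-valued plateaus counted once) are its **peaks**; an
image with ≥ 2 peaks is **complex**. The **signal mass** of an image is
Σ [Ca] (nmol/L) × V_voxel, with V_voxel = (100 nm)³ = 10⁻¹⁸ L.

**Tracking.** Images in consecutive frames pair when their lowest-bin
footprints share at least one voxel. A dynamic LCR is built from these pairs:

* an unpaired current image is a **birth**;
* a current image claimed by ≥ 2 tracks is a **collision** — the track whose
  previous-frame image has the largest signal mass survives, the others are
  terminated *by collision* (collisions take priority over separations);
* one previous image feeding ≥ 2 current images is a **separation** — the
  track continues with multiple **threads**, and it dies only when *all* its
  threads have ended;
* a track with no surviving pair dies *by stochastic attrition*; a track
  reaching the last frame is *alive at end*.

An LCR containing ≥ 1 complex image is a **complex LCR**; otherwise simple.

**Statistics.** Per LCR: signal mass (Σ image masses × Δt, nmol·ms), path
area (union of all voxels ever occupied, μm²), max amplitude (μM), duration
((last − birth + 1)·Δt, ms), birth time from the window start (ms), thread
and separation counts, termination type. `summarize()` aggregates per class
(all / complex / simple) with histograms of birth time and signal mass.

**Diastolic window.** Given a membrane-potential trace, the analysis window
runs from the maximal diastolic potential (MDP) to the first upward crossing
of −50 mV (L-type channel activation threshold).

**Synthetic ground truth.** `lcrtrack.synth` renders scripted Gaussian-blob
events over an exponentially decaying background and exports exact ground
truth (births, deaths, footprints, scheduled merges/splits), so the whole
pipeline is testable without microscope or simulation data.

## Worked example

```bash
python - <<'EOF'
from lcrtrack import synth
sc = synth.Scenario(height=32, width=32, n_frames=10, b_rest=0.05, b0=0.05,
                    tau_ms=1e9, events=[synth.EventScript(
                        event_id=0, birth_frame=1, end_frame=8,
                        row=16, col=16, amplitude=3.0, sigma=3.0)])
sc.save("scenario.json")
EOF
lcrtrack synth scenario.json --out synth_out
lcrtrack track synth_out/stack.tif --out track_out
```

prints

```
10 frames, 1 events -> synth_out
1 LCRs (0 complex) -> track_out
```

and `track_out/summary.json` contains (abridged)

```json
{"per_class": {"all": {"count": 1,
  "total_signal_mass_nmol_ms": 6.78e-12,
  "avg_path_area_um2": 1.69,
  "avg_max_amplitude_uM": 3.05,
  "avg_duration_ms": 40.0}}}
```

— one simple LCR: a 3 μM blob on a 0.05 μM background (detected amplitude
3.05 μM), alive 8 frames × 5 ms = 40 ms, occupying 169 voxels of the
supra-mean footprint (1.69 μm²), with total signal mass ≈ 6.8 × 10⁻¹² nmol·ms.
`track_out/` also holds the per-LCR metrics table, the track table, the
event log, and the exact run configuration.

The same pipeline is available as library calls
(`track_stack`, `compute_metrics`, `summarize`).

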