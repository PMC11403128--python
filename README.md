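# emgvestal — EMG-projected MEG source imaging

`emgvestal` localizes movement-coupled primary motor cortex (M1) activity from
continuous, un-averaged MEG recordings. Instead of averaging over trials, it
projects the band-filtered MEG sensor matrix **B** (M sensors × T samples)
onto a bank of delayed, normalized surface-EMG copies

    E = [ e(t + d₁); … ; e(t + d_D) ],   d ∈ [−100, 0] ms (1-ms steps, D = 101)

giving the EMG-projected data **F = B Eᵀ** (M × D). Brain activity
synchronized with the muscle at some lag in the pre-movement window survives
this projection; everything else averages out. The dominant spatial modes
u_i s_i of F (from its SVD, count κ chosen against the empty-room noise
floor) are then imaged by a depth-weighted, rotation-invariant group-sparse
minimum-L1-norm inverse (Fast-VESTAL), solved as a second-order cone program:
with the gain SVD G = U_G S_G V_Gᵀ,

    minimize   Σⱼ ωⱼ √( Σᵢ h²ᵢⱼθ + h²ᵢⱼφ )
    subject to ‖ S_G V_Gᵀ hᵢ − U_Gᵀ uᵢ sᵢ ‖₂ ≤ εᵢ ,   i = 1…κ

where ωⱼ are depth weights from diag(V_G V_Gᵀ) and the two tangential dipole
orientations (θ, φ) per grid node are grouped so the solution does not depend
on the dipole's orientation in its tangent plane. Per-node magnitudes
A = diag(H Hᵀ) (aggregated over each node's orientation pair) and
max-across-delay maps are thresholded at 1.5× the maximum magnitude the
identical chain produces on empty-room data (saturation at 3.0×).

The package ships the full pipeline — conditioning, band filtering (delta
1–4, theta 4–7, alpha 8–12, beta 15–30, gamma 30–90, upper-gamma 60–90 Hz),
noise whitening, projection, the GSOCP solver, thresholding and peak
scoring — plus an analytic single-sphere forward model, an HDF5 import path
for externally computed lead fields, and a synthetic MEG+EMG
corticomuscular-coupling simulator so everything is testable without
recordings.

## Worked example

```python
import warnings
from emgvestal import (scenario_presets, simulate_dataset, default_geometry,
                       reduce_orientations, sphere_leadfield)
from emgvestal.evaluate import PipelineConfig, run_pipeline

grid, sensors = default_geometry()            # ~700-node grid, 102 magnetometers
lf = reduce_orientations(sphere_leadfield(grid, sensors), grid, sensors)

scn = scenario_presets(seed=0, side="right")["healthy_multiband"]
data = simulate_dataset(scn, grid, sensors, lf)   # 60 s, ~1 Hz finger movement

cfg = PipelineConfig(bands=("delta", "theta", "gamma"))
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    res = run_pipeline(data["meg"], data["emg"], data["empty_room"], lf, grid,
                       cfg, truth_mm=data["truth"].target_coord_mm)
for band, br in res.bands.items():
    loc = br.localization
    print(f"{band:>6}: success={loc.success}  dist={loc.distance_mm} mm  "
          f"delay={loc.winning_delay_ms} ms  "
          f"map/threshold={br.image.A.max()/br.threshold.threshold:.2f}")
```

prints

```
 delta: success=True  dist=0.0 mm  delay=-59.0 ms  map/threshold=16.45
 theta: success=True  dist=0.0 mm  delay=-49.0 ms  map/threshold=37.87
 gamma: success=False  dist=None mm  delay=None ms  map/threshold=0.26
```

The simulated M1 source (coupled to the EMG in delta, theta and beta at lags
−60/−50/−40 ms) is recovered exactly in the coupled bands, with the winning
delay matching the injected lag; the gamma band — where no coupling was
injected — stays below the empty-room threshold.

A thin CLI mirrors the library: `emgvestal simulate healthy_theta -o dir`,
`emgvestal run -i dir -o out`, `emgvestal threshold`, `emgvestal evaluate`,
`emgvestal report`.

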