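# clpointer

Fiducial-free image registration for integrated correlative light and
electron microscopy (CLEM), using **cathodoluminescence (CL) pointers**.

In an integrated microscope the focused electron beam can be parked at a
commanded position `(x^E, y^E)`; the substrate luminesces there and the
spot appears on the fluorescence camera. Each such CL pointer therefore
ties a known EM coordinate to an observable FM-frame position — a
registration landmark that can be placed *anywhere*, in any number,
without depositing fiducial particles. This package implements the full
analysis chain for that idea, exercisable end-to-end on a built-in
virtual-microscope simulator:

1. **Spot localization** — sub-pixel CL-pointer centers via the
   radial-symmetry method (closed-form, no iteration), exploiting the
   circular symmetry of the pointer profile.
2. **Grid correspondence** — sorting the unordered detections into
   one-to-one pairs with the commanded beam grid (edge-based initial
   guess, iterative mutual-nearest-neighbour refinement).
3. **Similarity registration** — least squares over
   `x^F = a x^E − b y^E + t_x`, `y^F = b x^E + a y^E + t_y` with
   `a = s cosθ`, `b = s sinθ` (scale, rotation, translation; no
   reflection). Two general-position pairs already determine the fit.
4. **Distortion calibration** — the residual difference vectors
   `δ_i = (x_i^F, y_i^F) − T(x_i^E, y_i^E)` averaged over repeated pointer
   arrays give the non-linear distortion field between the frames, which
   is calibrated once and then subtracted from every registration.
5. **Overlay accuracy** — bootstrap resampling of N-pointer subsets maps
   the EM-image center repeatedly into the FM frame; the spread of the
   mapped centers is the overlay accuracy, scaling as `N^(−1/2)` and
   dropping below 5 nm near N = 9 at realistic noise.
6. **Overlay rendering** — the EM image resampled into the FM pixel grid
   with bilinear interpolation, plus blended RGB composites, all
   orchestrated by a config-driven pipeline and CLI.

Who is this for: microscopists and imaging-methods developers who want a
reference implementation of CL-pointer registration, a test bed for its
statistics, or building blocks (spot localization, similarity fitting,
point-grid matching, distortion-field calibration) for their own CLEM
pipelines.

## Worked example

Overlay accuracy versus pointer count on a simulated pool of 50
sequentially exposed 25 × 25 pointer arrays (4 µm pitch, 12 nm per-pointer
localization jitter):

```python
from clpointer import (PointerGridSpec, default_ground_truth,
                       simulate_pointer_pool, accuracy_curve)

grid = PointerGridSpec(rows=25, cols=25, spacing_px=800.0)  # 4 um at 5 nm/px
gt = default_ground_truth(seed=0, jitter_sigma_nm=12.0)
pool = simulate_pointer_pool(grid, gt, n_arrays=50)         # 31250 pairs
curve = accuracy_curve(pool, n_list=(4, 9, 16, 25, 64, 100, 256),
                       repeats=1000, seed=0)
for n, a in zip(curve.n_values, curve.accuracy_nm):
    print(f"N={n:4d}  accuracy {a:8.3f} nm")
print(f"power law: {curve.prefactor_c:.2f} * N^{curve.exponent_p:.3f}")
```

prints

```
N=   4  accuracy    7.320 nm
N=   9  accuracy    4.256 nm
N=  16  accuracy    3.135 nm
N=  25  accuracy    2.430 nm
N=  64  accuracy    1.520 nm
N= 100  accuracy    1.175 nm
N= 256  accuracy    0.742 nm
power law: 14.53 * N^-0.544
```

Each accuracy value is the per-axis-equivalent standard deviation
`sqrt((sd_x² + sd_y²)/2)` of the mapped EM-image center over 1000 random
N-pointer registrations, in nanometres. Nine pointers give 4.3 nm — a
handful of one-second beam exposures buys sub-5 nm overlay anywhere on
the sample — and the curve follows the expected `N^(−1/2)` statistics
(slightly steeper at small N, where the subset centroid wanders relative
to the probed image center; see `docs/methods.md`).

The same stages are available as a CLI:

```sh
clpointer simulate pointers --rows 25 --cols 25 --seed 0 --out-dir sim
clpointer localize sim/pointer_array.tif --expected-count 625 --out-dir run
clpointer pair run/detections.csv --rows 25 --cols 25 --spacing-px 800 --out-dir run
clpointer register run/pairs.csv --out-dir run
clpointer pipeline --config scene.yaml --out-dir overlay_out
```

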