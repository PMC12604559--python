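# palpsim

Simulation and analysis library for **bimodal robotic tactile palpation** of
tissue phantoms: Bayesian sequential palpation locates the centroid of a stiff
inclusion buried in soft tissue, and a sliding-scan segmentation stage then
traces the inclusion's boundary from that centroid. The package is aimed at
researchers prototyping active tactile exploration strategies (surgical
robotics, tactile elastography) who want a reproducible, fully synthetic
benchmark before committing to hardware.

## The problem and the model

A planar phantom contains a single hard inclusion (circle, rectangle or
horseshoe; ~5 GPa PLA) in a soft matrix (~7 kPa Ecoflex). A tactile sensor
carries a 400-µm elastic film: pressing it on the phantom compresses the film
to a residual thickness that depends on the local stiffness (≈100 µm over the
inclusion, ≈300 µm over the matrix). A reading is classed *hard* (y = 1) when
the residual thickness is at or below the calibrated threshold d_t = 150 µm.
Contact force follows Hertz theory, F = M·d^{3/2}, with a calibrated piecewise
extension for large deflections.

**Stage 1 — centroid search.** The workspace is discretized into a coarse
(5×5) and fine (50×50) lattice, x_i = x_0 + i·Δx with Δx = (x_max − x_min)/N.
The binary hardness field is modelled as a Gaussian process with a squared
exponential kernel k(x, x′) = σ²·exp(−‖x − x′‖²/2l²). After n_init random
probes, an acquisition function proposes the next probing site from the
posterior (μ, σ²); six strategies are provided: EVR, EI, UCB, LSE, ILS-UCB and
RASEC. Thresholding the posterior mean at y = 0.5 yields the predicted
inclusion mask, scored by fine-grid F1 and by the Euclidean error between the
mask centroid and the true inclusion centroid. Iterations are counted from
the first probe that lands in the lesion (the benchmark convention); total
probe counts are always reported alongside.

**Stage 2 — boundary segmentation.** From the estimated centroid, the sensor
slides outward along 4/8/12/16 equally spaced rays, one reading per 0.02 mm.
Crossing the boundary produces a derivative spike with a characteristic
polarity: negative on soft→hard entry, positive on hard→soft exit. Detected
boundary points are interpolated into a closed contour (periodic cubic spline
in polar form, or a raw polygon), giving the estimated area A, the area error
ΔA = A − A_true and the precision 1 − |ΔA|/A_true. Instead of the 6,250
A-lines per conventional rotary B scan (250 kHz / 40 fps), the sliding mode
needs a single A-line per position — a 6,249-fold reduction.

## Worked example

```python
import palpsim as ps
from palpsim.search import summarize

circle = ps.standard_phantom("circle")          # area 12.566 mm², r = 2 mm

# stage 1: UCB search, noiseless sensing, 5 seeds
table = ps.benchmark({"circle": circle}, ["UCB"], n_repeats=5, n_iter=30, seed=0)
print(summarize(table))

# stage 2: 16-ray segmentation from the true centroid
bps = ps.segment(circle, circle.true_centroid, n_rays=16)
est = ps.reconstruct(bps, mode="spline", true_area=circle.analytic_area)
print(est.area, est.area_error, est.precision)
```

The search summary prints:

```
 shape strategy  N_acq       f1  centroid_error  coverage  N_total
circle      UCB      5 0.387220        0.888310       1.0       10
circle      UCB     10 0.572564        0.654428       1.0       15
circle      UCB     15 0.715964        0.557172       1.0       20
circle      UCB     20 0.822377        0.342634       1.0       25
circle      UCB     25 0.890686        0.140369       1.0       30
circle      UCB     30 0.910654        0.096975       1.0       35
```

F1 of the predicted inclusion mask climbs towards ~0.91 by 30 sampling steps
(35 probes in total) while the centroid error falls below 0.1 mm — half a
fine-grid cell. The segmentation stage prints

```
12.566211393134159 -0.0001592212250134395 0.999987329577497
```

an estimated area of 12.5662 mm² against the true 12.5664 mm²: an area error
of 1.6·10⁻⁴ mm² and a precision of 0.99999, since the sub-sample pulse
localization pins each of the 16 boundary points to well under the 0.02-mm
ray step and the periodic spline closes the circle almost exactly.

The same stages are scriptable from the shell:

```sh
palpsim search --shape circle --strategy UCB --iters 30 --repeats 5 --seed 0
palpsim segment --shape horseshoe --rays 16 --mode spline --centroid true
palpsim pipeline --config fixtures/circle.yaml
palpsim budget --rate 250000 --fps 40
```

## Layout

- `palpsim.phantom` — phantom geometries, grids, stiffness-map normalization
- `palpsim.contact` — Hertz/calibrated force laws, virtual sensor, classifier
- `palpsim.gp` — exact GP posterior (squared-exponential kernel)
- `palpsim.acquisition` — the six acquisition strategies, initial design
- `palpsim.search` — the sequential palpation loop, metrics, benchmark
- `palpsim.sliding` — ray signals, pulse detection, contour reconstruction
- `palpsim.dataflow` — configs, CSV/JSON serialization, pipeline, fixtures
- `palpsim.cli` — `palpsim` command-line entry point

See `docs/methods.md` for modelling assumptions, parameter defaults and known
limitations.
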