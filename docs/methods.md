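# Methods

This note documents the models behind `palpsim`, the defaults and why they
were chosen, what the synthetic data does and does not emulate, and the
numerical choices that affect results.

## Phantom model

Phantoms are planar, two-material, single-inclusion bodies. Membership is a
deterministic analytic predicate (boundary inclusive); there is no stiffness
gradient at the boundary, matching cast-phantom construction where a rigid
printed part is embedded in silicone. The three standard fixtures are sized
so their analytic areas match the benchmark samples:

| shape      | geometry                                   | area (mm²) |
|------------|--------------------------------------------|-----------|
| circle     | r = 2.0 mm                                 | 12.566    |
| rectangle  | 3.6 × 2.164 mm                             | 7.790     |
| horseshoe  | annulus r ∈ [1.2, 2.2] mm, material span solved from the area | 7.880 |

The workspace is 10 mm × 10 mm centred on the inclusion — large enough to
contain every fixture with margin and chosen so the 50×50 fine grid has a
0.2-mm pitch. Grid points sit at cell corners, x_i = x_0 + i·Δx with
Δx = (x_max − x_min)/N, i ∈ [0, N−1].

The horseshoe's reference centroid is the centroid of the *material* region.
It lies inside the notch, i.e. on soft material — outward rays from it enter
the annulus (negative pulse) before exiting it (positive pulse), which is why
segmentation tracks inner and outer boundary rings separately for this shape.

Stiffness maps are normalized by subtracting the mean and dividing by the
peak-to-peak range; a constant field normalizes to zeros with a warning.

## Sensor model

The virtual sensor reports the residual thickness of a 400-µm film under a
fixed preload: 100 µm over hard material, 300 µm over soft, optionally plus
Gaussian noise truncated to [0, 400] µm. These two fixture values are a
declared choice — the physical benchmark states only the film thickness and
the 150-µm classification threshold — and straddle that threshold so that the
noiseless classifier reproduces membership exactly. A reading is hard (y = 1)
iff residual thickness ≤ 150 µm, ties classed hard: harder material
compresses the film more.

Contact force uses the calibrated 400-µm-film law: the Hertz branch
11 751.422·d^{3/2} below d = 1.85·10⁻⁴ m and a two-term Gaussian sum above
it, with the published coefficients used exactly as printed (the printed
exponential branch is written in a mixed variable x/d; we evaluate it with
d in metres). Two consequences of taking the fit literally: the branches
disagree by ~3% at the breakpoint, and the Gaussian-sum tail decreases
beyond its centres (~4.4·10⁻⁴ m), outside the calibrated loading range.
`contact.monotonicity_violations` scans for and reports these regions rather
than silently correcting the fit; the force value plays no role in search or
segmentation decisions, which consume only the thickness classification.

## Gaussian-process search

The hardness field is modelled as a zero-mean GP over the continuous
workspace with squared-exponential kernel. Observations are the *binary*
classes {0, 1} (regression on class indicators), so the 0.5 cutoff on the
posterior mean is directly the class boundary; regression on normalized
deflection is available behind `observation_scale="deflection"`.

Hyperparameters are fixed per run, no marginal-likelihood optimization:

- σ²_k = 1 — the natural scale of 0/1 observations;
- l = 0.5 mm — the length scale sets the resolution of the recovered
  boundary. A kernel at the inclusion's own scale (l ≈ 1–2 mm) blurs the 0.5
  level set by about a millimetre *no matter how many probes are spent*,
  capping fine-grid F1 near 0.8; at 0.5 mm (2.5 grid cells) the posterior
  can place the boundary to about one cell while still interpolating between
  probes a millimetre apart.
- σ²_n = 10⁻⁴ — small ridge for numerical stability and label smoothing.

The posterior uses a Cholesky factorization of K + σ²_n·I; a singular Gram
matrix (duplicate probes at zero noise) gets 10⁻⁸ diagonal jitter and a
warning. Posterior variance is clipped at zero.

Acquisition scores use the standard literature forms (EVR, EI, UCB, LSE,
ILS-UCB, RASEC — see `palpsim/acquisition.py` docstring; the benchmark treats
the family as pluggable and these reconstructions as declared choices, since
only the strategy *names* are fixed by the protocol). Defaults β = 1.96,
ξ = 0.01, h = 0.5, γ = 0.8, λ_e = 0.05 mm⁻¹, n_init = 5. RASEC's energy
constraint is modelled as a linear Euclidean travel penalty from the current
probe — an approximation of the original rescaling schedule. Candidates are
restricted to the 50×50 fine grid; visited points are masked; ties break
toward the lowest flat grid index so traces are bit-reproducible for a fixed
seed. EVR's total-variance-reduction score is computed through a low-rank
identity against a cached prior Gram matrix, avoiding an N²×N² posterior
covariance per iteration.

### Iteration counting

The benchmark clock counts sampling steps from the first probe that lands in
the lesion; the preceding random initialization and any burn-in exploration
are not counted (burn-in is capped at 30 steps). `run_search` defaults to
the simpler acquisition-step clock (`counting="acq"`, trace length exactly
n_init + n_iter); `benchmark` uses `counting="valid"` and reports both the
checkpoint step N and the total probe count N_total, so either convention
can be read off the table. Checkpoint metrics at N ∈ {5, 10, 15, 20, 25, 30}
are computed from the posterior at exactly that step. Empty-mask checkpoints
record NaN centroid error and are excluded from averages, with a coverage
column tracking how often that happened.

## Sliding-scan segmentation

The simulated sliding signal is the residual-thickness baseline with each
material transition rendered as a logistic ramp (scale 0.75 ray steps, so the
transition spans ~3 samples) centred on the *exact* geometric crossing,
located by bisection of the membership predicate. The signal's discrete
derivative therefore shows a pulse at each boundary with the physical
polarity — negative at entry, positive at exit — and the pulse peak sits at
the boundary. Lateral membrane mechanics are not modelled; what matters
downstream is the polarity-and-threshold detection logic, not the membrane
physics. Detection thresholds the per-step change (default 10 µm against a
~50 µm/step peak; a flat noiseless baseline has zero variation), groups
same-sign runs, and refines each peak by parabolic interpolation of three
neighbouring derivative samples. On noiseless signals this localizes
boundaries to well under a step; noisy signals are supported but should use a
proportionally higher threshold.

Rays default to a fan of n_rays ∈ {4, 8, 12, 16} outward rays from the
centroid at θ_k = θ_0 + 2πk/n (single boundary point per crossing); a
diametric mode scanning full chords through the centroid is available behind
`diametric=True`. The angular phase θ_0 defaults to 0 and is exposed because
polygon accuracy for rectangles depends on corner alignment.

Reconstruction orders boundary points by polar angle around the centroid and
closes them with either a raw polygon or a periodic cubic spline on r(θ)
densified to 720 vertices (the default; geometry by shapely). A
self-intersecting spline falls back to the polygon with a warning; duplicate
angles are merged. For the horseshoe, inner (entry) and outer (exit) rings
are reconstructed separately and the material area is outer − inner; rays
through the opening detect nothing and simply leave gaps, so the closed
contours chord across the opening — an inherent limit of centroid-anchored
ray segmentation on non-star-shaped material, and the main reason horseshoe
area errors exceed the convex shapes'. Precision is defined as
1 − |ΔA|/A_true throughout.

## Synthetic data: what it does and does not emulate

The generator reproduces the *decision problem* of the physical benchmark —
binary-contrast phantom geometry at the printed areas, grid-restricted
probing, threshold classification, boundary-pulse polarity — under exactly
controlled noise (default: noiseless, matching the deterministic thickness
readings of a rigid inclusion under fixed preload). It does not model OCT
speckle, film hysteresis or abrasion, probe-pose uncertainty, partial
contact at inclusion edges, or depth-dependent stiffness. Passing benchmarks
here therefore validate the algorithms' statistical and geometric behaviour,
not their robustness to instrument physics.

## Problem sizes and determinism

Benchmarks run 3 shapes × 6 strategies × 20 seeds × 30 iterations on the
50×50 grid (a few minutes on one CPU); segmentation uses a 0.02-mm ray step.
Every random quantity (initial design, sensor noise, ray noise) derives from
explicit seeds through per-stage `numpy` SeedSequence streams; identical
configs give byte-identical outputs.

## Known limitations

- Paper-scale search accuracy (mean F1 ≈ 0.98, centroid error ≈ 0.03 mm on
  the circle) is not reached under the declared defaults; the best strategy
  attains F1 ≈ 0.92 and ≈ 0.08 mm. The benchmark's noise model and GP/
  acquisition hyperparameters are not public, and the achievable ceiling is
  sensitive to them; the suite therefore enforces the robust floors
  (F1 ≥ 0.9, centroid error < 0.2 mm) and reports the paper-level
  comparison.
- Single inclusion only; no multi-lesion competition for probes.
- The horseshoe's reconstruction chords across its opening (see above).
- EVR is a space-filling criterion: at l = 0.5 mm and ≤ 45 probes it cannot
  cover the workspace and ranks last here, whereas smoother settings favour
  it — strategy rankings are hyperparameter-dependent and should be read
  qualitatively.
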