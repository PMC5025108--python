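# Methods

## Model

The detector treats every pixel of a grayscale frame as a pulse-coupled
neuron (Intersecting Cortical Model, the three-equation reduction of the
five-equation PCNN). Each neuron carries an activation F, a dynamic
threshold E and a binary pulse Y, updated in lockstep:

    F[n+1] = f·F[n] + S + (W ∗ Y[n])
    Y[n+1] = 1  if F[n+1] > E[n]  else 0
    E[n+1] = g·E[n] + h·Y[n+1]

Within one update the freshly computed F is compared against the previous
threshold (F feeds the comparator that produces Y, and Y in turn drives the
threshold update); firing requires strict inequality, so exact ties do not
fire. The link correlation W ∗ Y uses zero padding: border neurons simply
receive less linking input, and border regions are discarded downstream
anyway.

Assumptions this encodes:

- **Heads are the darkest compact blobs.** The stimulus S is the min–max
  rescaled LoG response of the frame, so stimulus rank order equals
  "blob-likeness at the head scale". Anything darker and more compact than
  the heads would be segmented instead.
- **Thresholds decay uniformly.** E starts at 5 everywhere (well above the
  stimulus range, so the first iteration never fires) and decays by g per
  step; neurons therefore fire in stimulus order, and the iteration count n
  acts as an intensity threshold selector.
- **Firing is persistent.** h < 0 pushes a fired neuron's threshold down,
  so the segmentation after n iterations is the cumulative set of neurons
  whose stimulus rank has been reached — a nested family as n grows.
- **Linking is weak and local.** The 0.01 neighbour weights let a fired
  region pull near-threshold neighbours over the line (closing anti-aliased
  head boundaries) without flooding the frame; the centre weight 1 is the
  self-feedback that makes persistence robust.

## Fitness and per-frame tuning

The four constants (f, g, h, n) are re-optimised for every frame by a
global-best particle swarm over [0, 1]⁴ with a scaling map enforcing the
network's validity region: f = 0.05 + 0.94·p₁, g = f·(0.05 + 0.9·p₂)
(so 0 < g < f < 1 by construction), h = −(0.1 + 9.9·p₃), and
n = 1 + round(4·p₄) ∈ {1…5}.

The objective is the feature-mutual-information error |MI(X; Y) − 0.07|,
with X the original grayscale frame quantised into equal-width intensity
bins and Y the candidate mask. The 0.07-bit target is the MI a *correct*
head mask attains: with ~60 heads covering ~0.9 % of a 480 × 640 frame,
H(Y) ≈ 0.07 bits, and a well-placed mask is nearly a deterministic
function of intensity class, so MI ≈ H(Y). `fitness.mi_target_from_truth`
recomputes this value for any annotated frame (it lands at 0.066–0.072 on
the synthetic scenes) should the target need re-deriving for a different
assay.

**Intensity binning is the fitness's noise floor.** With fine binning
(e.g. 256 bins) a mask that adds locally-dark *background* pixels remains
"informative" — sensor noise and illumination structure masquerade as
signal — and the |MI − 0.07| landscape develops near-zero minima at masks
several times larger than the true foreground. The default of 4 equal
bins makes the bin width (0.25) exceed both the noise scale (σ ≈ 0.02)
and the within-class illumination spread (≈ 0.2), so the histogram
separates intensity *classes* (head ≈ 0.35, debris/tail ≈ 0.55–0.6,
background ≈ 0.65–0.85) and junk-padded masks lose MI steeply. The bin
count is exposed in `FitnessConfig` for assays with different class
structure.

Swarm settings: population 50, c₁ = c₂ = 2, inertia ω(t) = 0.9 − 0.5·t/t_max,
velocity clamped at 0.25 per dimension (the search box is the unit cube),
positions clipped to [0, 1]. Personal/global bests are replaced only on
strict improvement, so the convergence trace is non-increasing. The search
stops when the best error reaches the tolerance (default 0.005 bits) or
after max_iterations = 15 sweeps beyond the initial evaluation; in
practice the target is typically reached within the first one or two
sweeps, and the ceiling only bounds the cost of frames whose best
reachable MI sits just outside the tolerance. All randomness flows from
`SwarmConfig.seed`, making a run bit-reproducible.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| `log.sigma` | 1.5 | px | zero-crossing ring σ√2 ≈ 2.1 px ≈ head semi-minor axis; matching the narrow axis keeps the LoG valley between touching heads deep enough to separate agglutinated pairs, while still averaging sensor noise |
| `log.kernel_radius` | ceil(3σ) | px | captures >99 % of kernel mass |
| `icm e_init` | 5 | — | above any reachable first-step activation (S ≤ 1) |
| `fitness.mi_target` | 0.07 | bits | MI of a correct head mask (see above) |
| `fitness.intensity_bins` | 4 | — | bin width above noise and illumination spread |
| `fitness.tolerance` | 0.005 | bits | ~7 % of the target; tighter values buy nothing because frame-to-frame variation of the *achievable* MI is larger |
| `pso.population` | 50 | — | standard swarm size for a 4-dimensional search |
| `pso.max_iterations` | 15 | — | convergence ceiling; typical runs stop after 1–3 sweeps |
| `pso.h_range` | (0.1, 10) | — | magnitude ≥ 0.1 keeps refiring reliable; ≤ 10 keeps E finite-scaled |
| `features.connectivity` | 8 | — | compact blobs; avoids splitting anti-aliased edges |
| `features.border_margin` | 1 | px | partial heads at the frame edge give misleading centroids |
| `features.min_area` | 0 (off) | px | debris is rejected by intensity, not size; opt-in speck filter |

## Synthetic scenes

`spermseg.synthetic` emulates the target assay: 480 × 640 frames, 60
heads drawn as filled rotated ellipses (semi-axes 2–4 × 3–6 px) at
intensity 0.35 on a 0.75 background modulated by a tilted plane plus
Gaussian vignette (amplitude 0.1), 1-px random-walk tails at 0.6, 15
debris disks at 0.55, 10 % of heads as head-to-head agglutinated pairs
(anterior tips in contact, major axes roughly collinear — the canonical
head-to-head agglutination geometry; tails point away from the junction),
and optional additive Gaussian noise. The truth mask contains head pixels
only; debris and tails are clutter to reject. Head placement is
rejection-sampled so non-pair heads never touch.

What the generator does *not* emulate: phase-contrast halo optics, motion
blur of fast cells, out-of-focus depth layers, intensity texture inside
heads, and frame-to-frame temporal coherence. Passing the synthetic
benchmark therefore demonstrates the algorithm's behaviour under the
assay's *geometry and contrast statistics*, not its performance on any
particular microscope's output; on real data the MI target and σ should
be checked with `mi_target_from_truth` and a pilot frame.

## Numerical choices and degenerate inputs

- Convolution border handling: reflect padding for the LoG (avoids a
  spurious dark frame), zero padding for the link kernel.
- A constant LoG response (blank frame) rescales to uniform 0.5; the
  network then pulses uniformly and the border filter leaves at most one
  frame-filling region — a blank frame yields ≤ 1 detection, not an error.
- Metrics with zero denominators are reported as NaN with a warning,
  never silently as 0; batch means are NaN-aware.
- Batch evaluation reports both the unweighted per-image mean (headline)
  and pooled-count metrics, which differ whenever foreground fractions
  differ across frames.
- Detection matching is greedy nearest-neighbour, one-to-one, ties broken
  by row-major order of the truth point then of the prediction.
- 16-bit inputs are scaled by 65535, 8-bit by 255, keeping S in [0, 1].

## Design choices where the design was open

- **Mask convention:** the segmentation is Y at the final iteration (the
  cumulative fired set), not a union of pulse snapshots; the fitness is
  responsible for selecting an n at which heads, not background, have
  fired.
- **Update order:** Y compares the *new* F against the *old* E. The
  alternative (old F vs old E) merely delays every firing by one step.
- **Evaluation mask:** pixel metrics score the border-filtered mask — the
  regions the detector actually asserts — while the raw pulse image stays
  available for diagnostics.
- **Per-frame optimisation** (no warm start): frames are treated as
  independent; a warm-start option for video is a possible extension.

## Known limitations

- The MI fitness is a single scalar: masks of very different quality can
  tie. The coarse intensity binning removes the worst degeneracy, but on
  frames whose background has head-like intensity texture the fitness
  could still be misled.
- Agglutinated pairs in side-to-side contact (necks 3–5 px thick) are not
  separable by any intensity threshold, and the pulse network inherits
  that limit; separation works for tip-contact pairs, where the LoG
  valley at the junction is deep (~73 % of pairs on the synthetic
  benchmark).
- Sensitivity to noise collapses once σ approaches the head–background
  stimulus gap (σ ≳ 0.05 at default contrast): the LoG band-pass amplifies
  pixel noise and the background's upper stimulus tail crosses into the
  head range (see `examples/06_noise_robustness.py`).
- Runtime is dominated by fitness evaluations (each runs the network on
  the full frame); a frame takes a few seconds at the default budget on
  one core.
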