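# spermseg

Automatic sperm-head detection in phase-contrast microscopy frames, for
computer-assisted sperm analysis (CASA) pipelines that need the position of
every sperm nucleus in a 480 × 640 frame containing ~60 cells — including
rotated or distorted heads, debris that must be rejected, and agglutinated
(stuck-together) cells that must be resolved into separate heads.

## Method

The detector couples three classical ingredients:

1. **Laplacian-of-Gaussian (LoG) enhancement.** The frame is converted to
   grayscale and convolved with

   `LoG(x, y) = −(1/πσ⁴) · [1 − (x²+y²)/(2σ²)] · exp(−(x²+y²)/(2σ²))`

   whose "Mexican hat" profile matches a compact dark head. The response is
   min–max rescaled to [0, 1] and becomes the stimulus image *S*: head
   centres carry the highest stimulus, flat background sits mid-scale, and
   smooth illumination gradients are cancelled.

2. **Intersecting Cortical Model (ICM) segmentation.** A reduced
   pulse-coupled neural network iterates, per pixel,

   ```
   F[n+1] = f·F[n] + S + (W ∗ Y[n])      feeding / internal activation
   Y[n+1] = 1 if F[n+1] > E[n] else 0    pulse
   E[n+1] = g·E[n] + h·Y[n+1]            dynamic threshold
   ```

   with link kernel W (4-neighbours 0.01, centre 1), decay factors
   0 < g < f < 1, negative threshold amplitude h, and E initialised at 5 so
   nothing fires immediately. Thresholds decay geometrically, so neurons
   fire in order of stimulus: there is an iteration count *n* at which
   exactly the heads have pulsed. The pulse image Y[n] is the segmentation.

3. **Per-image parameter tuning by PSO.** The four free constants
   (f, g, h, n) are chosen per frame by a global-best particle swarm
   (population 50, c₁ = c₂ = 2, inertia ω(t) = 0.9 − 0.5·t/t_max) that
   minimises the *feature mutual information* error |MI(X; Y) − 0.07|,
   where X is the original grayscale frame and Y the candidate mask. A
   correct head mask is small (~1 % of the frame) yet highly predictive of
   intensity, which pins its MI near 0.07 bits.

Detections are then the centroids of the connected components of Y[n],
after discarding components that touch the frame border. Evaluation
against ground-truth masks uses pixel-level accuracy, sensitivity,
specificity and precision.

A synthetic-scene generator (`spermseg.synthetic`) renders frames with the
same statistics as the real assay — dark elliptical heads on a brighter
non-uniform background, thin tails, debris, head-to-head agglutinated
pairs, optional Gaussian noise — together with exact ground-truth masks
and centre lists, so the whole pipeline is testable without annotated
data.

## Worked example

```sh
python examples/04_full_pipeline_detection.py
```

```
swarm picked        : f=0.754 g=0.163 h=-7.98 n=2
fitness (|MI-0.07|) : 0.00873 after 800 evaluations
mask MI             : 0.0613 bits
pixel metrics       : accuracy=0.9987  sensitivity=0.9715  specificity=0.9989  precision=0.8805
object level        : 58/60 heads found, 2 missed, 120 spurious
with min_area=4     : 58 matched, 30 spurious, precision=0.9406
```

The swarm settled on a 2-iteration network whose mask reaches an MI of
0.061 bits against the frame; 58 of 60 planted heads are recovered with
sub-head-radius centroid accuracy. The spurious entries are 1–3 px
specks; the opt-in minimum-area filter removes most of them.

The other scripts in `examples/` each demonstrate one capability: scene
generation, LoG enhancement margins, single-neuron pulse dynamics, swarm
convergence traces, and noise robustness.

## Command line

```sh
spermseg synth   --out data/ --count 5 --seed 1          # synthetic frames + truth
spermseg segment --in 'data/image_*.png' --out seg/ --seed 7
spermseg tune    --image data/image_0.png --out tune/    # swarm search only
spermseg evaluate --pred 'seg/*_mask.png' --truth 'data/mask_*.png' --out report.json
```

Masks are 8-bit PNGs ({0, 255}); centroids are CSV (`id,row,col`, 0-based,
row increasing downward); metric reports are JSON.

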