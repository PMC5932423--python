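# Methods

`prosthevis` implements a dual-spectrum (visible + thermal-IR) scene
optimization chain for retinal prosthesis front-ends, plus the optogenetic
stimulus encoding and percept simulation needed to evaluate it objectively.
This note documents the models, the parameters that matter, and the design
choices made where the problem was genuinely open.

## Processing model

### IR decision map

A microbolometer frame `I` (bytes 0–255, gain-mapped from a declared
temperature range, default 0–40 °C) is stretched exponentially together with
its photographic negative,

    I_e  = exp(0.025 · I),      I_Ne = exp(0.025 · (255 − I)),

and recombined with a second exponential,

    IR_map = exp(0.025 · (I_e + I_Ne)),

which suppresses mid-scale (ambient) pixels and boosts both hot and cold
extremes. The raw map is Gaussian-smoothed (reflect padding; σ defaults to
2 % of the shorter frame side, clamped to ≥ 1 px) and min–max normalized to
[0, 1]. The construction is *exactly* invariant under byte inversion
`I ↦ 255 − I`, which is the formal statement of "hot and cold objects are
equally important"; the test suite asserts this bit-exactly. The largest
exponent reachable from byte input is 0.025·(e^6.375 + 1) ≈ 14.7, so the
computation is safely finite in float64 (this is checked, not assumed).
Normalization happens once, after smoothing. A constant frame has zero
dynamic range and normalizes to an all-zero map with a warning.

### Visible-scene simplification

Anisotropic (edge-stopped) diffusion iterates

    I^{n+1} = I^n + Δt · div( C · ∇I^n ),   C = 1 / (1 + |∇_H|² + |∇_V|²),

with 3×3 Sobel gradients recomputed from the current iterate and the
conservative forward/backward-difference divergence. With `C ∈ (0, 1]` and
`Δt ≤ 0.25` every update is a convex combination of a pixel and its four
neighbours, so the scheme obeys a discrete maximum principle (output range
never leaves input range); `Δt` above the stability bound is rejected.
Defaults: Δt = 0.2, 15 iterations — enough to flatten texture at the tested
frame sizes while strong edges stay put.

Luminance is then soft-quantized with evenly spaced bins (Δq = 1/n_bins):

    Q = q_nearest + (Δq/2) · tanh(φ_q · (I − q_nearest)).

The tanh bounds every pixel to half a bin of its nearest centre. Note that
for large φ_q the saturated values `q ± Δq/2` coincide with the *bin
boundaries*, so a smooth ramp collapses onto the n_bins + 1 boundary levels;
the defaults (n_bins = 8, φ_q = 20) give visibly discrete but soft plateaus.
The cartoon is `(1 − |∇I_S|_norm) · Q` (dark contours at strong edges), and
the edge-weighted rendering multiplies the cartoon by
`W = max(|∇I_S|_norm, K)` with floor K = 0.25 by default: K tunes how much
non-edge background survives.

### Fusion

The decision map is a per-pixel convex blend weight:

    fused_edge    = seg · visible + (1 − seg) · edge_weighted
    fused_cartoon = seg · cartoon + (1 − seg) · visible

The two lines are deliberately asymmetric (thermally extreme regions keep
the raw visible scene in the first, the cartoon in the second); both are
exposed and both endpoint/convexity identities are tested. The reverse
modality (`ir_cartoon`) diffuses the thermal image itself — absolute
intensity is the signal there, so no quantization — and overlays the
*visible* scene's normalized gradient as contours.

Because the smoothed, min–max-normalized map saturates near (not exactly
at) 1 inside objects, the fused image tracks the object-side source to
about 0.02 in deep interiors rather than to one byte level; far background,
where the map decays to exactly 0, matches the background-side source
bit-exactly.

### Retargeting

Per-pixel importance is `M = |∇I_processed|_norm + seg`, floored at 1e−3 so
its reciprocal is bounded. For each line and a shrink amount of K pixels,

    S(j) = K · (1/M(j)) / Σ_j (1/M(j)),       Σ_j S(j) = K exactly,

and pixel j's unit width contracts to `1 − S(j)`. Lines are resampled with
a continuous forward area-weighted map (Fant resampling): output pixel k
averages the input pixels whose shrunk intervals overlap [k, k+1). Since
the widths tile the output exactly, constants are preserved and flat
importance reduces to a uniform (linear) rescale — both proved against an
independent brute-force overlap oracle in the tests.

Columns are removed first, then rows (single pass; the difference is
second-order at 30 % shrink). Per-row S fields are smoothed across rows
(σ = 1 px) to avoid row-to-row jitter, renormalized to sum K, and capped
below 1 with the residual redistributed by a short waterfilling loop so the
cumulative map stays monotone. On the reference disk fixture a 30 % shrink
in both directions retains 92–99 % of the hot disk's diameter (measured as
continuous row mass, which resampling preserves) while the frame itself
loses the full 30 %.

### Encoding

Three stimulation scenarios are covered. Cone drive is the processed
intensity image. Bipolar drive is a centre–surround difference of Gaussians
(σ_center = 1 px, σ_surround = 2 px at stimulator resolution) rectified
into ON (`max(D, 0)`) and OFF (`max(−D, 0)`) pathways, with `|on − off|`
as the single-pathway approximation. RGC spiking uses one Izhikevich neuron
per stimulator,

    v' = 0.04 v² + 5 v + 140 − u + I,   u' = a (b v − u),

with the canonical regular-spiking constants (a = 0.02, b = 0.2, c = −65,
d = 8; no constants are dictated by the problem, so the standard published
set is used), explicit Euler at 0.5 ms from the stable rest (v = −70 mV),
`I = 20 · drive`, over a 100 ms frame window (chosen so the 50 ms
channelrhodopsin recovery memory spans multiple events). Firing rate and
first-spike latency are monotone in drive over a 10-point ramp (tested);
the lowest ramp drives are subthreshold and never fire.

ChR2 pulse rule: a spike with no predecessor within the previous 50 ms
gets a 5 ms pulse (dark-adapted channels); a spike whose predecessor fell
strictly within 50 ms gets 10 ms (light-adapted). A gap of exactly 50 ms
counts as recovered. "Previous stimulus" is read as the previous spike
time, which matches the enumerated rule cases; a spike arriving while the
previous pulse is still on emits no new command, so widths remain exactly
{5, 10} ms and pulses never overlap per stimulator.

Time-to-first-spike decoding maps latency linearly to brightness
(`1 − t_first/duration`, silent stimulators black); on the disk fixture the
reconstruction's Spearman correlation with the drive exceeds 0.9.

### Percept simulation

The image is area-averaged onto the n×n stimulator grid and each
stimulator rendered as a Gaussian phosphene (σ = 0.4 of the pitch) at its
centre. The canvas is flat-field normalized — the blurred drive comb is
divided by the blurred all-ones comb — so a constant drive renders exactly
constant and the comb modulation cancels at dense arrays. This makes the
percept-fidelity metric (below) genuinely monotone in array size.

## Evaluation

The recognition-enhancement metric is `100 · (N_en/N_ac − 1)` for
recognition counts with/without processing; it is exercised only on
closed-form inputs (doubling recognition is exactly +100 %). Human
recognition itself is replaced by fixture-based proxies computed by
`array_sweep`:

- **iou** — best-threshold silhouette IoU between the percept and the
  ground-truth object mask (threshold swept over intensity quantiles; using
  the best threshold makes the score a property of the image, not of a
  thresholding heuristic);
- **contrast** — normalized inside/outside object contrast;
- **fidelity** — Pearson correlation between the percept and the
  full-resolution processed scene.

On the reference fixtures the edge-weighted mode beats the raw scene on
silhouette IoU at 16×16 (≈ 0.75 vs ≈ 0.70 on the disk scene) and fidelity
increases monotonically with array size for every mode. The cartoon-fused
mode — which by construction keeps the raw textured background — scores
*below* raw on the silhouette proxy; this is a real property of the printed
blend, not a defect, and is why the low-resolution regime favours the
edge-weighted rendering.

## Synthetic scenes

The generator emulates an optically co-registered camera pair: visible =
mid-gray background with band-limited texture (amplitude 0.08) plus flat,
mildly shaded geometric objects; IR = ambient plateau (20 °C) plus
per-object temperature plateaus gain-mapped to bytes with additive Gaussian
sensor noise of 1 byte level (no published sensor model exists for the
degenerate-retina context, so a minimal additive model is used). Fixtures
are bit-deterministic in their seed and carry ground-truth masks. What they
do *not* emulate: cluttered natural texture statistics, thermal gradients
within objects, motion, optical blur, or registration error — so passing
tests demonstrate the algorithms' contracts and relative ordering of
processing modes, not field performance on natural scenes.

Problem sizes used throughout the tests and the acceptance script (96–128
px frames, 16–128 stimulator grids, 100–200 ms spike windows) were chosen
as the smallest sizes at which every stage's behaviour is clearly resolved.

## Known limitations

- Registration is assumed solved optically; only a resize-to-common-grid
  helper is provided.
- The decision map is continuous, not a label image; no per-object
  segmentation or temperature calibration is attempted.
- Video is processed frame-independently (no temporal derivative channel,
  no optic-flow background subtraction for a moving camera).
- The cone-pathway pulse coding reuses the intensity-driven spike→pulse
  mechanism; a dedicated LED intensity-coding scheme is not specified by
  the underlying model and is left open.
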