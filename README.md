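# prosthevis

Dual-spectrum (visible + thermal-infrared) scene optimization for retinal
prosthesis, with optogenetic stimulus encoding and percept simulation.

Current retinal prostheses deliver on the order of 10²–10³ stimulation
sites, so users perceive coarse phosphene patterns in a narrow visual
tunnel. At that resolution, texture is noise: the useful strategy is to
decide *what* in the scene matters, simplify everything else away, and
spend the few available pixels on the objects that matter. Thermal imaging
is a strong cue for that decision — people, hot drinks and cold objects
stand out from ambient temperature regardless of visible contrast.

`prosthevis` is for researchers building or simulating prosthetic-vision
front-ends. It implements, as composable library modules with a thin CLI:

- **IR decision map** — exponential stretch of the thermal frame and its
  negative, `IR_map = e^{0.025(I_e + I_Ne)}` with `I_e = e^{0.025 I}`,
  `I_Ne = e^{0.025(255−I)}`, Gaussian-smoothed and normalized: hot *and*
  cold extremes map toward 1, ambient toward 0 (exactly symmetric under
  `I ↦ 255−I`).
- **Cartoonisation** — edge-stopped (Perona–Malik-type) diffusion
  `I^{n+1} = I^n + Δt·div(C ∇I)`, `C = 1/(1+|∇I|²)`; soft luminance
  quantization `Q = q + (Δq/2) tanh(φ_q (I−q))`; dark edge overlay and a
  multiplicative edge-weight matrix `W = max(|∇I|_norm, K)`.
- **Fusion** — the decision map as a per-pixel convex blend between raw
  and simplified renderings of the scene.
- **Nonlinear retargeting** — per-line shrinkability
  `S(j) = K·(1/M_j)/Σ(1/M_j)` from an importance matrix
  `M = |∇I_processed| + IR_map` (so `ΣS = K` exactly), applied by
  continuous area-weighted (Fant) resampling: background absorbs the
  compression, key objects keep their size.
- **Encoding** — ON/OFF bipolar split (difference of Gaussians),
  Izhikevich regular-spiking neurons per stimulator, and channelrhodopsin-2
  pulse scheduling: 5 ms pulses for dark-adapted (isolated) spikes, 10 ms
  when a predecessor fell within the 50 ms recovery window.
- **Evaluation** — percept simulation at 16×16…128×128 arrays, silhouette
  IoU / contrast / fidelity sweeps, and the recognition-enhancement metric
  `100·(N_en/N_ac − 1)`.

A deterministic synthetic scene generator (textured visible channel plus
gain-mapped thermal plateaus with ground-truth masks) stands in for the
two-camera rig, so everything is testable end to end without hardware.

## Worked example

```python
import numpy as np
import prosthevis as pv
from prosthevis.retarget import importance_matrix, retarget
from prosthevis import segmentation, simplify, fusion, encode, evaluate

fix = pv.standard_scene(seed=0)                     # 128x128 visible/IR pair
seg = segmentation.segment(fix.ir)                  # IR decision map
stages = simplify.simplify_chain(fix.visible)       # diffuse/quantize/cartoonise
fused = fusion.fuse_edge_weighted(seg, fix.visible, stages["edge_weighted"])

m = importance_matrix(simplify.gradient_magnitude(fused), seg)
small = retarget(fused, m, 38, 38)                  # 30% shrink per axis
print(f"retargeted frame: {small.width}x{small.height}")

person = fix.masks[0][1] | fix.masks[1][1]          # body + head ground truth
print(f"decision map on person: {seg.values[person].mean():.2f}, "
      f"background: {seg.values[~fix.object_mask()].mean():.2f}")

table = evaluate.array_sweep(fix, [16, 32], ["raw", "edge"])
print(table.round(3).to_string(index=False))

drive = np.clip(encode.box_resample(small.pixels, (16, 16)), 0, 1)
spikes = encode.izhikevich_spikes(drive)
pulses = encode.chr2_pulse_schedule(spikes)
n_spikes = sum(t.size for t in spikes.trains)
n_long = sum((p[:, 1] == 10.0).sum() for p in pulses.pulses)
n_short = sum((p[:, 1] == 5.0).sum() for p in pulses.pulses)
print(f"spikes: {n_spikes}, pulses: {n_short} short (5 ms) + {n_long} long (10 ms)")
```

prints

```
retargeted frame: 90x90
decision map on person: 0.83, background: 0.02
 size mode   iou  contrast  fidelity
   16  raw 0.606     0.081     0.789
   32  raw 0.646     0.093     0.903
   16 edge 0.631     0.563     0.968
   32 edge 0.666     0.608     0.993
spikes: 218, pulses: 98 short (5 ms) + 119 long (10 ms)
```

Reading this: the warm person saturates the IR decision map (0.83) while
the thermally ambient background is suppressed (0.02); a 30 % shrink in
both directions takes the frame to 90×90 while the importance field keeps
the person's geometry (see `tests/` for the quantitative claim); at a
16×16 array the edge-weighted rendering holds more object contrast (0.563
vs 0.081) and a higher-fidelity percept than the raw scene; and the spike
train's pulse schedule uses only the two channelrhodopsin widths, long
pulses appearing exactly when spikes arrive inside the 50 ms recovery
window.

The same chain is available from the shell:

```sh
prosthevis fixture --seed 0 --out fx/
prosthevis run --out run/                 # 10 stage artifacts + manifest.json
prosthevis ir-segment --ir fx/ir.png --out map.png
prosthevis retarget --in fx/visible.png --ir fx/ir.png --shrink 0.3 --out small.png
prosthevis evaluate --fixture-seed 0 --sizes 16,32 --modes raw,edge --out report.csv
```

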