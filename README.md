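# dgfseg — double geo-vector flow tongue segmentation

Automatic segmentation of the tongue body in face/tongue photographs,
for quantitative tongue diagnosis pipelines (traditional Chinese
medicine tongue inspection) and for anyone who needs a reproducible,
fully tested implementation of the *double geo-vector flow* (DGF)
family of active-contour methods.

## The method

The tongue protrudes below the two mouth corners ("angular points"),
whose row `sline` splits the problem in two:

* **Lower boundary** (mouth corners → tongue tip). A level-set field Φ,
  initialized piecewise-constant (−ρ inside an enclosing arc through
  the corners and tip, 0 on it, +ρ outside), evolves under the
  distance-regularized geodesic flow

  ```
  ∂Φ/∂t = μ[ΔΦ − div(∇Φ/|∇Φ|)] + λ δ(Φ) div(g ∇Φ/|∇Φ|) + ν g δ(Φ),
  g = 1 / (1 + |∇(G_σ * I)|²)
  ```

  with updates restricted to rows at or below `sline`. The curve can
  only shrink, and the edge indicator `g` halts it on the tongue/skin
  boundary. No re-initialization is ever needed (the μ-term keeps Φ
  close to a signed distance function).

* **Upper boundary** (mouth corners → tongue root). The upper crop is
  binarized to isolate the dark mouth-opening strip B; its gradient
  vector flow

  ```
  ∂V_B/∂t = w ∇²V_B − |∇B|² (V_B − ∇B)
  ```

  drives a snake `∂C/∂t = αC'' − βC'''' + max(V_B, G_B)` whose
  endpoints are pinned at the angular points. The geometric term
  `G_B = g_B·n̂` propels the arc outward where the vector flow
  vanishes, and the binary map prevents over-learning into the lip.

The two converged arcs are joined into one closed contour and
rasterized. A deterministic synthetic scene generator with
pixel-perfect ground truth (four clinical tongue-color classes,
optional nose block, seeded noise) backs every test, and the standard
boundary/area error metrics are included: normalized Hausdorff and
mean distance (percent of the image diagonal), and FP/FN/TP volume
fractions relative to the reference area.

## Worked example

```python
from dgfseg import SceneSpec, generate_scene, segment
from dgfseg.metrics import evaluate

scene = generate_scene(SceneSpec(seed=0))       # 256x256 synthetic scene
result = segment(scene.image)                   # full DGF pipeline
report = evaluate(result.mask, scene.tongue_mask)
print(f"TP {report.tp:.2f}%  FP {report.fp:.2f}%  FN {report.fn:.2f}%")
print(f"norm.HD {report.norm_hd:.3f}%  norm.MD {report.norm_md:.3f}%")
print("stage iterations:", result.iterations)
```

prints

```
TP 99.84%  FP 1.18%  FN 0.16%
norm.HD 0.564%  norm.MD 0.163%
stage iterations: {'geodesic': 1016, 'snake': 190}
```

i.e. the automatic mask covers 99.84 % of the true tongue area, adds
1.18 % spurious area (mostly a sub-pixel ribbon along the boundary and
the thin mouth-opening strip near the corners), and its contour stays
within ~0.6 % of the image diagonal of the true boundary everywhere.

The same pipeline is available from the shell:

```bash
dgf synth --n 5 --seed 0 --out scenes/
dgf segment scenes/scene_000.png -o out/
dgf evaluate --auto out/mask.png --ref scenes/scene_000_mask.png
```

`dgf window`, `dgf init`, `dgf geodesic`, `dgf gvf` and `dgf snake`
expose the individual stages for debugging and ablations
(`dgf segment --no-geometric-term`, `--upper-map gray`).

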