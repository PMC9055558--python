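# stereoslant

Model observers for **stereo slant and depth discrimination** of textured
planar surfaces, for computational visual neuroscientists studying how
much 3D information binocular disparity carries and how efficiently
humans use it.

A planar surface seen by two eyes induces a specific map between the
left- and right-eye images.  Given one eye's image and a candidate
surface — slant *s*, tilt τ (fixed at 0 here), intercept distance ζ —
the other eye's image can be predicted by back projection to the surface
and forward projection to the other eye.  With independent white noise
added to each eye's image, the maximum-posterior estimate of the surface
geometry minimizes the squared prediction error plus the negative log
prior:

$$\hat\theta = \arg\min_\theta \; \tfrac{1}{4\sigma_f^2}\,
\lVert \mathbf{L}_f - \hat{\mathbf{L}}_f(\theta, \mathbf{R}_f)\rVert^2
\;-\; \ln p(\theta)$$

Three observers share this matching core:

| observer | search | uses |
|---|---|---|
| **PM** (planar matching) | global (s, ζ) over the whole analysis window | location *and* pattern disparities, optimally |
| **LPM** (local planar matching) | (s_i, z_i) per square patch, then pooled | location and pattern disparities, locally |
| **LFM** (local frontoparallel matching) | z_i per patch (pure horizontal shift ≡ cross-correlation) | location disparities only |

LPM pools its patch maps two ways — regressing patch distances on
lateral position (slant from the disparity gradient) and averaging patch
slants — and combines the two cues by reliability weighting
$\hat s = (r_z\hat s_z + r_s\hat s_s)/(r_z + r_s)$.

Around the observers the package provides the full simulation pipeline:
sum-of-sinewaves textures rendered analytically on 3D planes (59
components, 0.1–3 cpd, 14.7% RMS contrast), per-eye Gaussian white noise
(5/17.5/34% RMS), radially symmetric low-pass prefiltering with a
performance-optimized cutoff (16/8/5 cpd per noise level), cumulative
Gaussian psychometric fitting (threshold = the slant difference at
d′ = 1), and a two-parameter account of real observers — an efficiency
scalar ε and internal estimation noise σ₀:
Δs_t = (1/ε)·√(σ² + σ₀²).

See `docs/methods.md` for the model conventions, numerical choices, and
limitations.

## Worked example

Render a stereo pair of a 60°-slanted plane at 99 cm with 17.5% per-eye
noise, then estimate its pose with the ideal (PM) and local (LPM)
observers:

```bash
$ stereoslant render --slant 60 --distance 99 --noise 0.175 --seed 7 --out demo
$ stereoslant estimate --observer pm --left demo.left.tif --right demo.right.tif --meta demo.json
{
  "observer": "PM",
  "slant": 59.75,
  "intercept_distance": 99.04,
  ...
}
$ stereoslant estimate --observer lpm --left demo.left.tif --right demo.right.tif --meta demo.json
{
  "observer": "LPM",
  "slant": 59.99,
  "slant_from_distances": 60.08,
  "slant_from_slants": 56.41,
  "intercept_distance": 99.06,
  ...
}
```

The PM observer recovers the pose to a quarter degree of slant and a
fraction of a millimeter of distance despite the noise; LPM's two pooled
cues (60.1° from the distance map, 56.4° from the slant map) combine to
60.0°.

Simulated discrimination thresholds come from the harness; one condition
cell of the slant experiment:

```python
>>> from stereoslant import model_threshold
>>> res = model_threshold("PM", reference_slant=50.0, noise_rms=0.34,
...                       n_trials=12, seed=0)
>>> print(f"{res.threshold:.2f} deg (95% CI {res.ci_low:.2f}-{res.ci_high:.2f})")
1.76 deg (95% CI 1.09-2.88)
```

i.e. at a 50° reference slant in 34% noise the ideal observer
discriminates slant differences of about 1.8° at d′ = 1.  The
`slant-exp`, `depth-exp`, `cutoff-search`, and `patch-sweep` subcommands
run the corresponding full experiment grids and write CSV tables with
bootstrap confidence intervals and provenance metadata.

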