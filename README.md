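# fundusdr

Simultaneous detection and segmentation of the three cardinal signs of
diabetic retinopathy — **exudates**, **hemorrhages** and
**microaneurysms** — in color fundus photographs.

Screening for diabetic retinopathy means finding all three signs at once:
bright lipid exudates, larger dark bleeds, and the tiny dark dots of early
microaneurysms. Methods that detect one sign at a time can assign the same
region to several signs and ignore the background that dominates a retina.
`fundusdr` implements a complete patch-based pipeline that avoids both
problems by classifying every pixel's neighborhood into four classes and
resolving conflicts explicitly:

1. **Contrast enhancement** — `I_CE = α·I + β·(G_σ ∗ I) + μ` with
   α = 4, β = −4, σ = 10 px (at 1500-px reference width), μ = 128: a
   Gaussian-difference band-pass that flattens smooth background to
   mid-gray and amplifies lesion-scale structure.
2. **Patch classifier** — a four-block CNN (conv 16×3×3 → ReLU →
   max-pool 2×2 → normalization, then FC 256 → dropout 0.5 → FC 4 →
   softmax) trained on S×S = 50×50 labeled patches with SGD
   (`θ(p+1) = θ(p) − γ ∂L_c/∂θ + ϑ Δθ(p) − aγθ(p)`,
   cross-entropy `L_c = −(1/|C|) Σ ln p(D_i|C_i)`), implemented in NumPy
   with explicit backprop and verified by numerical gradient checks.
3. **Probability maps** — the window centered on each pixel is classified,
   giving per-pixel softmax maps P_E, P_H, P_M (+ background).
4. **Segmentation** — per-sign thresholds chosen on held-out images by
   maximizing Youden's J on the ROC curve; binarization; overlap
   resolution by probability ranking; morphological closing 5×5 / opening
   5×5 / erosion 4×4; removal of components smaller than S²/4 px.
5. **Evaluation** — accuracy, error rate, PPV, sensitivity, specificity
   from one-vs-rest confusion counts, at patch and pixel level.

Because annotated clinical datasets are large external downloads, the
package ships a seeded synthetic-fixture generator (circular field of
view, vessel-like curves, planted lesions with exact ground-truth masks)
so the entire pipeline is testable offline; see `docs/methods.md` for what
the fixtures do and do not emulate.

## Worked example

Run the whole workflow on a 20-image synthetic set (train on 12, fit
thresholds on 4, segment and score the remaining 4):

```sh
fundusdr run-all --out rundir --seed 1
```

which trains for 25 epochs (validation accuracy ~0.92 at the end of the
log), writes probability maps, thresholds, label maps and reports into
`rundir/`, and prints the pooled pixel-level result on the held-out test
images:

```json
{
  "exudate": {
    "sensitivity": 1.0,
    "specificity": 0.9746681799552319,
    "accuracy": 0.9753406579916524,
    "dice": 0.6828498125123347
  },
  "hemorrhage": {
    "sensitivity": 0.9932874918140144,
    "specificity": 0.9781901604311686,
    "accuracy": 0.9785439172600049,
    "dice": 0.684492581937158
  },
  "microaneurysm": {
    "sensitivity": 0.8263888888888888,
    "specificity": 0.8570412463090551,
    "accuracy": 0.8569735146083968,
    "dice": 0.02489865306656205
  }
}
```

Sensitivity/specificity are pixel rates inside the field of view; `dice`
is the overlap between predicted and planted masks. Sliding-window
detections are intrinsically wider than tiny lesions (every window
containing a dot scores positive), so the microaneurysm Dice is low even
though most dot pixels are recovered — the sign is *detected* but its
extent is over-estimated, a known property of this construction discussed
in `docs/methods.md`.

Individual stages are available as subcommands (`simulate`, `enhance`,
`patchify`, `train`, `map`, `segment`, `evaluate`), each reading and
writing ordinary PNG/TIFF/CSV/JSON artifacts; the same functionality is
importable from Python (`fundusdr.enhance_contrast`,
`fundusdr.build_network`, `fundusdr.generate_maps`, ...).

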