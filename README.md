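# fluorotrack

Markerless lung-tumor motion tracking in X-ray fluoroscopy by **dynamic
intensity decomposition**.

Radiotherapy of moving thoracic tumors needs the target position in real
time.  Implanted fiducial markers track well but carry a pneumothorax risk in
lung; tracking the tumor itself on kV fluoroscopy is hard because every
frame is the *superimposition* of all traversed structures — the pixels at
the tumor are ribs + vessels + tumor at once, and plain template matching
locks onto the anatomy instead of the target.

`fluorotrack` separates each frame I(t) into a translating tumor layer and a
background layer, each generated from a time-invariant reference image:

    I(x, y, t) = I_ar(x − u(t), y − v(t)) + I_br(x − u_b(t), y − v_b(t))

The split is ill posed per frame but becomes well posed across the sequence.
Per frame the tracker registers the background reference to the frame,
registers the tumor reference to the background-subtracted estimate, refines
the tumor reference by steepest descent on J(t) = ½ Σ e², rewrites the
background reference so the recomposition is exact, and reads out the
position as the centroid of the binarized warped tumor component.  The
package also ships a synthetic chest-phantom generator with exact ground
truth, the evaluation metrics (mean Euclidean tracking error e_p, extraction
error J_a), and the no-decomposition template-matching baseline for
comparison.  See `docs/methods.md` for the model, parameters, and numerical
choices.

## Worked example

```python
import fluorotrack as ft

# render the default surrogate phantom: 100 frames, 600 x 250 px at
# 0.26 mm/px, rib-like clutter crossing the tumor's motion corridor,
# 9.42 mm peak-to-peak craniocaudal excursion
frames, truth = ft.render_sequence(ft.PhantomConfig(seed=0))

# rough manual initialization: the true support dilated by 4 px
outline = ft.rough_outline(truth, dilate_px=4)

res = ft.DynamicDecompositionTracker(frames, outline).fit()
print(res.summary())
print("decomposition e_p = %.3f mm" % res.tracking_error_vs(truth.trace_px))

base = ft.TemplateMatchingTracker(frames, outline).fit()
print("baseline      e_p = %.3f mm" % base.tracking_error_vs(truth.trace_px))
```

Output:

```
Tracking results
======================================================
method:           dynamic-decomposition
frames processed: 100
pixel pitch:      0.26 mm
displacement range (mm): u [-1.56, +1.87]  v [+0.00, +9.36]
objective J(t), first/last frame: 0 / 14.66
======================================================
decomposition e_p = 0.254 mm
baseline      e_p = 5.212 mm
```

The decomposition tracker follows the tumor to within one pixel pitch
(0.26 mm) on average — the error is dominated by the early frames in which
the flat initial reference is still acquiring the true tumor contrast,
after which the per-frame error sits at the ~0.1 mm trace-rounding floor.
Plain template matching on the raw frames is confounded by the rib-like
band crossing the motion corridor and is worse by more than an order of
magnitude.  `res.to_dataframe()` gives the per-frame trajectory;
`res.plot_trajectory(truth_trace_px=truth.trace_px)` overlays it on the
ground truth.

## Command line

```sh
fluorotrack simulate --frames 100 --seed 0 --out sim/
fluorotrack track    --input sim/frames.npz --outline outline.png \
                     --spacing-mm 0.26 --out run/
fluorotrack baseline --input sim/frames.npz --outline outline.png \
                     --spacing-mm 0.26 --out run_base/
fluorotrack evaluate --measured run/trajectory.csv \
                     --truth sim/truth_trace.csv --spacing-mm 0.26
```

Frames may be a multi-page TIFF, a directory of PNG/PGM/TIFF files, or a
`.npy`/`.npz` stack; outlines are binary mask images or polygon vertex text
files; trajectories are CSV with 1-based frame numbers.

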