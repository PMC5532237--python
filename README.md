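# blebsim

Contour-based biophysical prediction of **bleb nucleation sites** in
migrating cells.

Blebs are fast, pressure-driven protrusions that form where the plasma
membrane detaches from the actin cortex — the dominant mode of migration
for cells moving against mechanical resistance (e.g. *Dictyostelium*
chemotaxing under an agarose overlay).  `blebsim` takes segmented cell
outlines (closed 2D polylines, µm) and asks: *given only the cell's
geometry — and optionally a front-to-rear gradient in membrane–cortex
linkage — where will the next bleb form?*

For whom: cell-mechanics and quantitative cell-biology groups who already
segment outlines (QuimP or similar) and want a mechanistic, testable
site-ranking rather than a curvature heuristic.

## The model in brief

Membrane and cortex are closed polygons of N nodes (~0.3 µm spacing), the
cortex offset inward by the relaxed linker length L₀ = 30 nm and held
fixed; node pairs are coupled by linear springs (coarse-grained
membrane–cortex linkers) that break beyond a critical extension.  The
membrane minimizes a discrete Helfrich-type energy

&nbsp;&nbsp;E = ∮ (½α(|dx/ds| − x₀)² + ½β|d²x/ds²|² + ½k(L − L₀)²) ds − Δp·A

by gradient descent against the fixed cortex.  Prediction happens at the
**sub-critical pressure** — the largest Δp that breaks no linker, found by
bisection — where the local maxima of the linker-extension profile are the
candidate bleb sites, ranked by extension (rank 1 = longest linker), each
with a width between the flanking minima.  An optional exponential
stiffness gradient along the polarization axis (rear linkers up to 60%
stronger, mirroring the rear enrichment of the linker protein Talin)
redirects the top-ranked sites to the cell front.  The package also
detects observed blebs between consecutive frames (outside-points test +
fast-expansion distance constraint), matches them to predictions, and
evaluates the match with rank-distribution statistics, CDF-area summaries,
polar histograms, Kuiper and Mann–Whitney tests, and bleb–fluorescence
rank correlations.

See `docs/methods.md` for the full model, parameter meanings and
numerical choices.

## Worked example

```python
import numpy as np
import blebsim as bs

# a 5-um cell with one concave notch at 90 deg
spec = bs.FixtureSpec(shape="notched_circle", radius=5.0,
                      notches=((90.0, 1.0, 25.0),))
contour = bs.make_contour(spec)
params = bs.ModelParams.default()

sites, p_sub, state = bs.predict(contour, params, return_state=True)
print(f"N = {contour.n_nodes} nodes, sub-critical pressure = {p_sub:.4f}")
print(f"curvature minimum at node {np.argmin(bs.signed_curvature(contour))}")
for s in sites[:3]:
    print(f"rank {s.rank}: node {s.nucleation_node}, "
          f"extension {s.extension*1e3:.1f} nm, span {s.width_span}")
```

prints

```
N = 102 nodes, sub-critical pressure = 0.0160
curvature minimum at node 25
rank 1: node 25, extension 15.0 nm, span (14, 35)
rank 2: node 80, extension 13.8 nm, span (79, 81)
rank 3: node 82, extension 13.8 nm, span (81, 83)
```

The rank-1 site lands exactly on the notch (node 25, the curvature
minimum): at the sub-critical pressure the linker there is stretched to
the critical 15 nm extension, while the runner-up sites on the smooth part
of the contour stay ~8% shorter.  Membrane tension and bending push
outward where the contour is concave, which is why blebs nucleate there
first — raise Δp by 0.5% and that linker is the first to break.

The same pipeline is scriptable from the shell:

```bash
blebsim generate --shape circle --n-frames 6 --planted-blebs 3 --seed 5 --out-dir run/
blebsim predict  --input run/contours.csv --out-dir run/pred    # + --gradient 0.6
blebsim detect   --input run/contours.csv --out-dir run/det
blebsim evaluate --predictions run/pred/predictions.csv \
                 --blebs run/det/blebs.csv --out-dir run/eval
```

Every command writes a `manifest.json` (resolved options, version, seed);
identical config and seed reproduce byte-identical CSV/JSON outputs.

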