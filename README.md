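# contactsites

Segmentation-free reconstruction of sub-resolution membrane contact
sites (MCS) — e.g. mitochondria–ER contacts (MERCs) — from two-channel
3D fluorescence volumes, with per-contact morphometrics and cell-level
statistics.

## The problem

Organelle contact sites are 10–30 nm gaps between membranes, far below
the resolution of even super-resolution light microscopy (3D STED:
~120 nm lateral, ~250 nm axial at 25 × 25 × 100 nm voxels).  Overlap- or
threshold-based colocalization requires segmenting each channel first,
which is unreliable in dense, variable-intensity structures like the ER
and compounds the error of two segmentations.  This package instead asks
how the two channels' intensities *change in tandem*: where two labelled
objects abut, their blurred intensity profiles rise in opposite
directions across the hidden interface.

## The statistic

For channels $A$ (ER-like) and $B$ (mitochondria-like), compute the
negative part of the 6-neighbour Laplacian of each, $L_A^- = \max(-\nabla^2 A,\,0)$
(which peaks inside bright objects), then at every voxel the Spearman
rank correlation over a centred $(2w{+}1)^3$ window (default $w=2$, 125
voxels, ~350 nm):

$$\rho_\ell(v) = \mathrm{Spearman}_{u \in W(v)}\big(L_A^-(u),\, L_B^-(u)\big),
\qquad \rho_i(v) = \mathrm{Spearman}_{u \in W(v)}\big(A(u),\, B(u)\big).$$

The retained contact response is $|\rho_\ell|$ where both $\rho_\ell < 0$
and $\rho_i < 0$: anti-correlated curvature plus anti-correlated
intensity marks an interface between two distinct adjacent objects,
without segmenting either.  Being rank-based, the statistic needs no
intensity thresholds.  Successive stages then remove artifacts:

1. **bleed-through** — voxels must exceed an intensity z-score of 3 in
   both channels (the anisotropic PSF spills signal across z-planes);
2. **confidence** — a Fisher-z test per voxel ($\alpha = 0.05$) plus the
   minimum observable correlation at the window's sample size
   ($\rho_{\min} \approx 0.32$ for $n{=}125$, power 0.95);
3. **shadow** — voxels where the third derivative of intensity is zero
   for exactly one channel cannot be contacts and are removed;
4. **size** — 26-connected components of ≤ 2 voxels are below the
   diffraction limit and removed;
5. **vesicle filter** — contacts adjacent only to small/dim
   mitochondria-channel fragments (ln size < 9 or mean rescaled
   intensity < 0.2) are excluded, so contacts involve whole mitochondria.

Surviving contacts are quantified per contact (volume, geometric-mean
response, eigenvalue shape features: sphericity / planarity / anisotropy,
height) and per non-overlapping $5k \times 5k \times k$ sampling cube
(mitochondria surface coverage ratio, contact counts), with per-cell
aggregation and two-sided Mann–Whitney group comparison.

Everything is testable offline: a phantom generator produces two-sphere
sweep phantoms and whole-cell phantoms (membrane-labelled mitochondria,
ER sheets and tubes, vesicle decoys) with voxel-level geometric ground
truth.

## Worked example

```python
import numpy as np
from contactsites import (DetectParams, cell_phantom_spec,
                          make_cell_phantom, run_detect)

pair, truth = make_cell_phantom(cell_phantom_spec(seed=7))
result = run_detect(pair, DetectParams())
print(result.manifest.stage_voxels)
print(result.features[["label", "volume", "gm_spearman",
                       "planarity", "height_nm"]])
```

prints

```
{'response_gating': 521620, 'bleedthrough': 229, 'confidence': 148,
 'shadow': 148, 'min_size': 148, 'vesicle_filter': 148}
   label  volume  gm_spearman  planarity  height_nm
0      1      75     0.430749   0.187589      300.0
1      2      73     0.426770   0.174948      300.0
```

Half a million voxels carry a nominally negative gated correlation (the
rank correlation of weak noise is negative half the time); the
bleed-through and confidence stages reduce this to 148 voxels, which
label into exactly the two designated sheet contacts of the phantom —
the five vesicle-attached decoys are gone.  Each contact spans ~75
voxels over 3 axial slices (height 300 nm) with a geometric-mean
Spearman response of ~0.43.

The same pipeline is available from the shell:

```bash
contactsites phantom --kind cell --out phantom_dir
contactsites detect --channel-a a.tif --channel-b b.tif \
    --out results --voxel-size 100 25 25
contactsites compare cells_wt.csv cells_kd.csv
```

## Input expectations and limitations

Inputs are two co-registered single-channel multi-page TIFF stacks,
axis order (z, y, x), ideally deconvolved; intensities are used raw
(normalisation is unnecessary for a rank statistic and can harm the
differential reconstruction).  Channel registration is a precondition —
misaligned channels induce false responses.  Very low SNR breaks
differential analysis; proximate contacts are not separated; windows
much larger than the default risk cancelling opposing interaction
patterns.  See `docs/methods.md` for the full model description, window
physics, parameter table and limitations.
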