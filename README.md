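# stdifftcv

Moving-cell segmentation for 2D fluorescence time-lapse microscopy, combining
**spatio-temporal nonlinear diffusion** (motion detection) with **temporally
linked Chan–Vese level sets** (boundary refinement).

Quantifying cell-cycle progression, migration and growth in time-lapse
microscopy starts with segmenting every cell in every frame. Purely
intensity-driven segmentation struggles exactly where time-lapse data is
hardest: low SNR, heterogeneous staining, mitoses, and cells whose mean
intensity is close to — or even below — the background level. This package
implements a joint local/global approach (ST-Diff-TCV) that detects such
cells through their *spatio-temporal activity* and then refines their
boundaries with a region-based level-set model. It is aimed at researchers
processing fluorescent nuclei/cell sequences (e.g. Cell Tracking Challenge
style data) and at methodologists who want a reference implementation of the
individual stages.

## Method

For each frame *t* the pipeline runs:

1. **Intensity standardization.** A training pass pools all frames and
   records the cumulative probability *F*<sub>AF</sub>(*I*<sub>ref</sub>) of a
   background-tail reference intensity. Each three-frame window
   {*t*−1, *t*, *t*+1} is then matched: the intensity *I*<sub>test</sub> with
   *F*<sub>3F</sub>(*I*<sub>test</sub>) ≈ *F*<sub>AF</sub>(*I*<sub>ref</sub>)
   is found and the affine pair *T* = *T*₂∘*T*₁ maps it onto the reference
   and rescales to [0, 255], so one parameter set works across the sequence.
2. **Spatio-temporal diffusion.** A system of three coupled
   Perona–Malik-type PDEs ∂*I*/∂*s* = div[*g*(|∇*I*|)∇*I*] plus temporal
   coupling through the forward/backward frame differences *PF*, *NF* is
   solved by explicit finite differences. The diffusivity
   *g*(*x*) = 1/(1 + *x*²/*k*²) smooths the background while preserving
   spatial edges and temporal discontinuities — i.e. moving cells.
3. **Parzen edge map.** For each pixel, the likelihood of the local mean
   under a Gaussian-kernel density estimate
   *f*<sub>h</sub>(*x*) = (1/*nh*) Σ *K*((*x*−*x*<sub>i</sub>)/*h*) of its
   neighborhood intensities yields an edge-occurrence index (bimodal window
   ⇒ unlikely mean ⇒ edge).
4. **Watershed delineation.** The edge map is flooded from its regional
   minima; basins are classified into cell/background by a Gaussian MAP rule
   over region area and mean intensity (with the standardized threshold
   *T*(*I*<sub>ref</sub>) as the simple alternative), and adjacent cell
   basins merge into instances.
5. **Temporally linked Chan–Vese refinement (TCV).** The Chan–Vese energy
   *F*(φ, *c*₁, *c*₂) = μ·length + ν·area + λ₁∫<sub>in</sub>(*I*−*c*₁)² +
   λ₂∫<sub>out</sub>(*I*−*c*₂)² is minimized by gradient descent on the
   level-set field φ; frame *n*+1 starts from frame *n*'s converged field
   (φ<sub>n+1</sub>(·;0) = φ<sub>n</sub>(·;*i*<sub>final</sub>)). Every *k*-th
   frame φ is re-initialized from the ST-Diff mask, which catches mitoses and
   cells entering the view.

The four methods exposed — `CV`, `TCV`, `STDIFF`, `STDIFF_TCV` — correspond
to plain per-frame Chan–Vese, temporally linked Chan–Vese, the diffusion
pipeline alone, and the joint method.

## Worked example

```python
from stdifftcv import (PipelineConfig, generate_sequence, standard_fixtures,
                       segment, sequence_dice)

sim = standard_fixtures()["clean_two_blob"]      # 10 frames, 2 moving nuclei
seq, truth = generate_sequence(sim)              # frames + ground-truth masks
masks = segment(seq, PipelineConfig(method="STDIFF_TCV"))
d = sequence_dice(masks, truth)
print(f"mean Dice {d.mean():.3f} +/- {d.std():.3f} over {len(d)} frames")
print("instances per frame:", [m.n_instances for m in masks])
```

prints

```
mean Dice 0.976 +/- 0.005 over 10 frames
instances per frame: [2, 2, 2, 2, 2, 2, 2, 2, 2, 2]
```

i.e. the joint method overlaps 97.6 % (Dice) with the ground truth on every
frame and finds exactly the two simulated nuclei. On the `dim_mover` fixture
— a single absorption cell darker than the background, moving 4 px/frame —
plain Chan–Vese recovers none of the cell's pixels while ST-Diff-TCV recovers
~99 % of them: the cell is found by its motion, not its brightness.

## Command line

```bash
stdiff-tcv simulate --fixture clean_two_blob --output data/
stdiff-tcv segment  --input data/frames --method stdiff-tcv --output pred/
stdiff-tcv evaluate --pred pred/ --ref data/masks --out dice.csv
```

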