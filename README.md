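# raman-cellstate

Label-free prediction of immune cell state from single-cell Raman
spectra.

A Raman spectrum of a living cell encodes its biochemical composition
without any staining: each band corresponds to a molecular vibration
(e.g. 753 cm⁻¹ cytochrome c, 1004 cm⁻¹ phenylalanine, 2852 cm⁻¹ lipid
CH₂, 2956 cm⁻¹ protein CH₃). Although two lymphocyte populations — say
naive and activated T cells — have very similar spectra, they can be
separated by **discriminant analysis of principal components (DAPC)**.
This package implements that pipeline for hyperspectral Raman microscopy
images, for researchers who want to classify or visualize single-cell
states from spectra alone:

1. **Background subtraction** — per image, the mean spectrum of the 25
   background pixels farthest from any cell region (silica substrate,
   water, detector readout) is subtracted from every pixel.
2. **Cell averaging** — pixels of each mask-labeled cell region are
   averaged into one spectrum per cell.
3. **SNV standardization** — each cell spectrum is centered and scaled
   to unit standard deviation.
4. **NIPALS PCA** — loading vectors `P` and scores `T = X_c P` are
   extracted sequentially by power iteration with deflation (k = 7 by
   default), reducing dimension below the cell count.
5. **Fisher discriminant** — the F1 axis `w ∝ S_w⁻¹(μ₂ − μ₁)` on the PC
   scores; the *LDA score* of a cell is `t·w`. Per-class Gaussian
   parameters (mean, covariance, prior) are kept in the manner of QDA.
6. **Frozen-space projection** — spectra from later timepoints are
   projected into the already-built PC + discriminant space (inner
   products only, no refitting), tracing an activation trajectory.
7. **State maps** — every pixel of an image is projected the same way
   and colored by its two QDA log-probabilities: naive drives the
   synchronized blue+green channels, activated drives red.

Classification error is estimated by leave-one-out cross-validation with
the PCA refitted inside every fold.

Because no public single-cell Raman dataset accompanies this design, the
package ships a first-class synthetic generator (`raman_cellstate.synth`)
producing Lorentzian-band class profiles, silica-substrate scenes with
disk-shaped cells, and convex naive→activated mixtures for time courses.

## Worked example

`examples/01_classify_cells.py` simulates 96 naive and 60 activated
cells, runs steps 3–5 and prints:

```
explained variance fractions: [0.065  0.0141 0.0134 0.013  0.0126 0.0125 0.0123]
      naive: mean LDA score -1.27 (sd 0.29, n=96)
  activated: mean LDA score +2.04 (sd 0.23, n=60)
training error: 0.00%
LOO error: 0.00%
```

PC 1 carries the class contrast (6.5% of variance; the rest is the noise
floor), the two classes sit more than ten pooled standard deviations
apart on the F1 axis, and no cell is misclassified under leave-one-out.
`examples/02_timecourse.py` projects simulated 0/2/6/12/24 h activation
stages into the frozen state space — the mean LDA score climbs from
−1.12 to +1.87, affine in the mixing fraction (R² = 0.998) — and
`examples/03_state_map.py` renders a pseudo-colored image in which the
naive cell averages RGB (106, 254, 254), the activated cell (254, 77, 77)
and a half-activated cell an intermediate hue.

The same steps are available as a thin CLI:

```sh
raman-cellstate simulate dataset --seed 1 --out sup.h5
raman-cellstate train --dataset sup.h5 --k 7 --loo --out model.npz
raman-cellstate simulate stack --seed 2 --out img.h5
raman-cellstate colorize --model model.npz --stack img.h5 --out state.png
```

All commands are deterministic: rerunning with the same seeds produces
byte-identical files.

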