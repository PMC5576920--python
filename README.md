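# pcpkit

Quantitative image analysis for planar-cell-polarity boundary formation in
synthetic cell culture: co-cultures of cells expressing the atypical
cadherins Fat4-citrine and Ds1-mCherry form bright, colocalized
accumulation zones on heterotypic cell–cell boundaries. pcpkit provides
the full measurement machinery around that phenomenon, plus synthetic
generators with ground truth for every input modality, so each stage is
benchmarked end to end.

The package is aimed at quantitative cell biologists analysing
multi-channel fluorescence snapshots and movies of boundary accumulation:

- **Snapshots** (`pcpkit.snapshot`): nuclei-seeded watershed segmentation
  of the co-culture, typed cells, colocalization-based detection of
  accumulating boundaries, and a dual-lattice assignment of accumulation
  to specific cell–cell interfaces.
- **Statistics** (`pcpkit.stats`): fraction of accumulating boundaries vs
  expression, Hill fits y = f_max·xⁿ/(Kⁿ+xⁿ) with 95% CIs (the Hill
  coefficient n measures the sharpness of the threshold response; n > 1
  indicates positive feedback), log-binned 2D distributions of flanking
  intensities, and accuracy-optimal (Ds, Fat) threshold estimates.
- **FRAP** (`pcpkit.frap`): bleach-profile fitting with
  f(x) = U0·(1 − A·(1 + erf((x − x0)/L))/2), diffusion from
  L² = L0² + 4Dt, exchange from A(t) = A0·e^(−kt), kymograph extraction
  with drift registration, TIRF photobleach correction, and group
  statistics (mean ± SEM, t-tests).
- **Rainbow & polarity** (`pcpkit.rainbow`): sub-resolution measurement of
  the red–green peak separation ("gap") along boundaries via straightening
  and per-position Gaussian fits, bead-based chromatic registration,
  cytoplasmic gradient measurement with nucleus/vesicle exclusion, and
  classification of polarity-vs-gradient alignment (both/Fat/Ds/NP).
- **Pair dynamics** (`pcpkit.pairdyn`): total and boundary traces for
  single cell pairs, threshold-onset detection, and the Fat:Ds boundary
  stoichiometry (Pearson ρ).
- **Synthetic data** (`pcpkit.synthetic`): generators for all of the
  above — tessellated co-culture snapshots under a steep Hill
  accumulation rule, 1D reaction–diffusion bleach-recovery movies,
  two-channel boundaries with a known nm-scale offset, and
  maturation-delayed induction time series — each with exact ground truth.

See `docs/methods.md` for the models, defaults, and their rationale.

## Worked example

Measure the sub-resolution gap on a simulated boundary:

```python
import numpy as np
from pcpkit import (RainbowTruth, SimConfig, measure_gap, simulate_rainbow,
                    straighten_boundary)

poly = np.array([[28.0, 6.0], [28.0, 90.0]])          # (row, col) vertices
truth = RainbowTruth(gap=116.0, polyline=poly, snr=10.0)
cfg = SimConfig(seed=7, pixel_size=80.0, psf_sigma=106.2,
                image_shape=(56, 96))
img, _ = simulate_rainbow(truth, cfg)                  # (2, H, W)

straightened = straighten_boundary(img, poly, normal_halfwidth=10)
gap = measure_gap(straightened, pixel_size=80.0, psf_sigma=106.2)
print(f"mean gap {gap.mean_gap:.1f} ± {gap.sd_gap:.1f} nm "
      f"over {gap.n_valid} positions")
```

which prints

```
mean gap 114.7 ± 14.2 nm over 85 positions
```

The injected 116 nm separation — far below the 250 nm-FWHM optical
resolution — is recovered from the fitted Gaussian peak centers; the
per-position spread reflects the SNR-10 noise. The same machinery is
available from the shell:

```bash
pcpkit simulate rainbow --seed 7 --gap 116 --out sim/
pcpkit rainbow measure sim/rainbow.ome.tif --boundary sim/boundary.txt \
    --pixel-size 80 --out meas/
```

Every CLI run writes a `manifest.json` with checksums, the configuration
snapshot and the seed.

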