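# Methods

pcpkit quantifies how the atypical cadherins Fat4 and Dachsous1 (Ds1)
accumulate and polarize on cell–cell boundaries in a synthetic cell-culture
system. The package has two halves: analysis pipelines for the four
measurement modalities (co-culture snapshots, single-pair induction movies,
boundary/TIRF FRAP, and high-resolution two-channel "rainbow" images), and
synthetic-data generators that emulate each modality with known ground
truth so every pipeline stage is testable without raw microscopy data.

## Synthetic co-culture snapshots

Cells are laid out as a seeded random tessellation: nucleus points are
rejection-sampled with a minimum spacing inside a central ellipse covering
about two thirds of the frame, and each pixel joins its nearest nucleus,
clipped at 1.15× the nominal spacing. The ellipse leaves true glass
background around the tissue patch, which is what makes automatic
foreground detection well posed; within the patch the tissue is confluent,
as in a real HEK co-culture. Real cell shapes are not modelled — only the
contact topology and the intensity statistics matter downstream.

Per-cell expression is log-normal per channel (defaults: Fat median
300 a.u., Ds median 200 a.u., σ_ln = 0.8; arbitrary units, since camera
settings in such experiments are arbitrary too). Cell types are Fat-only,
Ds-only, or dual-expressing in configurable fractions.

A heterotypic interface accumulates with probability

    p = f_max · H(I_Ds; K_Ds, n) · H(I_Fat; K_Fat, n),

where H is a Hill function, I_Fat/I_Ds are the flanking cells' true
levels, K_Ds = K_Fat = 150 a.u. and n = 16 by default. The steep exponent
implements the "soft threshold gate" reading of the observed behaviour:
the accumulating and non-accumulating populations in the 2D expression
histograms separate sharply, which is exactly what a shallow exponent
would destroy. The population-level fraction-vs-expression curve and its
Hill fit are a separate question handled by the statistics module.
Contacts shorter than 2 µm never accumulate (`min_contact`): a
sub-resolution contact cannot host a resolvable stripe, and a stable
accumulation zone needs somewhere to nucleate.

Accumulating interfaces are rendered as a colocalized stripe on the
boundary pixels of both cells, with amplitude `stripe_gain` (default 5) ×
the population median of each channel — bright enough that stripe pixels
exceed the 95th percentile of non-interface pixels in min(green, red),
making detection well posed by construction. Images are blurred with a
Gaussian PSF and corrupted with Poisson-Gaussian noise (shot-noise gain
0.5 a.u./photon, read noise 3 a.u.).

The snapshot-scale default pixel pitch used throughout the tests is
400 nm/px (a 512 px frame ≈ 205 µm of tissue, ~120 cells); the
high-resolution generators (rainbow, FRAP) default to 80 nm/px with a
110 nm PSF sigma.

## Snapshot analysis

z-stacks are reduced by average-intensity projection. Nuclei come from the
smoothed blue channel: an Otsu threshold that must additionally clear the
dark-decile noise floor (so a blank channel yields no seeds), then local
maxima with a minimum separation of one nuclear diameter (10 µm; the
suppression radius is divided by √2 because the peak finder works in a
square footprint). The watershed floods the union of the per-channel
foregrounds from those seeds. Types are assigned by channel dominance of
background-subtracted, foreground-median-normalized intensities averaged
over the eroded cell interior (the rim carries PSF bleed from neighbours);
'dual' requires both normalized channels above 0.3.

The colocalization score is min(Ĝ, R̂) of the normalized channels; the
accumulation mask is its Otsu threshold floored at 2.0 — genuine
accumulation is at least twice the median membrane level in both channels,
while PSF overlap at a plain heterotypic contact stays below that — with
0.5 µm² small-object removal. Because both channels are normalized before
thresholding, the mask is invariant to joint affine rescaling of the
intensities.

Interfaces are enumerated from 4-neighbour label adjacency. Every mask
pixel is assigned to the nearest interface pixel (the dual lattice), with
a 1.5 µm capture radius; unassigned pixels are dropped and counted. An
interface is flagged accumulating when (i) at least 4 px of mask are
assigned to it, (ii) the assigned pixels span ≥ 50% of the interface's
extent along its principal axis (junction spill-over from a neighbouring
stripe clumps at one end and fails this), and (iii) the contact is at
least 2 µm long. Flanking intensities are the Fat-brighter cell's green
mean and the Ds-brighter cell's red mean.

`analyze_snapshot` additionally recomputes cell means over the eroded
interior excluding the (dilated) accumulation mask and subtracting the
dark-decile background. The stripe is 5× brighter than cytoplasm and
would otherwise inflate the expression estimate of every cell flanking an
accumulating boundary by ~35%, which both breaks the flanking-mean
contract and biases the threshold estimates; the refined means estimate
expression, not expression plus boundary.

## Accumulation statistics

The Hill model y = f_max·xⁿ/(Kⁿ+xⁿ) is fitted by unweighted least squares
on log10(x), where the curve is logistic and the problem is well
conditioned; predictions are identical. The 95% CI on n is 1.96× the
covariance standard error. f_max is free, bounded by 1.

For the 2D distributions, flanking intensities are shifted so the dimmest
cell maps to 10 a.u. (the binning cutoff) and binned on 50 even log10 bins
per axis. Class-conditional frequencies are normalized per bin by the
two-class sum, so occupied bins sum to exactly 1.

Thresholds are the axis-aligned separator (accumulating iff Ds ≥ T_Ds and
Fat ≥ T_Fat) maximizing classification **accuracy** over the bin-edge
grid, computed in closed form from suffix sums of the two histograms. We
deliberately use plain accuracy rather than balanced accuracy: the optimum
of plain accuracy sits where the accumulation probability crosses 1/2 — a
fixed point of the underlying rule, independent of how many boundaries
happen to accumulate in a batch — whereas the balanced-accuracy optimum
sits where p/(1−p) equals the class-prior ratio and therefore drifts with
the induction level. With plain accuracy, thresholds estimated
independently per induction batch agree to within one log-bin, mirroring
the observation that the separation stays put while expression rises.
`criterion="balanced"` is available for comparison.

The per-cell source-data workbook dialect (rows labelled IDs_xh, IFat_xh,
IFatDsAccumulating_xh, IFatDsNonAccumulating_xh with values across the
row) is parsed by row-label prefix; the accumulating fraction per
induction time is n_acc/(n_acc+n_non) and the mean Ds level is the mean of
the IDs row, which feed the Hill fit.

## FRAP

The bleach edge along a boundary is modelled per frame as
f(x) = U0·(1 − A·(1 + erf((x − x0)/L))/2); a bleached stripe as a
difference of two erf edges sharing A and L (the exact heat-equation
solution for a top-hat initial condition). Initialization: U0 from the
unbleached quartile mean, A from the min/max contrast, x0 at the steepest
gradient, L twice the sample spacing. Stripe fits are warm-started from
the previous frame because depth and width are anti-correlated once the
stripe widens.

Diffusion follows from the linear growth L² = L0² + 4Dt (weighted
regression; var(L²) ≈ 4L²·var(L) with L floored at the grid step so a
single sharp-edge frame cannot dominate), and the exchange rate from
A(t) = A0·e^(−kt) (log-linear initialization, bounded nonlinear fit; an
A_∞ immobile-fraction offset is optional but off by default because it is
unidentifiable when A barely decays). Frames enter the L² regression only
when the edge is resolved (L ≥ dx/2), its depth clears the noise
(A ≥ 4·residual RMS/U0), the fit residual is below 20% of U0, and — for
stripes — the width has not reached 0.75× the stripe width (beyond which
depth and width are no longer separately identifiable; those frames are
also excluded from the A(t) fit). Time origin is the first post-bleach
frame.

The 1D reaction-diffusion simulator (explicit finite differences,
zero-flux boundaries, exchange integrated exactly per step as linear
relaxation) is independent of all fitting code and serves as its oracle;
it conserves mass to float precision when k = 0 and matches the analytic
erf solution to < 1% RMS.

Kymographs are extracted as the maximum over a nine-pixel strip normal to
the boundary polyline at 1 px arclength steps. Frames are registered by
cross-correlation of high-pass-filtered profiles (the broad bleach edge
widens between frames and would swamp the peak; the fine intensity texture
along the membrane is what encodes drift), consecutive-frame pairwise with
accumulated shifts, 4× upsampling plus parabolic refinement. TIRF movies
are corrected by background-ROI subtraction and division by the
reference-ROI decay before averaging along the stripe axis.

Group statistics are mean ± SEM per condition with two-sample t-tests
between condition pairs.

## Rainbow gap and polarity

Boundaries are straightened by bilinear interpolation onto an
(arclength × normal) grid; the normal is the tangent rotated +90°
((−t_col, t_row) in row/col coordinates), which fixes the sign of all
offsets. Per position and channel a Gaussian (amplitude, center, width,
offset) is fitted to the normal profile; gates require amplitude > 3× the
residual noise, center inside the window, and width within 0.5–5 PSF
sigmas. The signed gap is (red center − green center)·pixel size; signed
statistics feed polarity, unsigned ones the gap distribution. A boundary
is non-polarized when |mean signed gap| < 30 nm or fewer than 5 positions
pass the gates.

Chromatic registration matches bead centroids across channels (local
maxima refined by intensity centroid, nearest-neighbour matching within
3 px, ≥ 3 matches required) and applies the negated mean displacement to
the red channel — removing an injected chromatic shift while preserving a
co-injected true gap.

Cytoplasmic gradients use 3×3 µm boxes at 1.5 µm standoff from the
boundary midpoint along the normal, restricted to each flanking cell's
mask, excluding nucleus pixels and pixels above the per-cell 99th
percentile (vesicles). The reported value is the area-normalized total
(mean of used pixels × nominal box area) so exclusions do not deflate the
estimate; a box that loses > 75% of its area is flagged unreliable.
Gradient signs are zero when the two sides differ by < 5%.

Alignment: with the A→B normal convention, polarity aligns with the Ds
gradient iff p = g_Ds (the red peak sits on the high-Ds side) and with the
Fat gradient iff p = −g_Fat; 'both' when both hold, 'Fat'/'Ds' when one
does, 'NP' when p = 0 or neither holds. Flipping the A/B labels negates
all three signs and leaves the category unchanged.

## Single-pair dynamics

The induction generator: transcripts rise linearly after doxycycline;
observable (matured) Ds1-mCherry appears only after a 100 min maturation
delay and then grows quadratically; the boundary fraction of total Ds
follows a Hill threshold on the total (so boundary Ds rises faster than
total Ds after onset); boundary Fat is a fixed stoichiometric ratio
(default 0.5) of boundary Ds; total Fat is constant. The true onset is
where the noiseless boundary trace exceeds five noise standard deviations.

Quantification fixes the two cell regions from the per-channel time-max
projection (the two-cell assay fixes identities; per-frame thresholding
would fail before the red fluorophore matures), thresholded at the
dark-decile background plus six noise sigmas. Totals are
background-subtracted sums over the regions; the boundary signal is the
sum over the per-frame overlap of the green and red areas. Onset is the
first time the boundary trace exceeds the baseline mean + 5 sd (baseline =
first quartile of frames) and stays above for three frames. Stoichiometry
is the Pearson correlation of the paired boundary intensities (linear
values by default, log values also reported) plus the least-squares slope
and the boundary-Ds span in decades. The nonlinearity trend is the sign of
a linear fit to the post-onset boundary/total ratio, normalized by the
mean ratio and duration, with a ±0.1% dead zone.

## Problem sizes used by the test suite

Snapshot batch experiments use four induction batches (Ds medians 160–300
a.u., spanning accumulating fractions ~0.3–0.5, the regime where both
populations are well represented) of ten 512² images with ~120 cells each,
about 1,400 heterotypic interfaces per batch. The FRAP sweep covers
D ∈ {0.01, 0.1, 1} µm²/s × k ∈ {0, 0.003, 0.03} s⁻¹ with ten replicates at
SNR 20, grid steps scaled as dx ∝ √D and durations as min(2/k, 600) s. The
rainbow benchmark uses 50 boundaries at 80 nm/px, 250 nm FWHM PSF, SNR 10.

## What the generators do and do not emulate

They reproduce contact topology, intensity statistics, the threshold
accumulation rule, 1D bleach-recovery physics, the sub-resolution
two-channel offset, and maturation-delayed induction — with exact ground
truth. They do not reproduce real cell morphology, segmentation-hostile
clutter (debris, uneven illumination, out-of-focus boundaries), bleed-
through between fluorophores, z-dependent PSFs, or manual-correction
workflows. Passing tests therefore certify the algorithms against the
stated image-formation model, not performance on arbitrary real data.

## Known limitations

- The colocalization score is a stated, reproducible stand-in for a
  trained pixel classifier; its fixed 2× floor assumes accumulation is
  substantially brighter than the membrane pool, as observed.
- The accuracy-optimal threshold estimator is quantized to the log-bin
  grid and needs on the order of 10³ heterotypic interfaces per batch for
  sub-bin stability.
- For stripes, D and k become unidentifiable once the erf width
  approaches the stripe width; the quality gates simply discard that
  regime rather than model it.
- Boundary FRAP registration needs intensity texture along the boundary;
  on a perfectly smooth synthetic boundary the correlation peak is
  degenerate.
- The per-cell workbook reader implements the documented row-label
  dialect; other layouts need a custom reader.
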