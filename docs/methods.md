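# Methods

`facetwear` re-implements, as tested and reusable code, the quantitative
pipeline of a controlled feeding experiment on rabbits in which four
pelleted diets of known silica content were related to occlusal wear:
2D dental microwear counts and 3D areal surface texture (ISO 25178-type)
parameters, compared across diet groups with robust heteroscedastic
statistics and canonical discriminant analysis. Because the original
confocal scans and per-animal measurements were never deposited, the
package pairs the measurement pipeline with a synthetic-surface generator
calibrated to the group-level values the experiment reports; all
downstream stages are exercised and validated on those surrogates.

## Synthetic cohort

Four diet groups — grass meal (G, n = 7), grass + oats (GO, n = 6),
lucerne + oats (LO, n = 7), lucerne (L, n = 6) — with dietary silica as
the driving covariate. The printed anchors are 11.96 mg/g dry matter (G)
and 0.10 mg/g (L); the oats-containing diets are placed at 1.65 and
1.30 mg/g. The intermediate values are not printed anywhere, and placing
the two oats diets close together in log-silica is what reproduces the
reported overlap of their texture signatures; they remain separated far
beyond the 5% assay CV used for the per-animal silica covariate, so all
four groups still differ significantly in silica.

Group wear parameters are tied to silica by affine-in-log(SC) coupling
between the G and L anchors:

| parameter | G (11.96 mg/g) | L (0.10 mg/g) | direction |
|---|---|---|---|
| pit rate (per 300×300 µm) | 21.7 | 45.9 | pinned to printed Np means |
| scratch rate | 30 | 8 | more scratches at high silica |
| mean scratch length (µm) | 59.1 | 38.9 | pinned to printed Ls means |
| orientation concentration κ | 8 | 0.8 | aligned scratches at high silica |
| between-animal CV | 0.12 | 0.45 | low-abrasion diets more variable |
| feature depth scale (µm) | 1.2 | 2.0 | fewer but deeper lesions at low silica |
| micro-relief rate (per field) | 5 | 40 | accumulated texture at low silica |

Scratch and pit rates are expectations per counting square; each animal
carries a gamma multiplier (mean 1, CV as above) applied to all rates and
(through a square-root link) to feature depths, which is what produces
the larger between-animal interquartile ranges in the low-silica groups.
Scratch orientations are axial von Mises draws (preferred direction 30°,
a fixed chewing-stroke direction); pit diameters are log-normal around
8 µm (σ_log 0.45) so the >5 µm and >10 µm size classes are both
populated; scratch lengths are log-normal with arithmetic mean pinned to
the group's target Ls.

Each animal yields two independent draws of this process:

* a 160×160 µm, 512×512-point **3D height map** — quadratic facet form
  (~4 µm sag), two waviness sinusoids (λ 60 and 90 µm, amplitudes 0.5 and
  0.4 µm, random phases), rendered wear features, *micro-relief*
  (shallow dimple/plateau pairs ~5 µm across, modelling texture that low
  wear rates fail to overwrite; invisible to the 2D counting method),
  white instrument noise (σ 0.05 µm) and a 5% random non-measured
  dropout mask;
* a **2D feature field** for the 300×300 µm counting square, drawn on a
  1.2× region so edge features can fall either side of the square.

The two-magnification design mirrors the experiment, where microwear was
counted under a stereomicroscope and texture measured confocally; it also
means pit counts and texture parameters are correlated only through the
shared per-animal multiplier, as in real animals.

Features are elliptical-Gaussian depressions
`depth · exp(−2((u/a)² + (v/b)²))` with semi-axes a = length/2,
b = width/2, rendered inside a 3-length window and exactly zero outside,
so rendering commutes for disjoint features. Per-animal streams derive
from `SeedSequence([master_seed, crc32(label), animal_index])`, with
separate child streams for the 3D surface and the 2D field, making every
bundle bit-reproducible and the standalone generators consistent with the
bundle generator.

What the generator does **not** emulate: enamel microstructure, chip
formation, spatially clustered dropout, scan stitching artefacts, or any
mechanistic wear physics. Passing tests therefore show that the
*measurement and inference pipeline* recovers the group structure put
into the surrogate data — not that the biological claims hold on real
scans.

## Surface stages

* **S-filter (primary surface):** areal Gaussian lowpass,
  `w(x,y) = 1/(α²λc²) exp(−π(x²+y²)/(αλc)²)`, α = √(ln2/π), applied
  separably with mirror padding; amplitude transmission is 50% at the
  cutoff. Default cutoff 8 sample spacings (~2.5 µm on the default grid)
  — a denoising nesting index; the sources give no value.
* **F-operator (S-F surface):** least-squares bivariate polynomial of
  total degree 2 (handles tilt and cylinder/bowl curvature), fitted on
  centred, scaled coordinates.
* **L-filter (S-L surface):** Gaussian highpass, default cutoff 25 µm
  (one nesting class below the ~0.1 mm field). A border band of λc/2 is
  cropped from the S-L stage only, where mirror-padding end effects are
  not attenuated.

All cutoffs and the degree are config-exposed. Non-measured points are
filled before filtering (surfaces failing the 80% measured-point rule are
rejected): each void gets the mean of a row-wise and a column-wise linear
interpolation from its nearest measured neighbours, falling back to
nearest-neighbour at borders — deterministic, order-independent and
idempotent, adequate below the 20% dropout ceiling.

## Texture parameters

Heights are referenced to the least-squares mean plane before height,
functional and feature parameters (so tilt residue cannot bias Ssk/Sku);
hybrid parameters use the surface as given. Conventions pinned where the
standard leaves room:

* material-ratio heights are type-7 quantiles (linear interpolation
  between order statistics); volume parameters are means of the positive
  part of (z − h(p)), i.e. exact integrals of the empirical
  Abbott-Firestone curve;
* Smr is referenced `c = 1 µm` under the highest peak;
* Sal/Str sample the FFT-based unbiased autocorrelation along 180 rays
  (half-spacing radial steps); rays that never decay below s = 0.2 are
  capped at half the field and flagged;
* Std is the dominant angular power-spectrum lobe + 90° (texture lies
  along the grooves), parabolic peak interpolation, ties toward the
  smaller angle;
* motif segmentation is watershed on the (inverted) surface after an
  h-extrema transform with pruning height 5% of Sz — the Wolf-pruning
  default; motif volumes are integrated against the pour-over saddle
  (the lowest rim point of the basin); Sda/Sha/Sdv/Shv are arithmetic
  means over closed motifs;
* Spc averages the mean principal curvature −(z_xx+z_yy)/2 of 5×5 local
  quadric fits at hill peaks (finite differences are too noise-fragile);
* on a constant surface Ssk/Sku are NaN with an explicit warning, and
  segmentation raises (no motifs).

## Robust statistics

Per variable: Welch-Yuen heteroscedastic omnibus on 15%-trimmed means
(g = ⌊0.15 n⌋ per tail, winsorized variances, Welch-Satterthwaite ν₂;
with four groups ν₁ = 3), pairwise Yuen statistics with Welch df and
familywise control by the studentized maximum modulus over the 6
comparisons, and Cliff's delta with the consistent dominance-matrix
variance, asymmetric (delta-transformed) CI and normal-reference p.
A contrast is *dual-significant* iff p ≤ 0.05 (≤, not <) in both the
pairwise and the Cliff route. Complete separation in Cliff's test (zero
variance) is flagged and assigned the minimal achievable two-sided level
2·m!n!/(m+n)!.

The SMM adjustment uses the closed form 1 − (2F_ν(|t|) − 1)^C, exact for
independent t variates and identical to a Šidák adjustment of the
two-sided p — no Monte-Carlo tabulation is needed. No correction is
applied across the ~30 parameters (none was in the protocol), and Cliff
p values are not familywise-adjusted across pairs (noted in output).

Box-plot summaries use type-7 quartiles and whiskers at the most extreme
data within 1.5 IQR.

## Discriminant analysis

Forward stepping by partial Wilks-lambda F (`F = (n−k−p)/(k−1) ·
(Λ_p/Λ_{p+1} − 1)`), thresholds F-to-enter = 1, F-to-remove = 0.9
(f_remove < f_enter guarantees termination). Canonical axes solve the
between/within generalized eigenproblem, normalized to unit pooled
within-group covariance; the sign of each axis makes its
largest-magnitude coefficient positive; scores are grand-mean centred.
Group centroids get *confidence regions for the mean*: the 2D score
covariance scaled by χ²₀.₉₀(2)/n_g. (The alternative reading —
data-concentration ellipses — is not implemented; with the experiment's
n of 6–7 the χ² region is also mildly anticonservative, which the
coverage test documents by using a large group.) Ellipse disjointness is
decided by centre containment plus dense boundary sampling.

## Problem sizes and numerical choices

Default 3D grids are 512×512 over 160×160 µm (dx ≈ 0.313 µm), matching
the scale of the published surface models. The pattern-recovery
diagnostics run 10 replicate cohorts on a fast path that computes only
the headline texture parameters (Sda on primary via segmentation, Sp on
S-L); Monte-Carlo calibration uses 10,000 omnibus null simulations and
5,000 coverage replicates. Gaussian kernels are truncated at ±λc
(≈5.3 σ) and renormalized, making DC transmission exactly 1 and the
cutoff transmission 50% within 0.03%. Degenerate inputs (constant
surfaces, zero winsorized variance, groups smaller than 3 for ellipses)
raise or flag explicitly rather than returning silent zeros.

## Known limitations

* Sal/Str/Std have no independent closed-form oracle here; they are
  validated on constructed anisotropy, symmetry and rotation properties.
* The watershed/pour-point motif volumes are grid approximations; the
  tests allow 2% on constructed Gaussian pits.
* The pipeline's absolute test statistics are not comparable to the
  original experiment's (those depend on the undeposited animal data);
  only the qualitative group structure and the printed calibration
  anchors (group sizes, silica extremes, Np and Ls group means) are
  reproduced.
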