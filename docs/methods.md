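# Methods

## Scope and data model

The package analyses per-patch reflectance spectra of bird plumage at the
clade level. A *patch* is one measurement on one specimen, tagged with
species, sex and one of seven standard body regions (crown, cheek, throat,
upperparts, wing, tail, underparts; an eighth region, undertail, can be
enabled for parakeet-style layouts where long tails make the undertail
measurable). All computation happens on a canonical wavelength grid of
300–700 nm at 1 nm (401 samples), spanning the avian-visible range used by
the cited color-space models; input spectra are linearly interpolated onto
it, with up to 5 nm of edge-hold extrapolation at either end. Reflectance
is stored as proportions; files in percent are detected (maximum value
> 1.5) and divided by 100, overridable per file.

Patches whose mean reflectance falls below a threshold (default 0.02) are
flagged *black*. Black patches keep their luminance score but are excluded
from every chromatic computation: a (near-)zero catch has no logarithm in
the receptor-noise model, and noise on near-black museum patches would
otherwise produce arbitrary hue directions. Their color score is recorded
as missing, never as zero.

## Visual model

Cone spectral sensitivities are generated from the Govardovskii A1
visual-pigment nomogram (alpha plus beta band, unit peak), without
oil-droplet or ocular-media filtering; tabulated curves can be supplied
instead when a fully filtered system is wanted. Default peak wavelengths
are the average avian tuning classes: UVS 372/456/544/609 nm and
VS 418/478/542/607 nm, differing only in the two shortest-wave cones;
luminance uses a blue-tit-like double cone at 563 nm. Quantum catches are
trapezoidal integrals of reflectance × sensitivity × illuminant; the
default illuminant is idealized uniform light, so the von Kries correction
reduces to dividing by the cone's integral over the illuminant. Against a
0.1 nm brute-force oracle the 1 nm trapezoid is accurate to better than
1e-4 in relative catch.

Weber fractions default to e = (0.2, 0.1414, 0.1414, 0.1) for (u, s, m, l),
derived from relative cone densities 1:2:2:4 with the most abundant cone
at e = 0.1 (a Leiothrix-like set); they are configurable and shared
between the distance model and the XYZ construction (single source of
truth).

## Color spaces

*Tetrahedral space.* Relative catches map to the regular tetrahedron with
the achromatic point at the origin and pure-cone vertices at distance
0.75. Occupancy is the convex-hull volume of a patch cloud; the default
reference for percentages is the full tetrahedron volume
(a³/(6√2) ≈ 0.2165064). The literature convention of referencing the
published total avian *plumage* color-space volume is supported by passing
that volume as the reference scalar; reports label which reference was
used, since percentages differ between conventions. Hulls with fewer than
four distinct points, or volume below 1e-10 (near-coplanar clouds), are
reported as degenerate with volume zero rather than raising.

*Receptor-noise XYZ.* The Vorobyev–Osorio tetrachromatic distance is the
noise-weighted sum of squares of log-catch contrasts about their
noise-weighted mean (weights 1/e_i²) — an identity with the usual printed
quadratic form. This makes an exact Cartesian embedding available by
sequential weighted contrasts: X opposes l against m; Y opposes s against
the noise-weighted mean of (m, l); Z opposes u against the mean of
(s, m, l), sign chosen so more u-catch raises Z. Euclidean distance equals
ΔS to machine precision, every coordinate is a zero-sum contrast (so
uniform intensity changes cancel and the equal-catch stimulus sits exactly
at the origin), and the orientation is frozen and documented because any
isometric rotation would be equally valid: reported axis loadings are
meaningful only relative to this orientation. The explicit
`achromatic_origin` step is a no-op under this construction but is kept in
the pipeline so the choice of origin is visible and testable.

## Color scores and complementary-color tests

PCA (on the covariance of XYZ, since all three coordinates share JND
units) quantifies how linear the clade's chromatic cloud is; PC1's sign is
fixed to a non-negative Z weight for reproducibility. The elevation
Φ = atan2(Z, √(X²+Y²)) of each patch is the color score; azimuth is stored
for diagnostics only, and the axis report includes the azimuthal variance
fraction so the assumption that elevation dominates can be checked per
dataset.

Extreme scores (per-taxon maximum and minimum Φ) are taken over
patch-level scores of both sexes, not region means, because single
contrasting patches are exactly what the hypothesis concerns. The battery
is two one-sample t-tests (max vs 0, min vs 0) and a paired t-test
(max vs min), all two-sided with n−1 degrees of freedom. Zero-variance
inputs give an infinite t with an exact-tie flag. Histogram bins are
anchored at zero so no bin straddles the achromatic point.

## Species × region aggregation

Scores are averaged patch → specimen → species within each region, so
heavily sampled specimens do not dominate the species mean. Black patches
contribute to luminance means but never to Φ means; never-measured cells
stay missing. Comparative analyses use male scores by default (sex filter
configurable); species with no male rows are dropped with a warning. The
coefficient of variation across species (sample sd / |mean|) is reported
per region, flagged missing when the mean is numerically zero.

## Phylogenetic signal

The Brownian covariance C has C[i,j] equal to the shared root-to-MRCA path
length. Pagel's λ multiplies the off-diagonal of C; the mean and rate are
profiled out by GLS and λ maximized on [0, λ_max], where
λ_max = min(diag C)/max(off-diag C) (≥ 1; the largest value keeping the
transformed covariance well-conditioned). A ridge of 1e-10 × max(diag) is
added before Cholesky factorization because deep Yule trees produce
numerically semidefinite covariances. Significance is by tip-label
permutation (default 1000, p = (1 + hits)/(n+1)), with a χ²(1)
likelihood-ratio test against λ = 0 reported as a cross-check (the two can
disagree; the permutation p is the headline number). Star phylogenies make
λ unidentifiable and are flagged rather than fitted. The implementation
agrees with an independent reference implementation (R `phytools::phylosig`)
to ~1e-3 in λ̂ and ~1e-4 in log-likelihood on test fixtures. Zero-length
branches are perturbed by 1e-8 with a warning; polytomies are accepted.

The Mantel test correlates the upper off-diagonal triangles of a trait
distance matrix (|mean_i − mean_j| per region) and the patristic distance
matrix, with a one-tailed (greater) permutation p, default 999
permutations — one-tailed because the hypothesis is positive association
between relatedness and similarity.

## Synthetic data

The generator is first-class, tested code; it defines the study
conditions under which the pipeline's behavior is demonstrated. Spectral
classes are phenomenological: logistic long-pass (carotenoid red, default
inflection 575 nm, scale 25 nm, plateau 0.85), short-wave Gaussian
(structural violet-blue, default peak 410 nm, sd 45 nm, plateau 0.65 — a
violet-blue with a UV tail, which keeps the planted pair on opposite sides
of the achromatic point under both UVS and VS systems), melanin brown (a
gentle long-pass from 0.08 to 0.30), flat white (0.90) and black (0.01).
No pigment chemistry or iridescence is modelled.

A clade is 27 species by default (the size of the largest empirical clade
analysed in this setting), 7 regions, 2 specimens per species, males only
unless dimorphic pairs are requested. Under the `redistributed` assignment
every species receives at least one region of each planted class, with
remaining regions drawn from {red, blue, brown, white, black}; under
`one_sided` only the long-wave class appears and backgrounds are brown and
black — deliberately no white, because a noise-perturbed spectrally flat
patch sits at the achromatic origin with a *random* hue sign, which would
contradict the one-sided ground truth the generator must plant (the
empirical analogue is a clade whose scores span zero to one side only).
Species-level template peak wavelengths drift by ±12 nm (sd) either
independently (`star`) or by Brownian motion along a simulated Yule tree
(`brownian`). Measurement noise is multiplicative Gaussian per wavelength
(sd 0.02, clipped to [0, 1]) — chosen to keep intraspecific variation
below interspecific variation, as observed on real skins; real within-patch
variance estimates do not exist for this protocol, so this is a free
parameter. All randomness derives from one seed through deterministic
substreams.

Yule trees come from a birth–death simulation (birth 1, death 0) with tip
branches extended by the exponential waiting time to the next unrealized
event, keeping all branch lengths positive and the tree ultrametric.
λ-transformed Brownian traits are drawn from MVN(0, σ²C_λ).

What passing tests on these data do **not** show: performance on real
spectra with glossiness, iridescence, fading, within-patch heterogeneity,
or species-specific visual systems; the synthetic clades are far cleaner
(PC1 fractions near 1 rather than the 0.7–0.85 typical of real clades).

## Problem sizes and numerical choices

The test suite and the acceptance script use desk-scale sizes chosen once:
100 random spectra for the integration oracle, 10 patches (45 pairs) for
the isometry check, n = 10,000 points for PCA recovery, 2000 simulated
datasets of 27 taxa for t-test calibration, 50 replicates on 64-tip trees
with 99 tip permutations each for λ recovery (the analysis default remains
1000 permutations), and 199–999 Mantel permutations. Determinism is
asserted at the byte level on full pipeline reruns. Other numerical
choices: trapezoidal integration at 1 nm; hull degeneracy tolerance 1e-10;
PC1 tie-breaks prefer non-negative Z, then Y, then X loadings; permutation
p-values use the add-one convention (1 + hits)/(n + 1).

## Known limitations

- Average UVS/VS systems, not species-specific ones; no oil droplets or
  ocular media unless tabulated curves are supplied.
- Luminance is the raw double-cone catch; no achromatic JND model.
- No evolutionary-rate or rate-shift models (Ornstein–Uhlenbeck etc.);
  λ and Mantel tests only.
- Bare parts (bills, legs), pattern geometry (barring, speckling) and
  light environments are out of scope.
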