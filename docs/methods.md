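# Methods

This note documents the models, defaults and numerical choices behind
`rsntopo`, in the order the pipeline applies them.

## Synthetic cohort model

The generator emulates the *statistical* structure the downstream
analysis assumes — correlation communities, band-limited spectra,
nuisance contamination — not haemodynamics or scanner physics.

**Atlas.** Six networks occupy compact voxel blobs placed on a ring in
the central axial slab of a 24×24×12 grid (3 mm isotropic voxels by
convention). Each ring-adjacent pair of networks shares a blob grown from
the pair's midpoint, sized so that every network's fraction of
multi-label voxels ≈ `overlap_fraction` (default 0.10). Overlap voxels
are excluded from analysis, mirroring the treatment of spatially
overlapping RSN maps.

**Signal model.** Within a network with `n_communities` communities, each
community latent is

    s_c = √b · g_net + √(1−b) · e_c,          b = between_community_r

with `g_net` the network latent and `e_c` independent. The network latent
itself carries a weak loading (squared loading 0.15) on a single cohort
latent, with opposite signs for the two groups; this produces the mild
anti-correlation between cognitive and perceptual network time-courses
seen in resting data. Every latent is synthesised directly in the
frequency domain — complex Gaussian coefficients whose in-band
(0.01–0.08 Hz) and out-of-band groups are rescaled so the realized
in-band power fraction equals `low_freq_fraction` exactly (in the same
one-sided periodogram convention the spectral module uses).

Each voxel mixes the community latents with weights
`w ∝ exp(−d²/2ρ²)` on the distance to each community centre, then is
renormalised to unit variance using the latent covariance. Community
centres are drawn by farthest-point sampling **per subject**: functional
subdivisions vary across individuals, and (materially for inference)
per-subject geometry means network-level idiosyncrasies average into
subject-level noise instead of acting as fixed network effects that a
subject-replicate ANOVA would misread as group differences. The kernel
width is `ρ = 0.45 ×` the median voxel-to-nearest-centre distance
(floor 1 voxel): narrow enough that communities stay distinct, wide
enough that boundary voxels bridge them and keep graphs connected at the
highest threshold.

**Observed signal.** `y = g·x + noise_sd·n` with white voxel noise `n`
and the mixing weight solved from the target at the reference noise SD
of 1: `g² = r_w/(1−r_w)` with `r_w = within_community_r`. Hence the
realized same-community correlation is `g²/(g²+noise_sd²)`: equal to
`r_w` at the default `noise_sd = 1` and strictly decreasing in
`noise_sd`. `noise_sd = 0` returns the clean latents (correlation 1
inside a community). Nuisance sources — six motion random walks,
band-limited (< 0.1 Hz) white-matter, ventricular and global signals —
are added with per-voxel random loadings at configurable amplitudes
(defaults 0.4/0.3/0.3/0.5 signal units); setting all amplitudes to 0
gives the clean path used by calibration tests. A constant baseline of
100 is added so volumes look BOLD-like.

**Defaults and the built-in dichotomy.** 250 time points at TR = 2 s
(255 acquired minus 5 dummy volumes), 12 subjects. Cognitive networks:
5 communities, `r_w = 0.48`, `b = 0.15`; perceptual: 3 communities,
`r_w = 0.44`, `b = 0.30`. Sizes 180/190/260 (CEN/DAN/DMN) and
150/170/160 (SMN/AN/VN); low-frequency fractions 0.72/0.70/0.80 and
0.62/0.60/0.74, following the empirical ordering DMN > VN > CEN > DAN >
SMN > AN. These values were chosen once so that, at the analysis
threshold, cognitive graphs are sparse and modular (lower C, longer L,
γ and σ well above 1) while perceptual graphs are dense and closer to
degree-matched random (C high, σ modestly above 1) — the qualitative
dichotomy the analysis is built to detect. An important calibration
fact: band-pass filtering roughly doubles apparent correlations here,
because the clean signal concentrates in-band while the voxel noise is
broadband; the correlation targets are therefore set well below the
desired post-filter graph densities.

**What the generator does *not* emulate** — haemodynamic response
functions, spatial autocorrelation of scanner noise, subject motion
artefacts beyond additive regressable signals, registration error, and
physiological aliasing. Passing tests therefore demonstrate that the
*analysis machinery* behaves correctly under its own assumptions, not
that those assumptions hold in any particular real dataset.

## Preprocessing

Fixed order: overlap exclusion → optional isotropic Gaussian smoothing
(`sigma = FWHM/(2√(2 ln 2))` per axis in voxel units, nearest-edge
padding; default off, since voxel-level graphs on smoothed data inflate
local correlations — an `--smooth-fwhm 8` switch reproduces the smoothed
variant) → extraction → nuisance regression → band-pass.

The regression design has 19 columns: intercept, nine sources (six
motion, white-matter, ventricular, global), nine backward-difference
temporal derivatives (first entry 0); all but the intercept are
mean-centred. Residuals are exact least squares (`lstsq`; rank-deficient
designs fall back to the pseudoinverse with a warning) and are orthogonal
to every column; re-regression is a no-op.

The band-pass (0.01–0.08 Hz) is an order-2 Butterworth applied forward
and backward (zero phase, squared magnitude response). Input is demeaned
first and filtering uses Gustafsson initial conditions: the 0.01 Hz
corner otherwise smears reflection-padding edge transients over ~100
samples. Measured on 250-sample series: passband gain 0.996 at 0.04 Hz,
stopband amplitude 0.011 at 0.2 Hz and 0.079 at 0.005 Hz.

## Spectral summaries

Raw one-sided periodogram (no taper, no segment averaging), normalised so
ordinates sum to the series' sum of squares (Parseval; interior bins
doubled, DC and even-length Nyquist bins not). Spectra are computed on
**regressed but unfiltered** series: the summary covers the full
0–0.25 Hz range, which is empty after band-passing. `band_contribution`
is in-band power over total positive-frequency power of the
voxel-averaged time-course (DC excluded); `falff` is the same ratio per
voxel, averaged over the network (power ratio by default; a square-root
amplitude variant is available via `falff_mode="amplitude"`). The
cross-network 6×6 correlation matrix uses fully cleaned (filtered)
network-mean time-courses, per subject and averaged across subjects.

## Graphs and thresholds

Pearson correlation over all exclusive voxel pairs; edge iff signed
`r > T` (strict); an `absolute_r` switch thresholds `|r|` instead. The
sweep uses exactly {0.125, 0.150, …, 0.550}. The lower end corresponds to
uncorrected `p < 0.05` at df = 248 (critical r 0.1241 rounded up to the
grid); the single analysis threshold is the critical r at
`0.05 / (voxel pairs of the largest network)`, df = `t − 2`, rounded up
to the grid — 0.300 under the defaults. The upper end of the grid is
validated by the coverage rule: at `T = 0.55` the largest connected
component must retain ≥ 90% of voxels in every subject-network graph
(the acceptance script reports the realized minimum, ~95%).

`C_i = 2·t_i/(k_i(k_i−1))` with `C_i = 0` for degree < 2, averaged over
**all** nodes. `L` is the mean unweighted shortest-path length over pairs
of the largest connected component (reported with the component's voxel
fraction); distances are computed by dense boolean reachability expansion
(matmul BFS), exactly equivalent to all-pairs BFS and much faster on
these small dense graphs. Node equalization subsamples every network to
the smallest network's voxel count, uniformly without replacement, 10
seeded draws, metrics averaged over draws.

## Null model and small-world indices

Each graph is compared against `m = 30` Maslov–Sneppen randomizations:
repeated double-edge swaps that preserve every degree exactly, with a
burn-in of 10 successful swaps per edge (configurable). For graphs denser
than 50% the chain runs on the complement — complementation is a
bijection on the set of graphs with a fixed degree sequence, so
randomizing the complement randomizes the graph while keeping swap
acceptance high. A graph admitting no valid swap (e.g. complete) is
returned unchanged with a warning. Rewired graphs are not forced to be
connected; `L` on them follows the same largest-component rule.
`γ = C/C_rand`, `λ = L/L_rand` with the ensemble means, `σ = γ/λ`. The
closed forms `C_rand ≈ k̄/N`, `L_rand ≈ ln N/ln k̄` are exposed only as a
cross-check; the indices always use the empirical ensemble, which
respects the observed degree sequence.

## Statistics

Per network, γ, λ and σ are tested against 1 with two-sided one-sample
t-tests, Bonferroni-corrected over an explicit family (default
6 networks × 3 indices = 18). Differences across the six networks use
one-way ANOVA with subjects as replicates. The group comparison is a
two-way ANOVA with network nested within group, fitted sequentially
(group, then networks-within-group, subject-level residual error); the
family for its Bonferroni correction is the number of metrics tested
(seven: C, L, γ, λ, σ, band contribution, fALFF). The subject-replicate
error term is valid here precisely because the generator draws community
geometry per subject; with geometry fixed across subjects the same test
would be pseudoreplicated, which is observable as type-I inflation on a
null cohort (the test suite checks calibration on cohorts with identical
network specifications across 20 seeds).

## Problem sizes and determinism

Default conditions: 12 subjects, six networks of 150–260 voxels, 250
time points — a desk-scale stand-in for cohort studies with thousands of
voxels per network; the qualitative regime (graph densities 0.3–0.7,
σ between ~1.1 and ~1.8) matches what voxel-level RSN graphs show at the
corresponding analysis threshold. All randomness flows from explicit
seeds: the generator from `GeneratorConfig.seed` (per-subject named
substreams), equalization and rewiring from named substreams of
`PipelineConfig.seed`; fixed seeds give byte-identical cohorts and
bundles. Correlation matrices are computed once per subject-network and
shared across the 18-threshold sweep and equalization draws (in-memory
reuse; no disk cache).

## Known limitations

- The mean clustering coefficient is not strictly monotone over the
  threshold sweep on synthetic cohorts: pruning between-community edges
  can transiently raise the mean before node isolation dominates; E is
  strictly non-increasing and L strictly increasing, and C falls
  end-to-end.
- At 12 subjects, per-network exceedance of 1 for σ and γ in weakly
  small-world (perceptual-like) networks is detectable at uncorrected
  p < 0.01 but not always at the 18-family Bonferroni level — a power
  limit of the desk-scale cohort, not of the machinery.
- The generator's group dichotomy is a built-in construction; effect
  sizes are not calibrated to any particular empirical cohort.
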