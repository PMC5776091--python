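# Methods

This note documents the generative model behind the synthetic microscopy
data, the measurement pipeline's algorithmic choices, and what validation
against this generator does and does not establish about real data.

## The generative model

**Geometry and layout.** Cells are rods (a rectangle with semicircular
caps) of width 1.0 µm, placed on a non-overlapping grid with clear
background between slots, rendered at 0.1 µm/px. Initial lengths are
uniform on a configurable range (default 2.5–4.0 µm; 2.3–3.0 µm in
quiescence-exit recipes, reflecting the shorter, more uniform cells of a
stationary-phase culture). Growth is linear in time (default 0.02 µm/min).
A mother divides on reaching `division_length` (default 5 µm) into two
equal daughters separated by a 0.3 µm gap; each daughter keeps its
septum-side pole fixed and elongates outward, as real cells do.

**Fluorophore budget.** Each cell carries an intensity budget drawn from a
normal distribution (mean 5000 AU, CV 0.2 by default). The budget is a
concentration: it scales with the cell's silhouette area as the cell grows,
so the measured mean intensity (MI) stays flat during growth — protein
synthesis keeps pace with dilution, which is what flat MI traces in growing
cells imply. A fraction φ of the budget sits in at most one compact
cluster rendered as a 2-D Gaussian spot (width σ), discretely normalized
over the cell mask; the remaining (1−φ) is spread uniformly over the mask.
The split is exact, so in noise-free renders the per-cell summed intensity
is conserved to floating-point precision across cluster formation and
motion. Formation therefore consumes the pre-existing diffuse pool rather
than adding material.

**Cluster phenotypes and motion.** The four localization patterns get
distinct cluster phenotypes (non-Dyn: φ≈0.60, σ≈0.20 µm; Dyn-1P: φ≈0.40,
σ≈0.15 µm; Dyn-OP: φ≈0.25, σ≈0.10 µm), encoding the observation that
bigger, brighter clusters are less mobile. Centroids perform a random walk
with per-step length `v·Δt` in a uniformly random direction, reflected
(folded) into the pattern's axial window: the starting pole's zone for
Dyn-1P, the whole cell for Dyn-OP, no motion for non-Dyn. Speed follows
the power law `v = v0·(A_ref/A)^α` with defaults v0 = 0.02 µm/s at
A_ref = 0.2 µm², α = 1, and a per-cell lognormal scatter (CV 0.15). The
metabolic-inhibition (DNP) mode replaces this with a size-independent
residual 0.05·v0, with the same per-cell scatter — without that scatter
every cell would move at literally the same speed and any measured
speed ranking would reflect only localization noise.

**Ground-truth cluster area.** The "area" of a Gaussian spot is only
defined relative to a segmentation rule, so the generator defines the true
area as the bright-core footprint π·(1.5σ)², the compact core that
threshold-based spot segmentation of a Gaussian delineates in practice.
The pipeline's detected areas agree with this definition to well within
30% at the default detection settings. Where a continuous cluster-size
spectrum is needed (correlation experiments), σ scales with content as
σ ∝ φ^(1/3) — the projected-footprint scaling of a droplet-like body, and
the reason cluster area and SDI co-vary across a population.

**Stochastic kinetics.** Clusterless cells nucleate after an exponential
waiting time with rate λ (default 0.008/min, chosen so that roughly 14 of
36 diffuse cells form a cluster within an hour), independent of cell
length — formation is cell-cycle-independent by construction. The cluster
fraction then ramps linearly over `formation_duration` (3 min), producing
the abrupt SDI jump the formation detector keys on. Dispersal, the
converse process, is linear loss of cluster fraction at `dispersal_rate`
(2%/min): gradual, not switch-like. Quiescence-exit populations start
with three sub-populations (no cluster / small / big cluster, weights
13/64/23%); a configurable fraction of small-cluster cells disperses from
time zero and may later re-form. At division the cluster goes entirely to
one daughter with probability `inherit_single_prob` (default 0.72),
otherwise it is split between both.

**Class and pattern assignment.** Population mixtures (pattern weights,
quiescence classes) are allocated by exact largest-remainder counts and
then shuffled, rather than by multinomial draws. The configured mixture is
the population's composition; recovered fractions then measure classifier
error, not the generator's sampling noise.

**Image formation and noise.** The cell-body channel is a filled rod
silhouette (amplitude 100 over background 5). Noise is additive Gaussian
read noise per pixel (default SD 0.3 ≈ 2% of the typical per-pixel
signal), clipped at zero. There is no shot noise, no point-spread
function, no photobleaching outside the FRAP module, and no cell-to-cell
contact — each omission keeps the variance bookkeeping exact.

**Reporter channel.** Per-cell reporter means are drawn from a Gaussian
copula against the cell's true clustering level (cluster fraction at time
zero), with latent correlation 2·sin(π·ρ_s/6) so the configured value is a
Spearman rank correlation; at ±1 the pairing is exactly (anti)monotone.
The marginal is normal (mean 500, CV 0.2), rendered as a uniform fill.

**FRAP.** Bleach stacks hold static cells with one large polar cluster
(φ = 0.6, σ = 0.2 µm). At the bleach frame the pole box loses
`bleach_efficiency` (0.9) of its signal. The model is parameterized
directly by the normalized recovery curve `A·(1 − e^(−kt))` (percent of
bleached-away signal) that the analysis pipeline's double normalization
reports; the renderer inverts that normalization analytically, adding
recovered signal in the pole box proportional to the prebleach shape and
removing the same amount from the rest of the cell, so the cell total is
conserved (exchange, not creation). The untreated condition's amplitude
is the sum of an exchange component and a de novo synthesis component
(one third of the recovered signal); the chloramphenicol mode zeroes the
synthesis component at the same exchange rate k (default 0.005 s⁻¹), which
is why the two conditions share early kinetics and differ at the endpoint
(6% vs. 4% at 600 s).

## The measurement pipeline

**Segmentation** is global Otsu on the cell-body channel, hole filling,
8-connected labeling, an area window (0.5–20 µm²), and removal of
border-touching components. Length is the principal-axis extent of the
mask plus one pixel (a single-pixel mask has length one pixel); pole tips
are the extremal projected points. Cells are linked across frames by
maximum mask overlap (Jaccard, ties by centroid distance); one mask
mapping onto two at the next frame is recorded as a division with mutual
sister links.

**Cluster detection.** Candidate pixels are those above
`mean + k_sigma·SD` (k_sigma = 2) of the white top-hat-homogenized image
within the cell mask, with three robustness choices beyond the bare rule,
each adopted after the bare rule failed the pipeline's own
presence/absence fidelity requirement on diffuse cells:

1. The patch outside the cell mask is padded to the within-cell median
   before the top-hat, so the morphology sees no mask boundary (otherwise
   the opening rings along the rod caps and the cap crescents exceed any
   within-cell threshold).
2. Candidate components are labeled with 4-connectivity (compact spots do
   not need diagonal chaining; correlated noise exceedances do).
3. A copy-back confirmation: the component's mean on the *original* image
   must clear the same `mean + k_sigma·SD` rule computed on original
   intensities — the quantitative form of measuring on the original image
   after thresholding an enhanced one.

Measured on the generator at default noise: false-positive rate 1.5% per
diffuse cell-frame, true-positive rate 100%, presence agreement 99.4%.
Component area and mean intensity are measured on the original image; the
area filter is 0.04 µm² (4 px). The centroid is a baseline-subtracted
weighted centroid refined under a fixed 0.25 µm Gaussian window (two
iterations): a fixed window makes localization independent of which pixels
the threshold happened to include, cutting frame-to-frame jitter about
sevenfold and removing its dependence on spot size — without this, the
speed of near-static clusters is dominated by size-correlated jitter and a
spurious speed–size correlation appears in motility-suppressed data.

**MI/SDI** use the population (not sample) standard deviation over the
original-image mask pixels.

**Tracking** links detections within each cell by greedy nearest-neighbor
between consecutive frames, with deterministic tie-breaking (distance,
then observation index). The displacement gate is 1.0 µm per 10 s of
frame interval — a distance-per-time gate, so one-minute-interval census
movies do not fragment the trajectories of fast clusters. The default gap
tolerance is zero: one missed frame closes a trajectory. Average speed is
path length divided by elapsed time between the first and last linked
frames; singleton trajectories have undefined speed and are excluded from
speed–size statistics, as are secondary (non-primary) spots.

**Pattern classification** works on the per-frame primary-cluster record
over an 11-frame, one-minute window: UC below a presence fraction of 0.2;
non-Dyn when the maximum pairwise centroid displacement is under 0.2 µm;
Dyn-OP when any centroid enters the other pole's zone or the midcell band
(pole zones are the outer quarter of the normalized axis, the midcell band
an equal-width interval around 0.5; a midcell start counts as Dyn-OP);
otherwise Dyn-1P. Positions between a pole zone and the midcell band do
not by themselves trigger Dyn-OP. All three thresholds are exposed as
parameters. On noise-free-definition classes the classifier is exact for
non-Dyn and UC and ≥95% for the two dynamic classes.

**Event detection.** Formation: first frame whose SDI is at least
`jump_factor` (2.0, from the observed SDI doubling) times the median of
the trailing 3-frame baseline, with a detected cluster on that frame and
the next. Dispersal: a monotone non-increasing run of the 3-point-smoothed
SDI spanning at least 5 frames with a relative drop ≥ 0.4, or cluster
disappearance for two consecutive frames. Both detectors are deterministic
and time-translation invariant. Quiescence-exit classes split
cluster-bearing cells at an Otsu threshold on the time-zero SDI
(overridable). Sister status is evaluated at the pair's last common frame.
The timing-statistics helper reports the exponential goodness of fit
(Lilliefors) of formation times; note that *detected* times are truncated
by the movie window and the detector's baseline requirement, so the
goodness-of-fit claim about the generator is made on ground-truth
nucleation times.

**FRAP analysis** measures the pole-box mean and whole-cell total per
post-bleach frame (the bleach box is acquisition metadata, not inferred),
ratio-corrects, and normalizes to bleach depth:
`recovery(t) = (F̂(t) − F̂(0⁺))/(F̂_pre − F̂(0⁺))·100` with F̂(0⁺) the
first post-bleach frame on the 10 s grid. Whether published recovery
percentages are of prebleach pole intensity or of bleached-away intensity
is ambiguous; this package implements the bleach-depth normalization
(standard double normalization) as its contract, and the generator is
parameterized in the same convention. The exponential fit uses bounded
least squares with data-driven initialization; an all-zero curve is
returned flagged, with the rate marked unidentifiable.

**Statistics.** Correlations and ANOVA are computed with scipy
(Spearman with average ranks for ties; p-values from the t
approximation, with an optional permutation p-value for small samples);
the test suite checks them against independent direct-formula oracles to
1e-10 or better. Bootstrap bands are percentile bootstrap over cells.

**Carrier uniformity in the speed–size experiment.** Because the cluster
detection threshold is computed within each cell, the measured cluster
area depends not only on the spot but also on the carrier cell's size and
brightness. In the speed-versus-size recipe — whose object of study is the
joint (speed, area) distribution of the clusters themselves — carrier
cells are therefore kept uniform (lengths 3.0–3.4 µm, brightness CV 0.10);
with the default carrier heterogeneity the area ranks degrade (fidelity
~0.90 against truth) and the recovered correlation is systematically
biased toward zero.

## Reproducibility and problem sizes

A single integer seed drives everything; each recipe derives an
independent stream from it (`SeedSequence([seed, stream])`), so adding a
recipe never perturbs another's draws. Fixed-seed reruns are bit-identical
down to the rendered pixels. The acceptance recipes use the published
sample sizes throughout: 1000 cells for the pattern census, 120 tracked
clusters for speed–size, 14/12 bleached cells, 269 quiescence-exit cells,
200 divisions, 500/222 cells for the reporter correlations. The whole
acceptance run takes about a minute on one CPU; the test suite about two.

## What passing these tests shows — and what it does not

The generator produces exactly the structures the pipeline is designed to
measure: axis-aligned, non-touching cells, a single Gaussian spot, flat
backgrounds, Gaussian read noise. Parameter recovery on it validates the
pipeline's internal consistency — thresholds, normalizations, linking,
classification logic, statistics — but not robustness to the hard parts of
real microscopy: crowded or curved cells, segmentation errors from uneven
illumination, multiple or sub-resolution spots, focus drift,
photobleaching during acquisition, or PSF blur. The classification
thresholds (pole-zone fraction 0.25, static gate 0.2 µm, presence minimum
0.2) separate the generator's canonical phenotypes; on real data they are
starting points to be tuned against manual annotation. Known limitations:
no multi-generation lineages beyond one division, no probabilistic
tracking, no diffusion-model FRAP fitting, and no reproduction of
real-data ANOVA p-values.
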