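# Methods

This note documents the models, rules and numerical choices behind
`neuroscreen`, and what the synthetic-data generators do and do not
emulate.

## Imaging feature extraction

**Illumination correction.** Each channel is divided by a smooth
background surface and rescaled to preserve the channel mean. The default
surface is a least-squares quadratic polynomial fitted on a 4×-subsampled
grid; it removes linear and quadratic multiplicative shading exactly, out
to the field edges, and leaves a flat channel unchanged to numerical
tolerance. A Gaussian-blur-division variant (`method="gaussian"`, default
σ = ¼ image width) is available, but any boundary handling flattens the
blurred copy of a ramp within ~2σ of the edges, so the polynomial surface
is the default. All-zero channels pass through untouched; the divisor is
floored at 10⁻⁶ of its maximum.

**Nuclei segmentation and classes.** The nuclear channel is thresholded
(per-image Otsu, floored at median + 3 robust SD so empty channels yield
no foreground; a fixed override is accepted), holes filled, and touching
nuclei are split by watershed on the smoothed distance transform (peak
separation 7 px by default). Objects are classified by size and
intensity relative to the live population: debris below 25% of the median
live area; dead below 60% of the median live area *and* brighter than
1.5× the median live intensity (dead cells present as small, brightly
stained nuclei); everything else live. The live reference population is
taken as objects at least dead-sized; cutoffs are configuration values
because the original instrument thresholds were tuned per plate and never
published.

**Marker positivity.** Ki67 and HuC/D channels are thresholded the same
way; a nucleus is positive when *more than* 5% (Ki67) or 50% (HuC/D) of
its area overlaps the marker mask — strict inequalities, so an overlap of
exactly the cutoff is negative. Ratios are computed over live nuclei
only; a field with zero live nuclei reports undefined (NaN) ratios, never
zero, and is excluded from that feature's per-well mean.

**Neurite skeleton.** MAP2 is thresholded, closed (disk radius 2),
thinned to a 1-px skeleton, and endpoint spurs shorter than 8 px are
pruned. Length sums inter-pixel steps — 1 per 4-adjacency, √2 per strict
diagonal adjacency (a diagonal pair is only counted when neither shared
4-neighbour is set, so staircase corners are not double counted) — times
the pixel size. Digital geometry makes length rotation-dependent at the
~10% level; tests allow 15%.

**Puncta.** Difference-of-Gaussians band-pass (σ and 2σ, default σ =
1.8 px), local maxima at least 3 px apart and 4 robust SDs above the DoG
median, then per-peak measurement on the raw image: background median and
MAD in an annulus between 2σ and 4σ of the peak, SNR = (peak − median) /
(1.4826·MAD), region grown at half-max. Retained puncta must pass SNR ≥ 5,
area within [3, 200] px and background-subtracted amplitude ≥ 40 (all
configurable; the original size/intensity cutoffs are unpublished).
Integrated intensity is the background-subtracted sum over the grown
region.

**Synapse calling.** A punctum is on-skeleton when its centroid falls in
the skeleton dilated by 2 px. Candidate pairs are (Synapsin1, SHANK3)
puncta both on-skeleton within a 6 px pairing radius (~0.65 µm at the
60X-like pixel size); matching is greedy one-to-one by ascending centroid
distance with ties broken by the Synapsin1 centroid (row, col). Greedy
matching is deterministic and, at synaptic densities, agrees with
exhaustive maximum matching (verified against a brute-force oracle for up
to 12 puncta per channel).

**Colocalization** is the area-overlap fraction |A ∩ B| / |A| of the two
thresholded channels (undefined when |A| = 0). Manders or
correlation-based alternatives are out of scope; the quantity of interest
here is the fraction of ARPC2-positive area lying on ß-actin structures.

**Aggregation** is the unweighted mean over a well's fields, per feature,
with undefined fields excluded from that feature's mean and the per-feature
usable-field count recorded.

## Screening statistics

Normalization subtracts each plate's DMSO-well median per metric
(centered mode; a fold mode divides instead); plates with fewer than 8
DMSO wells are excluded. Plate QC computes Z′ = 1 − 3(σ₊+σ₋)/|μ₊−μ₋|
(sample SDs) between positive-control and DMSO wells per metric; a plate
passes when both metrics reach 0.2 (the boundary passes; coincident
control means are a failure). Hit calling averages replicates per
compound first, then applies the quadrant rule around the pooled
normalized DMSO median with a width of k = 3 pooled DMSO SDs (a per-plate
SD mode is available; global/normalized is the default since the original
choice is unrecorded). Toxicity uses the raw mean nuclei count, strictly
below 2,000. The window is centered on the *median* with *SD* width,
following the assay description literally. No multiple-testing adjustment
is applied anywhere, matching the study design.

Dose-response trend testing uses Spearman correlation of the per-dose
replicate means against log₁₀ dose, with an exact one-sided permutation
p-value (exhaustive enumeration up to 8 doses; achievable p-values are
multiples of 1/5040 at seven doses). Doses whose mean nuclei count falls
below the toxicity cutoff are removed first, and at least 4 non-toxic
doses are required. A compound is proliferation-specific when the Ki67
trend is significantly increasing (α = 0.05) in the mutant line and not in
the control line; differentiation-specific analogously for decreasing
HuC/D; selection requires both. Because the rule tests at α = 0.05, about
5% of genuinely flat compounds pass by chance and about 5% of genuine
specifics are lost to a chance control trend; on the packaged 42-compound
fixture the recovered count is therefore distributed around the planted
11 with SD ≈ 1.

ΔΔCt: ΔCt = Ct_target − mean(Ct_refs) (arithmetic mean of reference Cts,
i.e. geometric mean of reference expression), ΔΔCt relative to the
calibrator sample, fold change 2^(−ΔΔCt); the relative-to-reference level
2^(−ΔCt) is reported for expression-level comparisons. Welch's t-test is
implemented from the Welch–Satterthwaite formulas and checked against
scipy's implementation in the tests.

## MEA metrics

Spike detection estimates the noise SD robustly (MAD / 0.6745 over the
whole trace), places a spike at each negative-going crossing of
−5.5 SD refined to the local minimum within 1 ms, and enforces a 1 ms
refractory period; a flat trace yields no spikes. Activity is total
spikes / observation time averaged over electrodes (silent electrodes
count as 0 Hz unless filtered). Synchrony builds, per unordered electrode
pair, a cross-correlogram over ±20 ms in 1 ms bins, normalizes each bin by
n_a·n_b·bin/duration (so independent Poisson trains expect 1 per bin),
takes the mean bin minus 1 clipped at 0, and averages over pairs. The
instrument vendor's exact normalization and window are unpublished, so
only ordinal comparisons of synchrony are meaningful; window and bin are
configurable. Oscillation is the ISI coefficient of variation with sample
(n−1) SD, averaged over electrodes with at least two ISIs. Electrodes are
active at ≥ 5 spikes/min, wells at ≥ 25% active electrodes, and a
condition is reported only with ≥ 3 active wells.

## Synthetic data generators

Every generator draws from a stream keyed by (global seed, stage name),
so outputs are reproducible and stages are independent. Fields render
nuclei as noisy filled ellipses (live), smaller brighter ellipses (dead)
and small dim spots (debris); markers are painted over a configurable
fraction of each positive nucleus's area (default 100%, so the 5%/50%
rules are exercised by partial-coverage variants in tests); neurites are
random binary trees with exponential segment lengths drawn with Gaussian
cross-section; puncta are 2-D Gaussians placed on-skeleton (pairs
co-placed with ≤0.5 px jitter) or off-skeleton; colocalization fields
place ARPC2 disks either concentric within distinct actin disks or clear
of actin, so the realized area fraction tracks the target. A
multiplicative linear illumination gradient and additive Gaussian noise
are applied last. Neurite geometry is keyed by the seed only, not the
condition, so conditions rendered at the same seed share skeletons —
between-condition count ratios then cancel skeleton-length variability
(a common-random-numbers design).

Screens are generated at the table level: per-compound latent effects
shared across replicates (a same-sign component on both metrics plus
small independent parts), independent well noise, additive per-plate
jitter applied before normalization, actives shifted up in Ki67 and down
in HuC/D, toxics with depressed nuclei counts. The packaged fixture
calibrates the DMSO baselines (22%/25%), the positive-control separations
(Z′ ≈ 0.56/0.47 via shift = 6/(1−Z′) well-SDs), and the latent-effect
variance (replicate r ≈ 0.85/0.79 via r = between/(between+within)).
Spike trains are homogeneous Poisson, correlated by thinning a shared
mother process with probability ρ (pairwise count correlation = ρ) plus
2 ms jitter, or bursting (Poisson burst onsets with high-rate intra-burst
spiking over a tonic floor).

**What the generators do not emulate:** optics (PSF, depth, chromatic
effects), cell morphology beyond ellipses and polylines, spatial
clustering of cells, plate-position (edge) effects, compound
autofluorescence, non-Poisson single-unit statistics, and electrode
noise heterogeneity. Passing recovery tests therefore demonstrates that
the operators are correct and well-calibrated under the stated
statistical structure, not that they are robust to every real-microscopy
artifact.

## Problem sizes and defaults

The packaged experiments run at desk scale: 512×512 px fields at
0.65 µm/px (20X-like) or 0.108 µm/px (60X-like) instead of the
instrument's 2560×2160 — all operators are geometry-invariant; 50 fields
for the differentiation recovery, 30 paired fields per genotype for the
synapse ratio, 30 fields per condition for colocalization, the full
7,120-compound duplicate screen at the table level, and single
16-electrode 600 s wells for the MEA features. These sizes put the
recovery experiments' sampling error comfortably inside the tolerances
they are checked against while keeping a full run around half a minute.

## Known limitations

- Skeleton length is a digital estimate; rotational variability ~10%.
- Punctum detection merges spots closer than ~2σ, so measured counts
  undershoot truth by a few percent at high densities (visible as a small
  downward bias in dense-condition count ratios).
- Synchrony values are internally comparable only (vendor metric is
  proprietary); no burst or network-burst statistics are computed.
- Hit calling assumes two replicates for concordance; compounds with a
  missing mate are dropped from r but still called on available wells.
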