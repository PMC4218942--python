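# Methods

This note documents the models, numerical choices and limitations
behind each stage, in the order the pipeline runs them.

## Synthetic cohorts

The generator produces the *study conditions*, not arbitrary test data:
a passive duration-oddball session of ~2400 binaural tones at a 500-ms
onset asynchrony, standards (p = 0.90, 50 ms) and deviants (p = 0.10,
100 ms) with at least six standards between successive deviants,
sampled at 500 Hz on a 68-channel 10-5 montage (reduced 32/24/16-channel
symmetric montages ship for desk-scale runs).  Deviants are drawn by a
renewal rule — once the run constraint is satisfied a tone becomes a
deviant with probability p/(1 − 6p) — so the empirical deviant fraction
converges to p while the constraint holds exhaustively.

**Cortical sources.**  Six dipolar sources named for the cortical
regions they stand in for (right superior temporal, right inferior
frontal, ventral mid-cingulate, anterior cingulate, medial
orbitofrontal, dorsal mid-cingulate).  Their template coordinates,
orientations and all waveform parameters are implementer defaults on a
template head — plausible, but not measured quantities.  Each source
emits:

* 1/f background activity (exponent 1, ~10 µV RMS at the scalp) — the
  temporally independent signal that drives ICA separability;
* a small N1-like response (−100 ms latency region) on every tone;
* on deviant tones only, a triphasic MMN/P3a/RON sequence of Gaussian
  bumps (width SD 25 ms).  MMN latencies are staggered across sources
  (158–222 ms); P3a and RON follow at roughly +105 and +195 ms.  SZ
  amplitudes are the NCS amplitudes scaled per source (0.95 superior
  temporal down to 0.50 dorsal mid-cingulate), encoding a midline-
  dominant group deficit.

Per-subject jitter: location SD 5 mm (clamped inside the brain shell),
amplitude fraction SD 0.30, latency SD 10 ms.  Realized values are
recorded in the ground truth and are what the score couplings and the
recovery tests refer to.

**Non-brain sources.**  Blinks (Poisson 3/min, ~190 µV biphasic,
~300-ms primary lobe at an ocular location), two temporal-muscle EMG
sources (2.5 bursts/min, 20–100 Hz, ~350 ms), 60-Hz line noise with a
near-common scalp map, white sensor noise (3 µV), and 48 weak
fixed-random-map generators (0.8 µV each) that emulate the many small
cortical and non-cortical processes making real EEG's residual subspace
spatially structured but non-dipolar.  Ocular/EMG maps are computed as
bare (skull-free) dipole fields at their extra-cerebral locations and
normalised to unit peak gain, so their amplitudes are specified
directly in scalp µV; this is also what makes them fail the brain-model
dipolarity screen, as such components do in practice.  Artifact rates
and amplitudes were chosen once so that ~2–5 % of 500-ms windows
violate the ±150 µV criterion, giving the rejection stage realistic
work.

**Clinical scores.**  Ten variables (SANS, SAPS, GAF, SOF, UPSA, WRAT,
immediate/delayed CVLT, WCST, LNS) drawn from Gaussian distributions at
plausible clinical scales.  A coupling (score, source, peak, target r²,
group) replaces the independent draw by a linear model on the subject's
realized peak amplitude with noise variance set from the *theoretical*
amplitude SD (|base| × jitter fraction), so the population squared
correlation equals the target; across replicate cohorts the mean sample
r² recovers the target to ±0.05 at n = 42.

**What the generator does not emulate** — and hence what passing tests
do not establish about real data: non-dipolar (extended-patch) cortical
sources, inter-subject head-geometry differences (one spherical model
for everyone), stimulus-correlated artifacts, non-stationary background
spectra, and evoked responses that overlap *dependently* across
sources beyond the shared event times.

## Preprocessing

Band-pass 1–100 Hz: odd-length symmetric (linear-phase) Hamming FIR
applied by FFT convolution with reflect padding — exactly zero-phase in
one pass; transition width 0.8·lo_hz, giving ≥50 dB at 0.2 Hz when
lo = 1 Hz.  Windows of 500 ms start at each stimulus onset (truncated
final windows dropped).  The amplitude criterion flags any sample
beyond ±150 µV.  The improbability statistic estimates each channel's
amplitude density over all window samples (Freedman–Diaconis histogram,
probability floor 1e-12), scores each window by its mean negative
log-density, z-scores across windows per channel (single-channel flag
at z > 5) and over the channel-pooled statistic (all-channel flag at
z > 2); the z of a zero-variance statistic is 0, so identical windows
are never flagged.  Constant channels are excluded with a warning.
Default combination mode rejects on *any* criterion; the literal
"more than one" reading ships as `mode="at_least_two"`.  Filtering
precedes windowing.

## ICA

Extended Infomax: natural-gradient maximum-likelihood updates
ΔW ∝ (I − K·tanh(u)uᵀ − uuᵀ)W on symmetrically sphered data (the
sphering determinant is part of the MIR), with per-component
sub/super-Gaussian switching from a kurtosis estimate each pass.  One
iteration is one randomized pass in blocks of ⌊√(T/3)⌋ samples.
Learning rate 0.002, halved on divergence and annealed by 0.9 whenever
successive pass updates turn by more than 60° (the oscillation signal
near an optimum); stop at max_iter (2000 by default; reduced profiles
use 100–350) or weight change < 1e-7.  The configured-engine choice —
a single-model member of the same likelihood family as the adaptive-
mixture decomposition it replaces — is the pipeline's largest
simplification; the engine is pluggable, and the rejection schedule and
diagnostics are engine-independent.

Sample rejection: after passes 4, 7, 10, 13 and 16, samples whose model
log-likelihood is more than 5 SD below the mean are excluded from all
subsequent updates (mask accumulates, reported per snapshot).

Mutual information reduction: MIR = Σh(xᵢ) − Σh(uᵢ) + log₂|det W|,
marginal entropies by 512-bin histograms over ±5 SD — deterministic and
cheap; the trace's MIR asymptote is the practical convergence
diagnostic.  Scale/sign indeterminacy is resolved by unit-norm scalp
maps with the dominant channel positive; components are ordered by
back-projected variance.  Rank-deficient data are projected onto the
principal subspace first and the fact recorded in the trace.

## Forward model and dipole fitting

Three concentric shells (brain/skull/scalp radii 80/85/92 mm,
conductivities 0.33/0.0042/0.33 S/m).  For each harmonic order n the
shell potentials a·rⁿ + b·r⁻⁽ⁿ⁺¹⁾ are matched in potential and radial
current at both interfaces with an insulating outer boundary; the
resulting per-order transfer factor multiplies the infinite-medium
dipole expansion written as p·∇₀[bⁿPₙ(cos γ)], evaluated with stable
upward recurrences.  Truncation at order 60 converges below 1e-9
relative for eccentricities up to ~0.75 (order 40 would leave ~4e-8 at
60 mm).  Montage registration scales sphere-fitted template electrode
positions to the scalp radius, with a rotation about x putting Cz at
the apex.

Fitting minimises residual variance rv(position) with the moment solved
linearly at each candidate (separable least squares) on
average-referenced maps; a coarse random interior scan seeds
Nelder–Mead restarts, with an early exit once rv < 1e-8.  Candidate
positions range over the whole sphere interior (to 0.94 × scalp
radius): the series converges for any source radius below the electrode
radius, and letting the optimiser place ocular/myogenic generators
*outside* the brain shell is precisely what the inside-brain screen
keys on.  `dipole_potential`, the physical forward operator, still
rejects outside-brain sources.  Ties break on lowest rv, then smallest
|position|.  The screen retains ICs with rv ≤ 0.15 (the complement of
an 85 % map-variance criterion; the rv convention is fraction of
average-referenced map variance unexplained) and an inside-brain fit.

## Clustering

Feature blocks per IC: dipole position raw (3-D, no reduction — its
dimension is already minimal and it is the most subject-robust
measure), scalp map (z-normalised per channel, PCA to 7), 3–50 Hz log
spectrum (PCA to 5), standard+deviant ERPs concatenated before a joint
5-D reduction.  Each block is rescaled to unit total variance and
multiplied by its weight (10/3/2/1), so a weight w scales that block's
squared-distance contribution by w² — the usual weighted-preclustering
convention.  Euclidean k-means, k = 20, best of many restarts,
deterministic under seed.  Outliers beyond 3 cluster-RMS distances are
marked and centroids recomputed once; a `split_cluster` hook re-runs
k-means with k = 2 inside one cluster (the algorithmic stand-in for a
manual split, which cannot be reproduced programmatically).  A
post-hoc rule flags clusters whose median member rv exceeds 0.15 or
whose median position leaves the brain shell — normally a no-op with
the upstream screen, kept for pipelines run without it.  Cluster
centroid positions are converted to Talairach by the standard
piecewise-linear transform (separate affines above/below the z = 0
plane; the origin is a fixed point).

## Deviance response and peaks

Epochs −100..500 ms; only trials whose full epoch survives rejection
enter; the −100..0 ms baseline mean is subtracted *after* averaging and
after ICA (baselining continuous data before decomposition would bias
the unmixing).  The deviance response is the pointwise
Deviant − Standard difference.  Cluster contributions are
back-projected as Σ member map ⊗ source ERP after polarity alignment
(flip members whose map correlates negatively with the cluster mean —
a no-op on the sum), and summarised as RMS across channels signed at
the channel of maximal absolute cluster-map projection; RMS is
intrinsically unsigned, so the signing convention is a documented
choice.  pvaf = 100·(1 − var(total − component)/var(total)) pooled
over channels and the 0–500 ms window; it can be negative, and the
union of all cluster contributions plus the residual remainder gives
exactly 100 by linearity.  Peak scoring searches each fixed window
(MMN 140–240 ms negative, P3a 220–340 ms positive, RON 310–460 ms
negative) for the extremum of the nominal polarity (earliest sample on
ties; free-polarity mode available since medial projections can
invert), reports the mean over latency ±10 ms, and flags extrema on a
window edge.  Grand averages weight subjects equally; subjects absent
from a cluster are missing, not zero.

## Statistics

Spearman correlations (average ranks on ties), p from the two-sided t
approximation t = r√(n−2)/√(1−r²); pairwise deletion with each pair's
own n (a fixed-n override exists for strict parity with a single
reported sample size).  Bonferroni critical r² inverts that
approximation at the per-test α: with n = 42, α = 0.05/30 gives
r² = 0.22 and α = 0.05/180 gives 0.28.  Expected chance counts per r²
stratum are n_tests × P(R² > τ) under the same approximation, with a
Monte-Carlo alternative (independent Gaussian pairs, sample Spearman
r²) as the cross-check; the audit tabulates observed counts per
stratum (τ = 0.10..0.50) per family (channel-comparator family,
3 peaks × variables × 2 measure types; source family, clusters ×
peaks × variables × 2 — amplitude and latency count as separate
tests, the reading under which the family bookkeeping is internally
consistent).  Group contrasts are Welch t plus Cohen's d on the pooled
SD (sign NCS − SZ); a full mixed-model treatment is deliberately out
of scope and the outputs are labelled as two-sample contrasts.

A power note documented with the acceptance checks: with a planted
population r² of 0.48 at n = 42, the sampling distribution of the
Spearman r² puts only ~2/3 of its mass above the 0.40 stratum, so a
detection-rate bar of 80 % at that stratum exceeds what these study
conditions can deliver; the corresponding check reports the honest
rate (~0.65–0.70).

## Problem sizes

Chosen as the package's own trade-off between fidelity and desk-scale
runtimes: unit tests use 16–32-channel montages and 1–5-minute
sessions; the ICA benchmark uses 20 sources × 1e5 samples; dipole
recovery uses 50 noiseless fits on the 68-channel montage; clustering
recovery builds IC records for 40 subjects directly from generator
ground truth (forward maps, fitted dipoles, spectra, ERPs) rather than
from 40 full decompositions, whose integration is covered by the
end-to-end smoke run; the coupling and null audits use 100 and 200
latent-layer cohorts at n = 42.  The full-scale profile (68 channels,
20-minute sessions, 47+42 subjects, 2000 ICA passes) ships as
`orchestrate.paper_profile()` for machines with hours to spend.

## Known limitations

* The spherical head model and the single-model ICA engine are
  deliberate simplifications of the boundary-element template and the
  adaptive-mixture decomposition they stand in for; both substitutions
  are consistent between simulation and analysis, which is what makes
  recovery tests exact but also means model-mismatch effects present in
  real data are not exercised.
* EDF output quantises to 16 bits over ±1000 µV (~0.03 µV steps) and
  pads recordings to whole 1-s records; the generator always produces
  integer-second sessions so round trips are exact in length.
* The improbability statistic is a histogram-density surrogate for the
  cited joint-probability method, chosen for determinism; thresholds
  match (5 SD single-channel, 2 SD pooled) but exact flag sets need
  not.
* k-means with a fixed k = 20 can split a strong source across
  clusters or merge weak ones; purity checks count majority labels and
  do not require a one-to-one source↔cluster map.
* Scores are simulated; nothing here validates clinical instruments,
  only the audit machinery that consumes them.
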