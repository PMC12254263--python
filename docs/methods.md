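# Methods

This note records the models, conventions, and numerical choices behind
each module, what the synthetic-data generator does and does not emulate,
and the known limitations.

## Abundance normalization

The coverage-based virus-to-cell ratio divides a virus's mean read
coverage by the estimated number of cellular genome copies sequenced in
the same metagenome.  The cell estimate is the arithmetic mean of the
coverages of 16 universal single-copy ribosomal proteins; a marker absent
from a sample's table contributes 0 rather than being treated as missing
data, because a missing single-copy gene in a sequenced metagenome is
itself evidence of low cellular coverage.  The identity of the 16 markers
is configuration (`DEFAULT_MARKER_IDS`), not data.

Detection requires breadth strictly above the threshold (default 0.25):
a virus whose sequence is ≤25% covered is recorded as 0, and entities that
never pass the filter are kept as all-zero rows so that downstream
prevalence filters — not the normalization — decide their fate.  The
threshold is configurable for detection-sensitivity analyses.  The
coverage-per-Gbp variant uses the trimmed mean coverage by default, as
produced by standard coverage tools; when only plain means are available
`use_trimmed=False` selects those.  A zero cell estimate combined with
nonzero viral coverage raises rather than producing infinities.

## Subsampling diversity

Counts are rarefied without replacement by multivariate hypergeometric
draws (equivalent to vegan's `rrarefy`), 100 iterations per depth on a
50-count grid; depths exceeding a sample's total are skipped, never
extrapolated.  Evenness is Pielou's J = H/ln S with J = 0 when S ≤ 1.
Inputs must be integer counts: normalized abundances (cVCR) must be
converted back to read counts by the caller, since rarefaction of
non-count data is undefined.  The rarefaction slope at depth d is the
finite difference of mean richness over the preceding grid step — the
marginal discovery rate, comparable across samples of unequal depth.  On
even communities the implementation is tested against the closed form
E[S] = Σᵢ (1 − C(N−nᵢ, d)/C(N, d)).

## Seasonality statistics

Bray–Curtis similarity is computed between sample columns after an
optional detection threshold zeroes small entries.  A pair in which both
samples are entirely zero has no defined similarity and is returned as
NaN and excluded from time-decay binning: a zero caused by seasonal
absence and a zero caused by shallow sequencing are indistinguishable, and
scoring such pairs 0 would conflate them with genuinely disjoint
communities.  Time lags are binned half-open at the 30.5-day sampling
interval, self-pairs excluded, empty bins absent rather than zero.

The Mantel statistic correlates strictly-lower-triangle entries
(Pearson or Spearman with mid-ranked ties); the null permutes rows and
columns of the second matrix simultaneously; p = (#{permuted ≥ observed}
+ 1)/(B + 1) with ties counted toward the null (conservative).  A
zero-variance triangle yields (NaN, 1).

## Network inference

*Temporal profiles.*  Each series is linearly interpolated onto a regular
30.5-day grid and low-pass filtered by keeping the first 16 complex
coefficients of the real-input FFT (DC included, all higher frequencies
zeroed).  With 48 monthly samples this retains periods down to ~3 months —
enough to capture annual and bloom-scale structure while suppressing
observation noise.  Correlations are computed between time-domain
reconstructions (equivalent to correlating low-pass-filtered series); the
p-value's degrees of freedom use the original observation count, because
interpolation manufactures no information.  Only positive correlations
(r > 0.7, BH-adjusted q ≤ 0.05) form edges: co-exclusion is not
interpretable as virus–host association here.

*Modules.*  Louvain modularity maximization on the weighted graph, with 8
seeded restarts keeping the highest-modularity partition; the result is
deterministic given the seed.  The resolution parameter is exposed
(default 1).

*Direction.*  Convergent cross mapping: to test whether a prokaryote
drives a virus, the virus's series is delay-embedded (dimension E chosen
2–6 by univariate simplex self-forecast skill unless given; τ = 1) and
simplex projection (E+1 nearest neighbors, exponential distance weights,
leave-one-out) predicts the contemporaneous host values from random
libraries of increasing size.  Skill is the Pearson correlation of
observed and predicted host values, averaged over 50 library draws.
An interaction is convergent when skill(L_max) − skill(L_min) > 0.1 and
skill(L_max) > 0.  The library ladder is geometric from
max(E+2, min(n/8, 16)) to the full embedding: at that smallest library a
mere forcing correlation has already plateaued while a genuine cross-map
is still data-starved, which is what makes the gain criterion directional.
Directed edges are stored cause→effect (ASV→vOTU) and evaluated only for
pairs already connected in the correlation graph.

*Edge weights and significance.*  NMI uses equal-frequency discretization
into ⌊√n⌋ bins (stable rank order breaks ties), geometric-mean entropy
normalization, and the Miller–Madow small-sample correction.  Even
corrected, the plug-in estimator retains a positive bias of order
(bins²/n)/ln(bins) on independent series (~0.05 at n = 10⁴); significance
is therefore always assessed against a permutation null, where the bias
cancels.  The default null rotates the series by a uniform random offset
(circular scheme), preserving autocorrelation; full shuffling is available
and is demonstrably anti-conservative on AR(1) series.

*Lagged association.*  eLSA rank-normal transforms both series and runs a
dynamic program over positive and negative partial-sum alignments for
every delay in [−2, +2] sampling steps; the score is normalized by series
length, the optimal delay is the argmax of |score| with ties to the
smallest |delay| (positive first), and p-values use the full-shuffle null
on |score|, following the published eLSA convention.

## Amino-acid traits

Sequences are uppercased, trailing stop characters stripped; any letter
outside the 20 standard residues rejects the sequence (strict default;
an X-only mode matches pipelines that only remove ambiguous residues).
The nitrogen usage score weights residues by side-chain-plus-backbone
nitrogen: 4 (R), 3 (H), 2 (K, N, Q, W), 1 (the remaining 14), so NUS ∈
[1, 4].  The aliphatic index is Ikai's X_A + 2.9 X_V + 3.9 (X_I + X_L) in
mole percent, bounded by [0, 390].  Molecular weight uses average residue
masses (Biopython ProtParam) plus one water.  The isoelectric point solves
Q(pH) = 0 under the EMBOSS pKa set (N-term 8.6, K 10.8, R 12.5, H 6.5;
C-term 3.6, D 3.9, E 4.1, C 8.5, Y 10.1) by bisection; since Q is strictly
decreasing the root is unique, and the bracket is driven below 1e-7 pH so
the answer is correct to well under the 1e-3 tolerance even where the
charge curve is flat.  Group memberships (acidic {D,E} ⊆ polar-charged
{D,E,H,K,R}; polar-uncharged {S,T,N,Q,C,Y}; aromatic {F,W,Y}) are
configuration with common-usage defaults.  Sample-level traits are
unweighted means over a sample's proteins (not length-weighted); undefined
R/K ratios (no lysine) are excluded pairwise, and rejected-sequence counts
are reported per sample.

Trait–environment association uses per-trait Bray–Curtis distances
between samples against per-parameter Euclidean distances, with the
Spearman Mantel test (default 9999 permutations).

## Latitudinal smoothing and bimodality

The smoother is a penalized regression spline: cubic B-splines of basis
dimension k = 10 on uniform interior knots spanning the observed
latitudes, an exact second-derivative penalty (Gauss–Legendre per knot
interval), and a per-observation-normalized least-squares objective.  The
smoothing parameter minimizes GCV n·RSS/(n − edf)² over a log-spaced grid
(1e-10 to 1e4, penalty scaled to unit max) unless supplied.  Predictions
on the half-degree grid are clipped at zero.  With the penalty normalized
per observation, duplicating the dataset (doubling all weights) leaves the
fit identical at fixed smoothing.

Peaks are strict interior local maxima of the clipped grid; endpoints are
excluded (a monotone rise toward a pole is not a peak) and maxima below
1e-6 of the grid maximum are discarded as numerical ringing.  A k = 10
basis over a ~150° span has ~21° knot spacing, which has two consequences
worth knowing: a narrow mode's fitted peak can shift by 1–3° toward the
nearest representable bump center, and the spline rings around a strong
mode with sidelobes reaching 10–15% of its height.  Bimodality calling
(`cohort_summary`) therefore screens peaks below 0.2 of the highest peak —
comfortably above the sidelobe ceiling and below the smallest real
secondary mode the generator plants (≥0.55 before attenuation).  A vOTU is
bimodal when its two highest surviving peaks lie in opposite hemispheres;
a peak exactly on the equator belongs to neither.  The water-column split
is epipelagic ≤ 200 m, deep > 200 m (strict).

## The synthetic community

The generator produces the statistical structure the analyses assume,
not a mechanistic model of any particular sea.  Defaults mirror the
study design the package targets: 48 samples at 30.5-day spacing (four
years, near-monthly), 40 hosts and 120 viruses in four seasonal guilds,
with seasonal forcing shaped like a high-latitude mooring record
(temperature peaking late summer, MLD in winter anti-phase, PAR zero
through a 120-day polar night, polar water fraction peaking late summer).

Hosts follow a forced Ricker-type map
h′ = h·exp(dt·(r_g(env)(1−h/K) − d₀ − a·v̄)) whose growth rate is a
Gaussian niche response in standardized (temperature, oxygen, PAR, MLD)
space — four drivers whose seasonal phases straddle the year, so the
annual environmental trajectory is an injective loop and distinct
preferred days map to distinct niches.  Mortality is separated from the
density-dependent term so that a host's equilibrium tracks its niche
optimum (with mortality folded inside, the favorable-season equilibrium
would pin at K and host peaks would drift to the end of the favorable
window).  Each virus obeys v′ = v·exp(dt·(b·h_lag·(1−v/K_v) − m)) + ε·dt,
a discrete Lotka–Volterra response to its host's abundance lagged by 0, 1
or 2 sampling steps (probabilities 0.41/0.34/0.25, matching the observed
frequency of no-delay, one-step and two-step virus–host correlations in
this kind of series).  Two departures from the most literal predator-prey
map are deliberate:

- *Sub-step integration* (8 sub-intervals per sampling step).  Viral
  kinetics — latent periods of hours to days — are far faster than monthly
  sampling.  A map iterated once per sample caps viral growth at ~1 e-fold
  per month and forces a quarter-cycle phase lag behind the host, which no
  real monthly series of fast-responding viruses shows.  Sub-stepping lets
  viruses track their (lagged) host quasi-statically while planted lags
  remain exact integer sampling steps.
- *Saturation and immigration.*  The (1 − v/K_v) factor bounds viral
  growth (a pure exponential response integrates the host signal and
  phase-shifts it by ~90°), and the small immigration floor ε is a
  seed-bank term letting a virus re-grow promptly when its host returns.
  With b = 0 and ε = 0 the map reduces to pure exponential decay.

Guilds differ not only in seasonal phase but in two interannual signals
shared by guild members: a lognormal guild × year carrying-capacity
envelope (σ = 0.6) and a guild × year bloom-timing jitter (sd 15 days).
Both are features of real bloom records (the same lineage blooms strongly
in one year and weakly or late in another), and they are what makes
seasonal guilds identifiable as network modules: with pure phase
structure, a virus lagging its host by two steps (61 d) sits closer to
the next guild's phase (91 d) than to its own guild's unlagged members,
and no community-detection method could separate them.

Coverage observation multiplies true abundance by a per-sample depth
factor (sample Gbp over a 10-Gbp reference) and lognormal noise (σ =
0.25); marker coverage tracks total host abundance the same way.  Breadth
follows the saturating map min(1, 1 − e^(−0.75·cov)), so breadth ≈ 0.25
near coverage 0.38 and the detection filter is genuinely exercised by
low-abundance entities.  Contig lengths are ≥10 kb by construction.

Protein sequences are drawn i.i.d. from a 20-letter categorical
distribution whose aliphatic mass (A,V,I,L) rises and polar-uncharged
mass (S,T,N,Q,C,Y) falls linearly with temperature (bias 0.5 per 20 °C
around the sample mean); probabilities clipped at zero are renormalized
with a warning.  Latitudinal profiles are 1- or 2-component Gaussian
bumps (centers jittered ±2° around 61°N / 51°S, sd 5°, secondary
amplitude 0.55–0.9 of the primary) on a uniform grid over 70°S–80°N — the
span the global surveys this emulates actually cover — plus truncated
noise.

What the generator does *not* emulate: read-level sampling (FASTQ,
assembly artifacts), compositional coupling between viral and cellular
fractions, microdiversity within vOTUs, multi-host viruses, eukaryotes,
and amplicon chemistry.  Passing recovery tests therefore demonstrates
that the analysis chain is correct and well-calibrated under the stated
generating assumptions, not that those assumptions hold in any particular
ocean.

## Numerical conventions and degenerate inputs

- All generators and analyses are pure functions of (inputs, seed);
  identical calls are bit-identical.
- Constant series: CCM returns non-convergent with undefined skill; NMI
  returns 0; permutation p-values return 1; Spearman returns NaN.
- Abundance ceiling 10⁶ units guards against overflow in divergent
  parameter regimes (clipped with a warning).
- Bisection, GCV grids, and peak-floor constants are stated inline where
  they are used; none are fit to data.

## Problem sizes used in the recovery suite

The end-to-end checks run at the design scale of the study they emulate:
48 monthly samples, 40 hosts, 120 viruses, 4 guilds for the network; 50
pairs of length-400 coupled logistic maps for CCM direction; 500
replicates for permutation-test calibration; 200 vOTUs for bimodality; 20
replicates of 20-sample protein sets for trait–environment power.

## Known limitations

- The k = 10 smoother bounds peak-location accuracy to ~1–3° for narrow
  modes; increasing k would sharpen peaks at the cost of more ringing.
- CCM on ~48-point series is at the short end of what delay embedding
  supports; the auto-selected E is capped at 6 and results on such series
  should be read as screening evidence, not proof of causality.
- The NMI edge weight retains a small positive bias (see above); compare
  weights only at fixed n and bins.
- eLSA's shuffle null ignores autocorrelation and is anti-conservative on
  strongly autocorrelated series; it is kept because it is the published
  convention for the method, and the circular-null machinery is available
  separately for sensitivity checks.
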