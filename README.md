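# virotime

Analytics for multi-year time series of ocean virus communities observed
through metagenome read coverage: abundance normalization, subsampling
diversity, seasonality statistics, virus–host network inference with causal
direction, amino-acid cold-adaptation traits, and latitudinal bimodality of
virus populations.

The package targets the kind of study in which a high-latitude mooring is
sampled roughly monthly for several years, viral contigs (vOTUs, ≥10 kb) and
prokaryotic ASVs are quantified per sample, and the questions are: how
seasonal are the viruses, which prokaryotes do they follow, and how are
they distributed across the global ocean?  Because such studies hinge on
bespoke computations that standard ecology packages do not provide, each
step is implemented here as a tested, reusable function, and a first-class
synthetic-data module generates seasonally forced virus–host communities
with recorded ground truth so every analysis can be validated as a
parameter-recovery problem.

## What it computes

**Abundance (`virotime.abundance`).**  The coverage-based virus-to-cell
ratio normalizes viral mean coverage by the estimated number of cellular
genomes sequenced:

    cVCR(v, s) = cov(v, s) / (1/16 · Σ_m cov_m(s)),

where the denominator averages the coverages of 16 universal single-copy
ribosomal proteins, and a virus counts as detected only when more than 25%
of its sequence is covered (entries failing the breadth filter are 0).  The
coverage-per-gigabase variant divides trimmed mean coverage by sample Gbp.

**Diversity (`virotime.diversity`).**  Alpha diversity by iterative
subsampling without replacement (100 iterations on a 50-count grid up to
30,000): richness, Shannon H = −Σ pᵢ ln pᵢ, Pielou evenness J = H/ln S,
and the rarefaction slope (vOTUs discovered per additional read) at a
reference depth.

**Seasonality (`virotime.seasonality`).**  Pairwise Bray–Curtis similarity
S = 1 − Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ), its decay and annual recurrence binned at the
30.5-day sampling interval, Mantel tests (Pearson/Spearman statistic on
distance-matrix triangles, row/column permutation null), and Spearman
correlations of per-module summed abundance against environmental
parameters.

**Network (`virotime.network`).**  Temporal profiles are built from the
first 16 Fourier coefficients of each interpolated series; profile pairs
with Pearson r > 0.7 after Benjamini–Hochberg correction form an
undirected graph; Louvain community detection labels seasonal modules;
Convergent Cross Mapping assigns direction (a host drives a virus when the
virus's delay embedding predicts the host's states with skill that
converges as library size grows); normalized mutual information with a
circular-permutation null weights retained edges; extended Local
Similarity Analysis scores time-lagged association (±2 sampling steps) on
the untransformed series.

**Amino-acid traits (`virotime.aatraits`).**  Per-protein residue
frequencies, group fractions, R/K ratio, molecular weight, Ikai aliphatic
index, EMBOSS-scale isoelectric point, and the nitrogen usage score

    NUS = (4 F(R) + 3 F(H) + 2 F(K,N,Q,W) + F(rest)) / n,

the mean nitrogen cost per residue; sample-level trait means are tested
against environmental parameters with Spearman Mantel tests (Bray–Curtis
trait distances vs Euclidean environmental distances).

**Biogeography (`virotime.biogeography`).**  Per-vOTU coverage/Gbp over
latitude is smoothed with a penalized cubic B-spline (k = 10 basis
functions, second-derivative penalty, GCV-selected smoothing), predictions
are clipped at 0 on a 0.5° grid, interior peaks are extracted, and a vOTU
is bimodal when its two highest peaks lie in opposite hemispheres.

**Synthetic data (`virotime.synth`).**  Seeded generators for the
environment (annual cycles with a polar-night PAR window), a guild-
structured host community with Gaussian environmental niches, viruses that
lag-follow their hosts through discrete forced Lotka–Volterra dynamics,
read-coverage observation with depth variation, temperature-biased protein
sequences, and latitudinal profiles with planted bimodality — all with
ground truth recorded for recovery tests.

## Worked example

Simulate a four-year, monthly community (40 hosts, 120 viruses, four
seasonal guilds), observe it through read coverage, normalize to cVCR, and
infer the virus–host network:

```python
from virotime import synth
from virotime.abundance import AbundanceMatrix, compute_cvcr
from virotime.network import build_ccm_network
from virotime.seasonality import bray_curtis, time_decay

env = synth.gen_environment(48, 30.5, seed=1)
comm = synth.gen_community(env, n_hosts=40, n_viruses=120, n_guilds=4, seed=2)
cov, markers, gbp = synth.gen_coverage(comm, seed=3)
votu = compute_cvcr(cov, markers, sample_dates=comm.dates)
asv = AbundanceMatrix(synth.asv_relative_abundance(comm, seed=4),
                      "relative", comm.dates)
net = build_ccm_network(votu, asv, seed=5)
print(f"{len(net.undirected_edges)} correlation edges, "
      f"{len(net.directed_edges)} directed host->virus edges, "
      f"{len(set(net.modules.values()))} modules")

td = time_decay(bray_curtis(votu.values), comm.dates)
```

prints

```
1978 correlation edges, 506 directed host->virus edges, 4 modules
```

The four Louvain modules coincide with the four planted seasonal guilds,
and all 506 directed edges point from a prokaryote into the guild of the
virus's true host.  The binned Bray–Curtis time-decay from the same run
has a local similarity maximum at the ~1-year lag bin (350.8 d, mean
similarity 0.53) — the annual recurrence signature of a seasonal
community.  (A `RuntimeWarning` about the abundance ceiling may appear for
some seeds when a noisy trajectory transiently hits the overflow guard;
the trajectory is clipped there by design.)

The same steps are available from the shell:

```
virotime simulate --n-samples 48 --n-hosts 40 --n-viruses 120 --seed 1 --outdir out/
virotime normalize --coverage out/coverage.tsv --markers out/markers.tsv \
    --metric cvcr --out out/cvcr.tsv
virotime network --votu out/cvcr.tsv --asv out/asv_counts.tsv --env out/env.tsv \
    --outdir out/net
```

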