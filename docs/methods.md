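# Methods

## The serial coalescent

The simulator implements the coalescent for serially sampled (heterochronous)
data. Time is measured in generations before the youngest tip (t = 0 at the
youngest sample); ages given in years BP are shifted so the youngest tip sits
at the origin and divided by the generation time (floating point, no
rounding). Lineages are *activated* at their tip times. While j lineages are
active, the next coalescence occurs at instantaneous rate

    λ(t) = C(j,2) / N(t),

and a candidate waiting time that overshoots the next sampling time is
discarded in favour of advancing to that time and activating its tips —
valid because the inhomogeneous exponential is memoryless after time
rescaling.

**Demography.** N(t) = max(N₀·e^(−g·t), floor) with N₀ the *haploid* number
of gene copies at the most recent sampling time. The haploid convention is
the natural scale for mtDNA (one locus, maternal inheritance): the pairwise
coalescence rate is 1/N(t) per generation. Positive g means forward-time
growth, i.e. the size shrinks going backward. The trajectory is clamped at
`floor_size = 1` so that waiting times stay finite under strong decline
(g = 0.01 reaches the floor ≈ 920 generations back from N₀ = 10⁴). Waiting
times are drawn by closed-form inversion of the integrated hazard, piecewise
over the exponential and floor regimes; a numerically integrated CDF serves
as the test oracle for this kernel. For g < 0 (backward growth) the total
hazard is finite and the draw may be `inf` — such lineages never coalesce;
the study scenarios use g ≥ 0 only.

**Mutation overlay.** Per-branch mutation counts are Poisson with mean
(branch length in generations) × (μ per site per year × generation time) ×
L. Defaults are the study conditions: μ = 7.6×10⁻⁷/site/year, L = 360 bp,
generation time 7 years. Finite-sites mode draws the root sequence uniformly
over {A,C,G,T} per site, picks mutated sites uniformly, and applies a
transition with probability 50/51 (the Ti/Tv = 50 setting of mtDNA
control-region analyses), otherwise one of the two transversions uniformly;
recurrent hits are allowed. No rate heterogeneity across sites is modelled.
Infinite-sites mode opens a fresh binary column per mutation and is used for
the closed-form oracles (Watterson's E[S] = θ·a₁(n), tree-length identities).

**Sampling fixtures.** The default heterochronous schedule is 37 tips evenly
spaced from 2,000 to 12,000 years BP, shipped as an editable JSON file
(`serialcoal/data/default_het_ages.json`). This emulates the *span* of a
Holocene ancient-mtDNA collection; real radiocarbon age distributions are
typically clustered rather than uniform, and this is the single most
consequential approximation in the package (see Limitations). The
isochronous scheme places all 37 tips at one age; only relative ages enter
the coalescent, so the choice of that common age is irrelevant.

## Neutrality statistics and significance

Tajima's D uses the standard variance coefficients a₁, a₂, b₁, b₂, c₁, c₂,
e₁, e₂ as functions of n. Fu's Fs takes θ̂ = π (mean pairwise differences),
computes S′ = P(K ≥ k_obs | θ̂, n) under the Ewens sampling formula — with
unsigned Stirling numbers of the first kind evaluated in log space via the
|S_n^k| = |S_{n−1}^{k−1}| + (n−1)|S_{n−1}^k| recurrence, stable for n ≤ 200
and θ ∈ [10⁻³, 10³] — and returns the log-odds ln(S′/(1−S′)), computed as
the difference of the two complementary log-tail sums so neither tail
underflows. For n = 2 with both haplotypes distinct this reduces exactly to
ln θ̂.

**Monomorphic convention.** When S = 0 both statistics are reported as 0
with an `undefined` flag; scenario means include these zeros (keeping
1,000-replicate means well defined), and no significance call is made.

**Nulls.** Significance is assessed against empirical distributions from
isochronous constant-size Kingman genealogies with exactly S mutations
placed multinomially on branches proportional to length (fixed-S, i.e.
Hudson conditioning; infinite sites). Conditioning on the observed S rather
than on a θ estimate makes the null free of nuisance scale parameters and
allows memoization by (n, S): within a run each distinct conditioning is
simulated once, which is what keeps the full grid tractable. The null stream
for a given (n, S) is seeded from its own spawn key, so results are
independent of evaluation order. One-sided p-values use the plus-one
estimator (count + 1)/(reps + 1); a statistic is called significant in a
tail only if it also has the corresponding sign. Default α = 0.05 per tail
for both D and Fs; the stricter Fs convention (α = 0.02) is available via
the `alpha_fs` argument.

## Scenario grid

Each cell runs 1,000 replicate chains (genealogy → mutations → summaries →
D/Fs → significance) with per-replicate seeds spawned from the scenario seed
by replicate index, and per-scenario seeds spawned from the master seed by
grid index (`SeedSequence(entropy, spawn_key)`), so every replicate is
reproducible in isolation. The 95% interval column is the empirical
2.5/97.5 percentile range of the replicate values. Box-plot export covers
the constant-size (g = 0) cells and attaches median, quartiles and 1.5·IQR
whiskers per (scheme, Ne) group.

## Divergence statistics

Pairwise distances are plain mismatch counts with *pairwise deletion*: any
site carrying a gap or a non-ACGT symbol in either sequence of a pair is
excluded for that pair. The difference count itself is used as the squared
distance δ² in the AMOVA sums — the convention of the AMOVA framework when
"number of differences" is the chosen molecular distance. The two-level
decomposition is

    SSD_total  = (1/2N) Σ_ij δ²_ij,   SSD_within = Σ_k (1/2n_k) Σ_{i,j∈k} δ²_ij,
    σ²_w = SSD_within/(N−K),  σ²_a = (SSD_among/(K−1) − σ²_w)/n′,
    n′   = (N − Σ_k n_k²/N)/(K−1),    Φst = σ²_a/(σ²_a + σ²_w).

The permutation test shuffles individuals among groups (sizes fixed) and
uses the plus-one estimator on Φst(perm) ≥ Φst(obs). Bootstrap standard
errors resample individuals within groups — with a single locus there is no
locus level to resample — and are flagged unavailable (NaN) for groups of
size 1.

MDS is classical Torgerson scaling (double-centering of squared distances,
eigendecomposition, top positive-eigenvalue axes), with Kruskal stress-1
reported against the input distances. This is a metric method: it recovers a
Euclidean-embeddable matrix exactly (stress ≤ 10⁻⁶) but will differ from
nonmetric algorithms (e.g. ALSCAL) on matrices that are far from Euclidean,
so stress values are not comparable across the two families.

**Synthetic two-group datasets.** `generate_structured_dataset` samples both
groups from one panmictic genealogy — making the grouping exchangeable, so
Φst ≈ 0 and permutation p-values are calibrated when no fixed differences
are injected — and then forces a chosen number of sites to alternative fixed
states between groups to mimic diverged haplogroups. It emulates haplogroup
*frequency* contrasts, not isolation-with-migration history: between-group
coalescence is that of a single population, so it cannot be used to study
divergence-time estimation.

## Problem sizes

The shipped test-and-reproduction runs use 1,000 replicates per scenario
cell with 1,000-draw nulls (the study design), 10⁴ replicates for the
isochronous calibration check, and 3,000–10,000 Monte-Carlo draws for
closed-form comparisons at 3 standard errors; cross-validation against an
independent coalescent simulator (msprime) uses 3,000–5,000 draws with a
Kolmogorov–Smirnov criterion.

## Limitations

* The default heterochronous age fixture is an even spacing over the
  2,000–12,000 BP span. Against published per-cell values obtained with the
  real (unpublished) radiocarbon ages, the isochronous cells and the
  heterochronous D means reproduce well, but heterochronous Fu's Fs —
  which amplifies the excess-haplotype signal — comes out systematically
  more negative here, consistent with the even fixture overstating the
  temporal spread of the real collection. Conclusions about the *direction
  and Ne-dependence* of the bias are robust to this; exact Fs percentages
  are not.
* Passing tests on simulated data show the statistical machinery is correct
  under the model; real ancient-DNA data add post-mortem damage,
  contamination, alignment gaps and non-uniform age distributions that the
  generator does not emulate (gaps/ambiguities are handled only at the
  distance-computation stage).
* No migration/structure, recombination, selection, or across-site rate
  heterogeneity in the simulator; no nonmetric MDS; no Bayesian demographic
  inference.
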