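# Methods

## Rate estimation chain

A MLH1 focus on a pachytene bivalent marks one reciprocal crossover, and one
crossover corresponds to 50 cM of genetic map (a crossover recombines half
the meiotic products). For a species with mean focus count $\bar{f}$ per
spermatocyte and genome size $G$ Mbp,

$$\text{map length} = 50\,\bar{f}\ \text{cM}, \qquad
  \text{rate} = \frac{50\,\bar{f}}{G}\ \text{cM/Mb}.$$

C-values convert to physical size at 978 Mbp per pg. Foci are counted on
autosomal bivalents only (the XY pair follows a different recombination
dynamic), so the haploid autosome number of an XY male is $(2n-2)/2$.

All arithmetic is carried at full floating precision; rounding is applied
only at the reporting boundary (Mbp and cM to the nearest integer, rates to
two decimals, means/SDs to one decimal, ties away from zero). Species SDs
use the sample ($n-1$) denominator. The cross-species average rate is the
unweighted mean over species — each species one vote, regardless of how many
cells were scored — and the "between-species variation" statistic is defined
here as (max mean foci − min mean foci)/grand mean, which evaluates to 3.3%
on the study species; other definitions of that spread exist and the
package documents rather than guesses the original one.

## Crossover-minimum analysis

Meiotic segregation requires ≥1 crossover per bivalent; the stricter regime
requires ≥1 per chromosome arm. A cell is *below* a floor only under strict
inequality — exactly aFN/2 foci can satisfy one-per-arm. Species-level
regime calls compare the species *mean* to aN/2 and aFN/2 (three regimes:
arm minimum met, chromosome minimum only, below chromosome minimum), while
the per-cell statistic — the fraction of cells under the per-arm floor — is
reported both pooled over all cells and species-averaged, because the two
weightings answer different questions and the pooled count depends on the
per-species sample sizes. Zero-focus bivalent frequency is only defined
when per-bivalent counts exist; with none present the result is explicitly
"not computable", never silently zero.

## Inferential machinery

`stats_core` is self-contained so that no opaque dependency sits in the
inference path.

- **One-way ANOVA**: textbook between/within sums of squares;
  $F = \mathrm{MS_B}/\mathrm{MS_W}$ with upper-tail p from the regularized
  incomplete beta function, evaluated by a modified Lentz continued
  fraction (convergence tolerance 1e-14, ≤300 iterations; agreement with an
  independent implementation is tested to 1e-10). Zero pooled within-group
  variance is an error, not F = ∞.
- **Spearman**: average ranks under ties; rho is the Pearson correlation of
  the rank vectors (the tie-corrected form). For n ≤ 9 the two-sided
  p-value is exact, enumerating all n! permutations of one rank vector
  (9! = 362 880; the tie-free null distribution is cached per n, so
  repeated calls — e.g. 1000 null replicates — cost a sorted-array lookup).
  For n > 9 the Student-t approximation with n − 2 df is used and the
  result records which method produced its p.
- **Sign convention**: divergence times are negated before ranking, so a
  positive rho means *younger clades recombine more*. This keeps the
  printed sign of the correlation positive for the relationship usually
  described as "lower rates in more basal clades".

Clade means are unweighted over included species; species appearing under
several measurement methods are averaged into one record first (logged), so
no species is double-counted. Linkage-map entries lacking known deep
coverage are excluded from all aggregates (shallow maps understate map
length) but retain their rate for reporting. The leave-one-out sensitivity
table flags clades whose removal moves the correlation p-value across a
chosen α (default 0.05).

## Synthetic-data generators

**Spermatocytes.** The published evidence constrains per-cell totals (mean,
SD, range per species) plus one per-bivalent fact (<1% of bivalents lack a
focus). The generator targets those summaries, not a mechanism: each of the
aN/2 bivalents gets an obligate focus with probability 1 − ε (default
ε = 0.005), and a per-cell number of extra foci is drawn from a
binomial / Poisson / negative-binomial law moment-matched to the residual
mean and variance, then spread multinomially over bivalents with weights
proportional to a linearly decreasing size proxy. Integer moment-matching
keeps the SD bias under ~0.1 focus for the study parameterizations; means
are exact in expectation. Defaults reproduce the study design: cell counts
30/36/37/31 (total 134), means 39.2/39.3/39.5/38.2, SDs 2.2/2.2/1.9/1.9.

What this stand-in does *not* reproduce: the true joint per-bivalent
distribution, crossover interference, inter-animal heterogeneity, or any
higher-moment structure of the real counts. Consequences worth stating:

- Statistics that depend on distribution *tails* — notably the fraction of
  cells below the per-arm floor — are only approximated. Under pure
  moment-matching the expected pooled fraction is ≈78% versus the ≈70%
  observed in the real cells (the real *D. hybridus* distribution evidently
  puts more mass at ≥38 foci than a moment-matched law does). The
  acceptance check therefore uses a pre-registered ±15-percentage-point
  band around 70%.
- The between-species F statistic on a simulated 134-cell dataset is a
  noncentral-F draw with substantial spread; the published F = 2.468 is
  checked for *coverage* — it must lie in the central 99% band of 300
  replicate simulated F values — not reproduced as a point value.

**Comparative database.** Nine clades (Marsupialia, Afrotheria,
Eulipotyphla, Primates, Xenarthra, Rodentia, Lagomorpha, Artiodactyla,
Carnivora) with fixed mean divergence times and base rates set once from
the published clade values (0.29 cM/Mb for Marsupialia and Afrotheria, 0.45
for Xenarthra) and the observed qualitative ordering of the remaining
clades; basal clades carry larger typical genomes so that the map-length
(cM) correlation comes out weaker than the rate correlation, as observed.
Each clade contributes 9 species (81 total, near the real database's 85):
rates scatter around `base_rate + signal_strength × recency` with Gaussian
noise (default SD 0.05 cM/Mb, so a clade-mean standard error of ≈0.017);
genome sizes scatter log-normally (CV 0.10) around the clade-typical size;
methods cycle chiasmata/MLH1/linkage with linkage rows deep-coverage
flagged. `signal_strength` defaults to 0 because the default base rates
already carry the empirical trend; setting base rates equal and
`signal_strength = 0` yields an exchangeable null under which the exact
Spearman test's rejection rate is calibrated (0.05 ± 0.02 over 1000
replicates in the acceptance suite). Pre-registered acceptance bands for
the stand-in statistics derive from this design: clade means to ±0.04
(≈2.4 standard errors), the rate correlation to ±0.12 and the map-length
correlation to ±0.15 of the published values (rank correlations at n = 9
move in steps of 1/60 ≈ 0.017, and adjacent clade rates differ by as
little as ~2 noise SEs, so occasional single-rank swaps are expected).

Everything is driven by `numpy.random.default_rng` with an explicit seed;
per-species streams are spawned via `SeedSequence`, and identical seeds
give byte-identical CSV output.

## Problem sizes

The default analyses use the study-scale inputs: 134 cells over 4 species,
81 database species over 9 clades. Calibration checks run 10 000 cells per
species; the F-coverage band uses 300 replicate datasets and the null
calibration 1000 replicate databases (with 2 species per clade — the clade
means, not the within-clade count, carry the null). Exact Spearman p-values
at n = 9 enumerate 362 880 permutations once and cache the null.

## Known limitations

- The generators target printed summaries; conclusions about real per-cell
  data should rest on the deterministic chain and the published tables, not
  on stand-in tail statistics.
- No formal phylogenetic comparative methods (PGLS, independent contrasts):
  the clade-level rank correlation treats clades as exchangeable points, as
  the original analysis does.
- The ANOVA assumes independent cells; animals within species are not
  modelled as a random effect (per-animal structure is not published).
- Exact Spearman p-values are limited to n ≤ 9 pairs; beyond that the
  t-approximation is reported and labelled as such.
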