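# Methods

`structne` studies how population structure biases linkage-disequilibrium
(LD) estimates of *recent historical* effective population size. It couples
a forward Wright–Fisher simulator of structured populations with a
moment-based LD→Ne estimator, a PCA structure screen, and the two remedies
that recover unbiased estimates: restricting the cohort to one inferred
group, and masking the genomic region spanned by a chromosomal inversion.

## The simulation model

Diploid individuals in one or more demes reproduce in discrete,
non-overlapping generations. Each offspring draws a parental deme (backward
migration, below), then two **distinct** parents from that deme with
probability proportional to fitness; each parent contributes one recombinant
gamete. The model is neutral except for the inversion fitness scheme.

* **Genome.** A single linear sequence of length *L* bp with a uniform
  genetic map (`map_rate`, Morgans/bp; the full-scale designs use 250 Mb at
  1 cM/Mb = 1e-8 M/bp). `n_chromosomes` independent replicates of the
  sequence are simulated per run and pooled at estimation time, mimicking a
  multi-chromosome genome.
* **Recombination.** Crossover count per meiosis is Poisson with mean equal
  to the map length; positions are uniform. Alleles at positions at or right
  of a crossover switch parental haplotype.
* **Mutation.** Neutral infinite-sites: Poisson(*L·μ*) new derived alleles
  per gamete at uniform positions, resampling any collision with a
  segregating site. Fixed and lost sites are pruned every generation; this
  never changes any genotype contrast because only segregating sites are
  exported.
* **Migration.** Backward model: an offspring in deme *i* has migrant
  parentage with probability *m*; the parental deme is uniform over the
  other *n − 1* demes (reciprocal/island model) or is the large source deme
  (source–sink, where the source itself never receives migrants). Backward
  migration keeps deme sizes exact every generation, matching the standard
  Wright–Fisher metapopulation convention. Pulsed migration (`migration_period
  = p`) applies *m* only in offspring generations divisible by *p*.
* **Demographic events** are declared in generations before present
  (generation 0 = the sampled generation) and converted to forward indices
  internally. An event at time *t* takes effect when the generation at
  *t − 1* before present is produced, so a deme "admixed *t* generations
  ago" has experienced exactly *t* reproduction steps at sampling. Splits
  found daughter demes by sampling parents from the ancestral deme; admixture
  draws every offspring's parental deme uniformly over the source demes and
  retires them.
* **Inversion.** A single interval with two haplotype orientations.
  Crossovers falling inside the interval in inversion *heterozygotes* are
  discarded (not relocated) — recombination suppression is absolute, which
  the tests verify exactly. Carrier individuals have fitness
  `w(q) = 1 − (q − 0.5)·s` with `s = 0.2` and *q* the current deme frequency
  of the inversion: neutral at q = 0.5, favoured below, disfavoured above,
  i.e. balancing frequency-dependent selection. `balanced` mode introduces
  one inverted haplotype at the start of the run and retries any replicate
  that loses it; `recent_low` mode introduces `initial_copies` haplotypes
  `introduce_time` generations before present so the inversion is still rare
  when sampled. Both initialization choices are configuration-exposed
  because there is no single canonical way to seed a balanced polymorphism.
* **Reproducibility.** One master seed per scenario; per-chromosome streams
  are spawned from `numpy.random.SeedSequence(seed)` in a fixed order, so
  runs are bit-reproducible and chromosome replicates independent.

Implementation note: the population is stored as a dense 0/1 haplotype
matrix over currently segregating positions, so a whole generation of
meioses is produced with vectorized array operations (crossover parity via a
cumulative-sum trick). The op-level `make_gamete` exposes a single sparse
meiosis with the same crossover model for inspection and unit testing.

## Expected-NeVk reference lines

The comparison baseline is the variance-of-progeny effective size: for a
panmictic Wright–Fisher deme, NeVk equals the diploid census size *N*; with
several contemporaneous demes the total reference is the **sum** of deme
sizes, and the focal (lower) line is the sampled deme's own size. The
reference is piecewise constant between demographic events. Mating without
selfing makes the realized NeVk exceed *N* by ~*N*/(2*N* − 1) ≈ 0.5
individuals; this O(1/N) effect is ignored.

## The LD → Ne estimator

For unphased diploid genotypes the package uses composite LD: r² is the
squared Pearson correlation of dosage vectors, which requires no phase.
For a random-mating population of effective size *N*, the expected value at
recombination distance *c* Morgans is approximately

    E[r²(c)] ≈ 1 / (α + 4Nc) + 1/n ,   α = 2 (unphased),  n diploids,

and LD at distance *c* predominantly reflects drift around t = 1/(2c)
generations ago. The estimator therefore:

1. enumerates all intra-chromosome SNP pairs with c ∈ [0.001, 0.05] Morgan
   (the same range used for the published analyses; c = 0.001 maps to the
   ≈ 500-generation horizon),
2. averages r² within 30 log-spaced distance bins (geometric midpoints),
   pooling chromosomes by pair-count-weighted means, with an optional
   100,000-pairs-per-bin seeded subsample cap,
3. subtracts the 1/n sampling inflation (toggleable), and
4. inverts the relation per bin: `Ne_hat(c) = (1/r2_adj − α)/(4c)` at
   `t = 1/(2c)`.

Bins with corrected r² outside (0, 1/α) have no positive solution and are
dropped (counted in the trajectory metadata). Genetic distance is used as
map distance directly: with c ≤ 0.05 a Haldane correction changes nothing
material. No smoothing or interpolation between bins is applied; the
trajectory is reported at the mapped bin times only. A split-halves mode
pools the chromosomes into two groups, estimates each, and averages the two
Ne curves.

This is a transparent moment estimator, not a re-implementation of a
genetic-algorithm trajectory fit; it reproduces the *phenomenology* of
structure-induced biases (direction, time window, remedy response), which is
what the acceptance suite asserts. Figure-level numeric agreement with any
specific software is out of scope.

## Structure screen and remedies

PCA on centered, unit-variance dosages (sign-canonicalized so the
largest-magnitude SNP loading of each component is positive, making runs
deterministic); k-means with 10 restarts on the top two components assigns
groups, labels canonicalized by group size then PC1 mean. Default 2 groups;
a heuristic group-count hint is available but never auto-applied — deciding
that structure is "clear" is a user call. The remedy re-runs the full
estimation on one inferred group after re-filtering monomorphic/low-MAF
sites. For inversions, the remedy is masking: all SNPs inside the inversion
interval are removed before estimation.

## Scenario presets and desk-scale rescaling

Full-scale presets cover every study condition: synthetic populations (two
or five sources of N = 1000 diverging T = 1000 generations, mixed into
N = 100 or 1000 at t ∈ {5, 10, 20, 50}), two demes of 1000 with Nm ∈
{1, 2, 5, 10, 20} plus a pulsed variant, a ten-deme island model of 500
with Nm ∈ {0.05 … 20}, source–sink designs (source 10,000 → sink 1000 with
recent decline/bottleneck/expansion variants; post-change sizes mirror the
inversion designs — decline/bottleneck to 100, expansion to 10,000 — since
they are free parameters, all overridable), and a closed population of 1000
with a 50 Mb mid-sequence inversion. Full-scale runs use 250 Mb, 20
chromosomes, μ = 2e-9 (within the 1–5e-9 range; the exact value per design
is a free parameter) and 10,000 generations.

Each preset ships a `-desk` variant rescaled by a factor of 10 (5 for the
panmictic design, giving N = 200) on a 10 Mb × 4-chromosome genome.
Rescaling preserves the diffusion-compound parameters: sizes ÷ f; mutation,
map and *effective* migration rates × f; event times and run length ÷ f.
Two subtleties:

* **Pulsed migration.** Scaling both the per-pulse rate (× f) and the pulse
  period (÷ f) would inflate gene flow by f²; what must be preserved is the
  effective per-generation rate m/period, so the period is divided (floored
  at 1) and the per-pulse rate adjusted to keep m/period × f. The
  pulsed-versus-continuous distinction is inherently lost once the period
  reaches 1 generation.
* **Inversion selection.** N·s is the invariant, so the selection
  coefficient is multiplied by f, capped at 1.9 to keep carrier fitness
  positive at all q. Without this the stationary spread of q around 0.5
  (sd ≈ sqrt(0.5/(N·s))) would widen under rescaling and the balanced
  polymorphism would not be comparable across scales.

Desk-scale runs (N per deme ≈ 100–200, 1000–2000 generations ≥ 10 N of
burn-in, 4 chromosomes of 10 Mb, ~1–2 k filtered SNPs per cohort) complete
in seconds each; the test suite uses 10 replicates per scenario family.

## What the generator does and does not emulate

The simulator reproduces the study conditions: neutral variation, uniform
map, exact Wright–Fisher reproduction, island/source–sink migration,
admixture, and inversion mechanics. It does **not** model variable
recombination maps, gene conversion, crossover interference, double
reduction of suppressed crossovers (they are discarded, not relocated —
mirroring the usual zero-recombination-region recipe), genotyping error,
missing data, selection outside the inversion, or partial exchange in the
center of old inversions. Passing tests therefore demonstrate the
structure-bias phenomenology under idealized WF dynamics, not estimator
performance on real data artifacts.

## Numerical and design choices

* MAF filter default 0.05 before estimation (configurable; no canonical
  value exists for this pipeline stage).
* Dosage alleles exported as A (ancestral, REF) / T (derived), unphased;
  internal coordinates 0-based half-open, PED/MAP and VCF 1-based.
* r² of a constant dosage vector is undefined; such pairs are skipped
  (post-MAF-filter matrices contain none).
* Ties/degenerate inputs: bins with zero pairs are carried as NaN and
  ignored at pooling; an estimation with *every* bin dropped raises an
  error reporting the adjusted-r² range rather than returning an empty
  trajectory.
* k-means uses 10 restarts with a seeded state; PCA uses the deterministic
  full SVD solver.
* Reported time windows in CLI reports: recent t ≤ 20, mid 20 < t ≤ 100,
  ancestral t > 100 generations, summarized by the median Ne_hat per window
  and its log-ratio to the reference lines.

## Known limitations

* The moment estimator shares the Sved-form approximation's mild upward
  drift of Ne_hat in the most ancestral bins (few pairs, small c); the
  acceptance checks are therefore medians over windows and directional
  signs over replicates.
* `bin_to_time` is the standard heuristic mapping, not an inversion of a
  full recurrence; trajectories are comparative diagnostics, not dated
  reconstructions.
* Very high migration (m close to 1) and overlapping generations are out of
  scope; deme sizes below 2 are rejected.
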