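# Methods

`rhoflow` quantifies how gene flow biases linkage-disequilibrium-based
estimates of the population-scaled recombination rate ρ = 4N<sub>e</sub>r.
It contains three layers: a forward-time Wright–Fisher simulator of
isolation-with-migration (IWM) demographies, a pairwise
composite-likelihood estimator of a uniform per-site ρ backed by
Monte-Carlo two-locus lookup tables, and an experiment harness that turns
replicate estimates into bias and variance summaries.

## Demographic model and rescaling

All runs are parameterized by genome-wide averages for *Drosophila
melanogaster*: per-site mutation rate μ = 5.49 × 10⁻⁹, per-site crossover
rate r = 2.23 × 10⁻⁸ (2.23 cM/Mb) and N<sub>e</sub> = 1.72 × 10⁶.  A
population this large cannot be iterated generation-by-generation, so the
standard rescaling is applied: an in-silico population of `N_model`
diploids with per-generation rates inflated by Q = N<sub>e</sub>/N_model
and durations shrunk by Q.  The population-scaled quantities θ/site =
4Nμ = 0.0378, ρ/site = 4Nr = 0.1534 and N·m are invariant under this
transformation (enforced as an invariant of `rhoflow.scaling.rescale`).

The demographic timeline: an ancestral population evolves for a 35 × 10⁶
actual-generation burn-in (≈ 20 N<sub>e</sub>, within the customary
10–20 N<sub>e</sub> practice), splits into two daughters of half size, and
the daughters exchange migrants with per-generation probability
m = Nem/(N_model/2) either from the split onward ("continuous") or only
after a 1.7 × 10⁶-generation isolation period ("secondary contact"; the
isolation span yields F<sub>ST</sub> ≈ 0.4–0.5 at contact).  Genotype
samples of 25 diploids per population are drawn at the migration onset and
every 1,751 actual generations thereafter, until 51,000 generations after
the onset.  Sampling is anchored at the onset rather than the split
because for secondary contact the 51,000-generation sampled window would
otherwise fall entirely inside the isolation phase; for continuous gene
flow the two anchors coincide.  Optionally population 2's crossover rate
is doubled at the split (the "recombination change" treatment, expected
detected divergence +2.23 cM/Mb).

## Forward simulator

`rhoflow.wf` implements a discrete-generation diploid Wright–Fisher model
on a 0-based integer genome.  Each offspring draws two parents uniformly
(selfing possible) from its parental pool; with probability m both parents
come from the other subpopulation, matching the offspring-fraction
semantics of standard WF migration.  Gametes receive
Poisson(r·L) crossovers placed uniformly (no interference, uniform map)
using the *parent's* population rate, and Poisson(μ·L) new mutations under
an approximate infinite-sites model (integer positions, redrawn on
collision with a currently segregating site).  Haplotypes are stored as a
0/1 matrix over currently tracked variant columns; lost columns are
dropped each generation and fixed columns are purged on a configurable
interval with a substitution log.  Collision checks consult segregating
sites only, which makes every sampled statistic exactly independent of the
purge interval (property-tested).  Randomness is split into independent
reproduction, mutation and sampling streams derived from one root seed, so
drawing samples never perturbs a trajectory.

Paired two-population samples share a column set assessed on the union of
the two samples, so between-population fixed differences survive
extraction and Hudson's F<sub>ST</sub> (ratio-of-sums estimator; the
fewest-choices standard for simulated haplotypes) is computable directly.

## Two-locus lookup tables

The estimator needs P(two-locus haplotype-count configuration | ρ_pair)
for a sample of `table_n = 20` haplotypes, conditional on both loci being
biallelic, over a grid of per-pair scaled rates ρ_pair = 4N·r·d (0 plus 15
log-spaced values over 0.1–200).  These are estimated by simulating
two-locus ancestral histories: lineages carry ancestral material at one or
both loci, any pair coalesces at rate k(k−1)/2 scaled by the
piecewise-constant relative population size of the current epoch, and
both-locus lineages split at rate ρ_pair/2.  Size histories are expressed
relative to the sampled population's contemporary size, which is also the
reference size for back-transforming ρ̂ to cM/Mb.

Conditioning on segregation uses the small-θ limit directly: exactly one
mutation per locus is placed uniformly along that locus's marginal branch
length, and the genealogy is weighted by the product of the two marginal
tree lengths (the probability of observing one mutation at each locus is
proportional to that product as θ → 0).  The tabulation is
Rao-Blackwellized: every pair of branch segments contributes weight
len<sub>A</sub>·len<sub>B</sub>, which converges roughly two orders of
magnitude faster per genealogy than a single placement.  A finite-θ
rejection mode (Poisson thinning on "exactly one mutation per locus") is
retained for cross-validation; its acceptance rate at realistic θ is a few
percent, which is why it is not the default.  Additional numerical
choices: per-cell ratio-estimator variances are stored and used for a
first-order Jensen correction of log P̂ (capped at 0.7), unobserved cells
are floored at half a Monte-Carlo count, and all grid columns reuse one
random stream (common random numbers) so Monte-Carlo noise deforms the
likelihood surface smoothly instead of jittering neighbouring columns.
Configurations are stored folded (allele relabelling at either locus and
locus exchange), matching how observed pairs are folded before lookup.

The table was validated against an independent oracle: msprime
two-site genealogies with exact edge-pair enumeration agree with the
tabulated configuration distributions to within Monte-Carlo noise at both
ρ_pair = 0 and moderate ρ_pair, and the branch-length-weighted marginal
spectrum reproduces the neutral 1/i law.

## Composite-likelihood estimation

`composite_rho` maximizes a Hudson-style pairwise composite log-likelihood
over candidate uniform per-site rates: each retained site pair contributes
log P(config | ρ_site · distance), linearly interpolated on
log-transformed grid coordinates, and the summed objective is maximized by
a coarse log-spaced candidate scan plus two local refinements.

Down-projection of an n = 50-haplotype sample to the 20-haplotype table is
*realized by hypergeometric subsampling*: five random draws of 20
haplotypes are taken, site pairs are selected (MAF and distance filters)
within each draw, and the pooled objective is maximized once.  Selecting
pairs at the table's own sample size keeps the frequency ascertainment of
the data consistent with the table's conditioning; on exact coalescent
input this estimator recovers the true ρ/site with a ratio of 1.00.  The
analytic alternative — projection-weight expectation over table
configurations — is retained as `mode="expectation"`; because its pairs
are ascertained at n = 50 while the table conditions at n = 20 it carries
a reproducible upward bias of roughly +10% and is used only as a
cross-check.  (A third variant, the log of the projection-weighted mean
probability, is badly non-centered — up to several-fold — and is not
offered.)  The Sved-type moment estimator, solving E[r²] − 1/n =
1/(1 + ρ_pair) per distance bin and regressing ρ_pair on distance through
the origin, serves as a fast order-of-magnitude cross-check; the two
estimators correlate positively across replicates.

Estimator defaults: `d_max = 2.5 kb` (so ρ_pair stays within the table
grid at the true rate), 1,500 pairs per subsample draw, candidate range
derived from the grid and the distance distribution.  The experiment
pipeline sets `maf_min = 0.05`, which at the 20-haplotype subsample scale
keeps singletons: migration-associated LD at low Nem is carried by
low-frequency immigrant alleles, and filtering at MAF ≥ 0.1 (the
`popgen_stats` default for generic LD summaries) measurably suppresses the
very signal under study while leaving equilibrium calibration unchanged
within tolerance.

## Experiment harness and scale presets

The desk preset runs N_model = 200 (100 for single-population equilibrium
calibration), L = 20 kb, 10–20 replicates, preserving θ/site, ρ/site and
all durations in units of N; a full run then takes minutes on one CPU.
The paper-scale preset (N = 1000, L = 100 kb, 100 replicates) is available
for larger machines.  One deliberate exception: continuous-gene-flow cells
at Nem = 100 run at N_model = 250, because with m = Nem/(N/2) any
N ≤ 200 forces m ≥ 1 — at m = 1 the two offspring pools swap wholesale
every generation and never mix, so the coupling effect the cell is meant
to measure cannot occur (measured bias ≈ 0).  N = 250 (m = 0.8) is the
smallest size at which Nem = 100 still describes genuine gene flow.

Within each replicate all cells branch from a single burn-in state, and
secondary-contact cells additionally share the isolation phase per
recombination setting; because migration is inactive before contact the
branching is exact (common random numbers), pairing each cell with its
Nem = 0 baseline and removing between-cell Monte-Carlo variance.
Lookup tables are built once per demographic context with the size change
placed at the midpoint of the sampling window (across the window the
change-time varies by under 2% of the coalescent timescale).

Percent bias is computed against the simulated Nem = 0 cell at matched
times — not against the analytic truth — which cancels estimator-intrinsic
offsets; pooled summaries average over populations, sampling times and
replicates.  The between-population contrast is the per-replicate
difference of back-transformed rates, p2 − p1, in cM/Mb.  The
variance-ratio test is a two-sided F-test (one-sided where an inflation
direction is predicted).  The original analysis's mixed model with random
intercepts for replicate and generation is approximated by absorbing both
factors as fixed group effects (within-group centering) in an OLS fit of
z-scored variables; coefficients are reported with conventional standard
errors and are not comparable to REML estimates from the full-scale study.

## What the synthetic data do and do not show

The generator reproduces the study's *design* — neutral Wright–Fisher
dynamics, uniform recombination and mutation maps, symmetric bidirectional
(or optional unidirectional) migration, instantaneous recombination-rate
change — at a rescaled population size.  It does not contain selection,
gene conversion, crossover interference, variable recombination maps,
sequencing error or missing data, so passing tests demonstrate the
internal consistency of the bias mechanisms (coupling at high gene flow,
migration-associated LD after secondary contact), not their magnitude in
any real data set.  Rescaling compresses the sampled window to a handful
of model generations, so time-resolved trajectories within the window are
coarser than at full scale, and the composite estimator carries a small
finite-sample inflation (of order +5–10% at N_model ≈ 100–200) that the
baseline-relative bias measures cancel by construction.

## Known limitations

- Exact two-locus likelihoods (Moran/ODE methods) and variable-rate map
  inference (fused-penalty windows) are out of scope; a single uniform
  ρ/site is estimated per sample.
- Lookup-table Monte-Carlo noise propagates into the estimator: column
  budgets below ~10⁴ genealogies per grid point shift replicate means by
  several percent.  The working budgets (8–20 × 10³, with the largest
  reserved for absolute-recovery checks and leaner ones for
  baseline-relative measures, where table error cancels) keep this below
  the tolerance of every check at a cost of one to two minutes per table.
- The secondary-contact grid at N_model = 200 cannot represent Nem > 100;
  the continuous Nem = 100 cell needs N_model ≥ 250 (see above).
- `hudson_fst` on unpaired samples treats positions absent from one sample
  as monomorphic ancestral; use paired draws for exact divergence.
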