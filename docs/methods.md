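# Methods

This note documents the models, conventions and numerical choices behind the
package, in the spirit of a statistical software methods appendix. It states
no empirical result beyond what the test suite and `scripts/acceptance.py`
compute.

## Mass budgets and indices

All budgets are on a dry-matter basis except the growth rate GR, which is
reported on fresh mass per larva (matching how growth trajectories are
observed). Per box:

* `I` — total substrate offered, summed over feeding events as
  fresh mass × dry fraction;
* `R` (total residue) — uneaten substrate plus egesta collected at the end
  day; used by SR and WRI;
* `E` — feed ingested. When the residue table separates egesta from uneaten
  substrate (the synthetic bundle does), `E = I − uneaten` exactly;
  otherwise egesta is estimated as residue minus uneaten, a convention the
  output flags;
* `R_e` (egesta) — used by AD and ECD. Carrying both residue quantities is
  deliberate: the two halves of this classical index family use the same
  letter for different collections, and conflating them produces
  inconsistent percentages;
* `A` — trapezoidal time-average of live dry biomass over the observation
  days (the "mean biomass during the feeding period" with unevenly spaced
  observations);
* `B` — end dry biomass (live plus pupated, each at its mass when counted)
  minus initial dry biomass. Dead larvae leave the live pool on the day
  recorded and do not enter `B`;
* `T` — days from diet introduction to the diet's termination day.

Division by zero in any index yields a flagged undefined value, never an
exception: a trial with no feeding events has no defined SR, and a
zero-assimilation box has no defined ECD.

Two identities hold for every valid budget and are enforced at 1e-9
relative tolerance: `ECI = ECD × AD / 100` and `WRI = SR / T`. Reported
tables round indices to one decimal and gram masses to three decimals.

Known reporting frictions in this index family, preserved rather than
hidden: a WRI printed at one decimal need not equal SR/T recomputed from
the rounded SR (the pipeline reports the unrounded quotient); and the
consumption index CI is sensitive to the mean-biomass convention, so CI is
reported but should not be compared across studies without checking that
convention.

## Synthetic feeding trial

The generator defines the study conditions: three diets (CFD chicken feed
control, FWD food waste, OWD oil waste), four boxes of 200 larvae each, fed
every second day over days 0–18, observed every second day, terminated at
day 18 (CFD), 20 (FWD) and 12 (OWD).

* **Growth.** Per-larva fresh mass follows a logistic
  `peak/(1+exp(−r(t−t_mid)))`; after the day the curve reaches 98% of its
  plateau, fresh mass declines linearly (modelled as water loss, so the
  dry-mass budget stays conservative). Defaults: FWD peaks at 206 mg around
  day 14 and loses ~3.3%/day afterwards; CFD peaks at 184 mg with a ~1.4%/day
  decline; OWD plateaus at 22 mg.
* **Feeding and ingestion.** Substrate is offered per feeding event as
  ration × interval × live count, into a per-box pool. Daily ingestion is
  demand-driven: the dry-mass increment required by the growth curve divided
  by digestibility × assimilation efficiency, capped by an
  ingestion-capacity limit (mg dry per mg larva per day) and by the pool.
  No per-day consumption measurements exist for such trials, so this rule is
  a modelling choice, not a reconstruction; it keeps budgets exactly
  conservative: offered = ingested + uneaten, and
  gain = digestibility × assimilation × ingested.
* **Two efficiencies.** Ingested feed splits into egesta
  (`1 − digestibility`), respiration (`digestibility × (1 − assimilation)`)
  and biomass. Digestibility is the truth behind AD, assimilation the truth
  behind ECD. A single-efficiency model cannot generate data in which AD and
  ECD differ — and they demonstrably do — so the generator carries both
  (CFD 0.477/0.375, FWD 0.827/0.30, OWD 0.30/0.20).
* **Mortality.** Piecewise-constant hazard, zero before a lag day. The OWD
  default (`lag 5 d, hazard ln(25)/7 ≈ 0.46 d⁻¹`) yields ~96% cumulative
  mortality by day 12; survival follows `exp(−h·(t−lag))` and the simulated
  binomial deaths track that closed form within sampling error.
* **Pupation.** After a start day, each live larva pupates with a fixed
  daily probability; pupae retain the dry mass at pupation. OWD never
  pupates.
* **Truth.** `SyntheticTruth` returns the daily streams and per-box index
  values computed from the noise-free observables with inline formulas, so
  the estimator path (CSV → budget → indices) can be validated against it to
  1e-6 relative; the conservation identities are asserted in the
  hazard-free configuration, since mortality removes mass from the live
  pool by design.

Observation noise is available (`observation_cv`, default 0: multiplicative
log-normal on the mass observables) but off in the validation conditions.

## Substrate physicochemistry

Seven sample groups (three fresh substrates, three residues, pine-humus
litter) × 17 variables (pH; dry matter and volatile solids in %; C_tot,
N_tot, NH4, COD, protein, sugars, fat and a seven-acid VFA panel in g/kg
DM). Replicates are normal draws (fresh n=3, residues n=4) truncated at
zero, with sd = 6% of the mean (0.1 pH units for pH). The planted contrasts
encode the measured shifts: NH4 ×20 (CFD) and ×30 (FWD) in residues,
protein ×10 in all residues, food-waste pH 4.5 → ~7.8, and an oil waste
that passes through the process nearly unchanged — its fresh and residue
groups share every mean except protein, and its absolute protein level is
low so the pair genuinely overlaps in standardized space. That overlap is
the designed condition under which cluster-number selection should merge
the two OWD groups (six clusters from seven planted groups).

## Multivariate stage

PCA standardizes variables (they carry incommensurate units) and fixes
component signs by making each loading column's largest-magnitude entry
positive. Variable k-means runs on the first two loading columns with
k-means++ and 25 starts. Hierarchical clustering offers ward/average/
complete linkage via the standard linkage algorithms.

The gap statistic draws B reference datasets uniformly over the data's
bounding box in PCA-rotated coordinates (the original recommendation) and
selects the smallest k with `Gap(k) ≥ Gap(k+1) − s(k+1)`,
`s = sd_ref·√(1+1/B)` (the "first SE max" rule). A reported nonstandard
cutoff parameter for this decision exists in the literature this package
emulates but is not interpretable as any standard quantity; it is not
reproduced. Two caveats the tests respect: the k=1-vs-2 decision can fail
on pathologically tight, symmetric cluster geometries (a known property of
the SE rule), and on the seven-group substrate design the 6-vs-7 decision
is intrinsically borderline — consistent with the fact that a nonstandard
cutoff was needed to report the merge in the first place. The borderline
property is therefore asserted at a fixed seed, not across all seeds.

## Community statistics

* **Rarefaction** subsamples without replacement (multivariate
  hypergeometric); samples below the target depth are dropped with a
  warning. Depth lists accept a `min` sentinel resolved against the table
  at hand.
* **Prevalence filter**: keep taxa with count ≥ 4 in ≥ ceil(10% of samples)
  samples. The alternative reading ("present in ≥ 4 samples") is available
  as a mode switch.
* **Diversity**: H′ = −Σ p ln p; J = H′/ln S, with J ≡ 0 for S = 1. Natural
  logarithms throughout (a rich, even community of ~60 taxa then has H′
  near 4, matching the magnitudes this convention implies).
* **Bray-Curtis**: Σ|x−y|/Σ(x+y); equal on counts and proportions whenever
  sample sums are equal, which the rarefied tables guarantee.
* **NMDS**: Kruskal stress-1 with disparities from pool-adjacent-violators
  isotonic regression on dissimilarity ranks and Guttman-majorization
  configuration updates. Start 1 is classical metric scaling, the remaining
  starts random; best of 20 starts returned, coordinates centered.
  Convergence: relative stress change < 1e-6, up to 1000 iterations; the
  majorization tail is slow, so a run can return `converged=False` with a
  perfectly usable stress — never silently.
* **PERMANOVA**: one-way pseudo-F from the distance-based SS decomposition
  (`SS_total = Σ_{i<j} d²/n`, within-group analogues per group), upper-tail
  permutation p. Crossed diet×time designs are tested as a combined
  one-way factor plus the separate one-ways; no sequential/marginal
  multi-factor decomposition is claimed.
* **Mantel**: Pearson correlation of condensed distances, permuting one
  matrix's sample order.
* **Permutation p-values**: Monte-Carlo mode uses `(hits+1)/(n_perm+1)`
  with its implied floor; exhaustive mode (small designs) enumerates all
  distinct label assignments and reports the exact fraction reaching the
  observed statistic, e.g. 2/20 for a perfectly separated 3+3 design.

## Indicator consensus

The LDA-effect-size screen normalizes samples to per-mille, removes taxa
failing Kruskal-Wallis at α = 0.05 (constant taxa take p = 1), and scores
survivors as log10 of the largest between-class mean difference averaged
over 30 bootstrap resamples; scores ≥ 2.0 are significant. This is a
documented simplified effect-size procedure on the same per-mille scale as
the original biomarker tool, not a bit-reproduction of it; the α and
threshold defaults are the canonical ones and are exposed in config.

IndVal multi-level pattern analysis uses the group-size-corrected
statistic: for a group combination C, specificity
`A = Σ_{g∈C} mean_g / Σ_h mean_h`, fidelity `B` = fraction of C's samples
with the taxon present (count > 0, no pseudo-counts), `stat = √(A·B)`,
maximized over all non-trivial subsets of groups except the full set.
p-values permute sample labels against the same max-over-combinations
statistic. Note the statistical cost of that maximum: for taxa present in
every sample (fidelity 1 everywhere) the permutation null is dominated by
nearly-as-good combinations and power drops — one reason consensus rules
intersect two different screens.

A taxon is a **consensus indicator** when both screens are significant and
the LDA top class lies within the IndVal combination. Records below 1%
mean relative abundance are kept but flagged below the display threshold.

## Synthetic communities

Dirichlet-multinomial: expected composition = power-law baseline (a few
dominant taxa, a long tail) perturbed per sample by a Dirichlet with
concentration `dispersion × p`, counts multinomial at a gamma-Poisson
depth. One succession taxon follows a logistic relative-abundance path
(default 1% at day 2 → ~88% by day 20) in the waste diets; outside its
bloom it sits near 0.2% of the community, as observed for the bloom genus
in control guts and fresh substrates. Other taxa share the remaining mass
proportionally. `sampling=False` returns the expectation itself (the
infinite-dispersion limit).

What the generator does **not** emulate: sequencing error and chimeras,
phylogenetic structure among taxa, copy-number variation, compositional
correlations beyond the single bloom, and batch effects. Passing tests
therefore demonstrate that the estimators recover the planted structure
under a clean overdispersed sampling model — not that they are robust to
every artifact of real amplicon data.

## Functional projection

Pathway profiles are a linear projection: per sample, reads of taxa covered
by the reference are renormalized and multiplied through rows of a
taxon×pathway matrix whose covered rows sum to 1; the covered-read share is
reported as the fraction assigned (a sample with zero covered reads gets an
all-missing profile and fraction 0, logged). Aggregation to a coarser
hierarchy level sums member pathways and preserves totals. No external
pathway database ships with the package; the generator produces a random
reference with configurable coverage, and any user-supplied matrix in the
same layout works. Because the projection is linear and reference rows are
shared across taxa, planted taxonomic contrasts blur at the pathway level —
the package asserts this as a property (lower PERMANOVA R² on projected
profiles than on taxa when groups differ in taxa but share pathway
repertoires).

## Validation problem sizes

The default validation conditions are: trials with 4 boxes × 200 larvae per
diet; gut tables of 42 samples (diet × day × 3 replicates) × 60 taxa at a
mean depth of 5000 reads; 400 null datasets of 12 samples for the PERMANOVA
type-I calibration at 99 permutations; 20 seeds × 199 permutations for the
indicator-recovery study; 50 reference datasets for gap-statistic runs.
These sizes were chosen so each property is measured with adequate
resolution while the whole suite stays comfortably interactive.

## Known limitations

* The exhaustive permutation mode enumerates multiset permutations and is
  only for small designs (capped at 2×10⁵ assignments).
* The LDA screen is one-dimensional per feature; multi-feature discriminant
  structure (and the original tool's subclass conditioning) is out of
  scope.
* PERMANOVA is one-way; use the combined-factor label for crossed designs.
* The CI (consumption index) depends strongly on the mean-biomass
  convention and should be compared across studies with care.
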