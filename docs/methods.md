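# Methods

This note documents the models, algorithms, parameter choices and
known limitations of `famba`.  It is written for a reader who wants to
know exactly what each stage computes and what the test suite does and
does not demonstrate.

## Fatty-acid arithmetic

Fatty acids are identified by `C:Dn-x` shorthand; molar masses use the
free fatty acid formula C_nH_{2n−2d}O₂ with atomic masses 12.011,
1.008 and 15.999 g mol⁻¹.  GC quantification is performed on methyl
esters, but balance methods report free-acid moles, so the free-acid
mass is used throughout; the constant table is regenerable from the
formula.  Lumped class entries ("Other SFA", "Other n-3 PUFA") carry no
molecular identity: they participate in percent sums and series ratios
but never in molar conversions or the bioconversion pathway.

Composition profiles carry three scalars that bridge relative
composition to absolute amounts: total fatty-acid content (mg g⁻¹
lipid), lipid content (g g⁻¹ dry matter) and dry matter (g g⁻¹ as-is).
Percent scale is 0–100 everywhere in the API; fractions appear only
inside formulas.  Profile validation accepts percent sums in
[93, 100.5]: published composition tables leave a few percent of minor
unidentified GC peaks unreported, so the conventional ≈100 expectation
is relaxed downward to match real tables.

## Growth, biometry and digestibility

SGR is computed as 100·ln(W_f/W_i)/d.  A formula occasionally printed
as `100 × (ln W_f / ln W_i)/d` is treated as a typographical slip: it
is dimensionally unsound and does not reproduce tabulated trial values,
while the log-ratio form does.  Fulton's condition factor includes the
conventional ×100 factor (weights in g, fork length in cm) so salmonid
values land near 1.  Apparent digestibility coefficients outside
[0, 100] are reported as-is with a `DataQualityWarning`, never clamped:
they flag analytical inconsistency and clamping would hide it.

## Whole-body fatty-acid mass balance

The balance operates per tank on micromoles per fish.  Gross intake of
each acid is feed intake × dry matter × lipid × total-FA × percent/100
÷ molar mass; net intake multiplies by the acid's apparent
digestibility.  Body-pool appearance is the final minus initial carcass
pool, with the initial pool computed from a pooled initial-population
carcass composition applied to each tank's initial mean weight.

Attribution runs backward along a linear pathway (default: the omega-3
chain ALA→SDA→ETA→EPA→DPA→DHA; DPA→DHA is modelled as a single step
because no C24 intermediates are quantified in composition tables).
For each node, the conversion flux demanded from its precursor is
max(0, appearance + onward flux − net intake); at the head this demand
must be zero or the inputs are inconsistent (the head acid cannot be
synthesised) and a `MassBalanceError` is raised.  Each node's
disappearance is supply (net intake + inflow) minus raw appearance, so
a shrinking terminal pool folds into that node's own oxidation;
oxidation is disappearance minus onward conversion, floored at zero.
Every material clamp is logged with its magnitude (negatives within
1e-9 of zero, relative to supply, are treated as floating-point noise).
Closure (accumulated + disappeared = supply) holds to numerical
tolerance before clamping.

**Identifiability.** The balance observes only net pool changes, so
β-oxidation of *intermediate* pools is not separately identifiable:
when a downstream node oxidizes part of its supply, the backward method
under-attributes conversion and over-attributes oxidation at that node.
Recovery of simulated ground truth is therefore exact precisely when
downstream nodes only retain or convert (the regime the round-trip
oracle samples); this is a property of the balance method itself, not
of this implementation.

Treatment summaries average per-tank percentages by default
("mean of ratios", the convention of trial tables, which is why printed
percent rows differ slightly from ratios of printed means); a
ratio-of-means mode is available for cross-checks.

## Deposition metrics

The diet-to-tissue percent difference 100·(diet − tissue)/diet reads as
deposition inefficiency; it is undefined (reported missing) when the
dietary concentration is zero.  Absolute tissue contents (mg per 100 g
dry matter) use the profile's lipid and total-FA scalars; the bundled
muscle profiles carry the cross-treatment mean lipid content because
per-treatment values were not published, which leaves reconstructed
contents roughly 1% away from published rounded figures.

## Group statistics

The experimental unit is the tank.  The recirculation system enters as
an additive fixed block: with a balanced design and no interaction the
diet F-test is identical to a random-block analysis, and nothing in the
reported degrees-of-freedom structure can distinguish the two.  Levene
centering defaults to group means (the classic test, matching the
default of the original analysis tool); median centering
(Brown–Forsythe) is available.  Tukey–Kramer q statistics use the
blocked residual mean square and the studentized-range distribution
(`scipy.stats.studentized_range`).  The compact letter display uses the
insert-and-absorb algorithm; it guarantees that significant pairs share
no letter and non-significant pairs share at least one.  On
(near-)constant data the ANOVA F is defined as 0 (the decomposition is
numerical noise at machine precision).

## Proteomics differential abundance

Filtering keeps proteins with ≥ 2 unique peptides that are not
reverse-database or contaminant entries and are detected (intensity
> 0) in at least three samples of at least one diet group.  Zero is the
not-detected code (MaxQuant convention); values are log2-transformed
with zeros becoming missing, and missing entries are excluded
protein-wise with residual degrees of freedom adjusted — no imputation.

Cyclic loess normalization iterates over all sample pairs, fitting a
lowess curve of M = x_i − x_j on A = (x_i + x_j)/2 over jointly
observed entries and moving each sample half the fitted offset; span
0.7 and 3 cycles by default (both configurable).  Three cycles damp a
1-log2 single-sample shift to below 0.05; samples with fewer than 10
observed values are excluded from normalization with a warning.

Sample quality weights come from a gene-by-sample heteroscedastic
model: iterate per-protein weighted least squares and per-sample
variance factors estimated from leverage-corrected squared
standardized residuals, then normalize weights to geometric mean 1.
Non-convergence (tolerance 1e-4 on log weights, 50 iterations) falls
back to unit weights with a warning.

The per-protein linear model is diet + system (treatment coding);
proteins are fitted in batches grouped by missingness pattern, which
makes the per-pattern normal equations reusable and the fit fast.  The
empirical-Bayes prior (d₀, s₀²) is estimated by moment-matching the
marginal distribution of log residual variances (digamma/trigamma
relations, trigamma inverted by Newton iteration); posterior variances
s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g) give moderated t statistics on
d₀ + d_g degrees of freedom.  The estimates agree with the reference R
implementation (`limma::squeezeVar`) to ~1e-6 in the test suite, and
the un-moderated fit agrees with a direct weighted least-squares solve
to 1e-10.  All three pairwise diet contrasts are extracted;
Benjamini–Hochberg adjustment is applied within each contrast
(`statsmodels` implementation behind the package surface).  Note the BH
step-up is *not* idempotent on already-adjusted values; tests assert
order-invariance and monotonicity instead.

Fold changes are ratios of group means of raw (non-normalized)
intensities over detected values only, signed as −1/ratio when below
1, with "ND" marking proteins detected in only one group.  Significance
is reported at adjusted p < 0.1 (primary) and < 0.3 (exploratory).

## Synthetic data

Generators are pure functions of (config, seed).

`simulate_trial` emulates the study design: 3 diets × 4 tanks × 2
recirculation systems over 89 days, initial weight ≈ 106 g, feed
compositions and SGR/FER targets from the bundled reference tables.
Weights follow exponential growth with lognormal tank noise (CV 0.03
by default) and a ±2% multiplicative system effect on growth rate;
feed intake realises the target FER; faecal marker and nutrient
concentrations are consistent with the configured digestibilities
(dry-matter AD 69.4% sets the marker concentration factor; lipid
94.0%, protein 89.3%).  Per-fatty-acid digestibilities default to
per-class values (SFA 85%, MUFA 92%, PUFA 96%) chosen to be realistic
for salmonids and consistent with the overall lipid AD; the published
per-acid table is external, so these are generator conditions, not
reproductions.  Final carcass compositions realise configured ALA fate
fractions through the forward flux simulator (defaults derived from
the reference partition: FO ≈ 92/0/8, FOPO ≈ 76/24/0.3, TOFX ≈
59/41/0.7 percent accumulated/oxidized/bioconverted), with downstream
nodes retaining 90% and converting 10% (identifiable regime) and
non-pathway acids retained at 60%.  The initial carcass composition is
a synthetic stand-in: the reference initial-muscle fatty-acid profile
combined with carcass-level lipid (0.414 g g⁻¹ DM), dry matter (0.343)
and an assumed 900 mg g⁻¹ total-FA content, with an "Other SFA" filler
topping percents toward 100.

`simulate_proteome` draws protein baselines from N(21, 2²) in log2
(raw LFQ ≈ 2 × 10⁶), per-protein residual variances from a scaled
inverse-chi-square (prior df 4, scale 0.3² — matching the moderated-t
model, so null p-values are calibrated by construction), optional
additive sample shifts, per-sample variance inflation and spiked group
effects, and intensity-dependent detection (logistic in log2 intensity,
midpoint 16, scale 1), so low-abundance proteins go missing more often.

**What the generators do not emulate:** individual-fish variation
within tanks (records are tank means), within-trial growth curves,
correlated missingness across proteins, peptide-level effects, and any
feedback of diet on tissue lipid content.  Passing tests demonstrate
algorithmic correctness and statistical calibration under these
idealised conditions, not robustness to every pathology of real tank or
spectrometry data.

## Problem sizes and numerical choices

The calibration suites use 200 forward-flux draws, 2 000 null ANOVA
replicates (12 tanks each) and 200 null proteome replicates of 1 000
proteins × 12 samples — sizes at which Monte-Carlo error is small
relative to the tolerances asserted while the whole suite completes in
a few minutes on one core.  Loess smoothing uses `statsmodels` lowess
with a delta of 1% of the A-range for speed.  Tolerances: closure and
clamp-noise thresholds at 1e-9 relative; trigamma inversion to 1e-10
relative; oracle agreement asserted at 1e-10.

## Known limitations

* Intermediate-pool oxidation is unidentifiable from a whole-body
  balance (above); reported oxidation at downstream nodes is a lower
  bound on conversion-adjusted disappearance.
* Negative digestibilities and >100% values are passed through with
  warnings; downstream interpretation is the analyst's responsibility.
* The proteomics stage starts from a protein-group table; peptide
  inference, match-between-runs and database search are out of scope.
* The random-block structure is approximated by a fixed additive block;
  variance components for the system effect are not estimated (no REML).
* Reference tables are treatment means; tank-level raw data are not
  published, so reproductions of published statistics are limited to
  quantities derivable from printed means.
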