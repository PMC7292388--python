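# Methods

This note documents the statistical models, numerical choices, and known
limitations of the package, and what the synthetic-data generator does and
does not emulate.

## Scope and populations

The package quantifies ingestion of fecal contamination (indicated by
E. coli) in the public domain of urban neighborhoods, for adults and for
children aged 5-12, across a nine-pathway registry: drinking water, bathing
water, surface water, ocean water, flood water, open drains, public/shared
toilets, raw produce, and street food.  Soil is supported as a background
sample type: concentrations are computed but feed no exposure pathway.
Children under five, dose-response modeling, and within-household (private
domain) exposure are out of scope.

## Survey decoding

Behavior frequency is collected as ordered categories.  The default
category map decodes them to contacts/month using range midpoints, 30
days/month, and 4.33 weeks/month: never=0, <1/month=0.5, 1-3/month=2,
1-2/week=6.5, 3-5/week=17.3, daily=30.  The map is a configuration item,
not code: real instruments differ in answer wording, and the decoded values
are the single strongest untestable assumption in the survey arm.
Household, school, and community surveys collect identical questions and
are pooled by default (a config flag restricts to one type).  A missing
answer excludes the respondent from that pathway — "never" is an explicit
category and is never imputed.

For the NB likelihood the non-integer midpoints are rounded **half-up**;
notably 0.5 ("less than monthly") rounds to 1 and not to 0, because that
answer asserts nonzero contact, and collapsing it to zero materially
understates percent exposed on intermittent pathways.  A continuous
(gamma-mixture) likelihood would avoid rounding altogether; it is noted as
an alternative but is not the default.

## Dilution arithmetic and censoring

Each sample carries 2-3 readings (membrane filtration counts, or
pre-computed MPN values for tray methods — the well-to-MPN lookup itself is
not re-implemented).  The selection rule keeps all readings in the
countable range, default (20, 200) colonies, inclusive; if none qualify it
keeps the single reading nearest the range.  Per-reading concentration is
`count / (amount_assayed x dilution_factor) x denominator_scale`, and
multiple readings are averaged on the log10 scale (a geometric mean),
matching the downstream log-normal model.  All-zero samples are
left-censored at the detection limit of the most sensitive plate
(`1 / max(amount x dilution) x scale`); series that saturate even at the
most dilute plate are right-censored at the concentration a top-of-range
count would imply there.  Censored samples enter estimation through
normal-CDF likelihood terms, never by substitution, which at n=10 would
bias `mu` noticeably (a dedicated test quantifies this).

Adjacent dilutions whose implied concentrations differ by the conflict
factor (default 10x) **or more** are flagged for review; the boundary is
inclusive so that identical counts across a ten-fold step — exactly a 10x
discrepancy — are flagged.  Flags are informational and do not alter the
estimate.

## Samplers

Both fits are own-code MCMC, chosen over an external PPL binary so that
runs are dependency-free and bit-reproducible from a seed.

- Frequency: `p | r` has a conjugate Beta full conditional; `r` moves by
  random-walk Metropolis on `log r` with a Gamma prior.
- Concentration: `mu` and `log sigma` move by component-wise random-walk
  Metropolis against the censored normal likelihood, with Normal and
  Half-Normal priors.

Proposal scales adapt multiplicatively toward ~40% acceptance during
burn-in only, so post-burn-in chains are valid Metropolis chains and seeded
runs are exactly reproducible.  Defaults: 4 chains x 5,000 iterations,
1,000 burn-in.  Chains start from dispersed method-of-moments estimates;
split-chain R-hat and ESS (via arviz) are exposed on the posterior objects.
Degenerate inputs are handled without crashing: all-zero count vectors
return a near-zero-mean posterior with a warning; identical concentrations
return a prior-dominated sigma with a warning; an all-censored pathway is
refused (it carries no location information).  Posterior summaries use
type-7 (linear-interpolation) percentiles.

## Monte Carlo exposure

Two variance levels are represented: parameter uncertainty (one posterior
draw of each parameter pair per iteration) and individual variability (a
simulated cohort per iteration, default 1,000 individuals, 1,000
iterations).  "Exposed" means at least one contact in the month.  Each
contact's dose is `10^(c + log10 intake)` with `c` drawn independently per
contact; per-individual doses are summed over contacts.  The headline dose
metric is the mean of log10 monthly doses among the exposed; the
arithmetic-scale mean is also emitted.  Iterations with no exposed
individuals contribute percent-exposed of 0 and no dose value; a profile
with no dose-defined iteration is flagged rather than fabricated.

Hand-to-mouth pathways are reduced to an effective per-contact intake
volume-equivalent that folds surface-to-hand transfer, hand adherence, and
exposure duration into one constant per pathway x population.  The shipped
intake constants are **placeholders** of plausible magnitude (e.g. 250 mL
per drinking-water contact, 1 serving of produce, 0.01-0.04 units for
hand-to-mouth routes) and must be calibrated from local or literature data
before any substantive deployment; every number sits in the config file.
Dominance uses `mean_log10_dose + log10(pct/100)` with an inclusive 1-log10
threshold, reflecting the protocol's design resolution of one order of
magnitude.

## Synthetic deployments

The generator draws monthly counts from the ground-truth NB and *encodes*
them to answer categories (nearest midpoint, ties to the coarser category),
reproducing the information loss of a categorical instrument; the induced
bias is computable analytically (`effective_monthly_mean`, `decoding_bias`)
so recovery tests can separate instrument bias from estimation error.
Under the default map, NB(2, 0.3) has a decoded-mean bias of -9.4%, within
±10% and far under half the widest category gap (6.35 contacts/month).

Sample generation draws each sample's true log10 concentration from
`Normal(mu, sigma)` and gives each plate a Poisson count with mean
`10^c x amount x dilution / scale` (the standard plating-noise model; the
field protocols specify no count-noise model).  The assay series emulates
bench practice: 2-3 ten-fold steps in `amount x dilution`, varying volume
filtered (1-100 mL) for dilute matrices and dilution for concentrated
ones, with the least-dilute step targeting the top of the countable range
and two more-dilute insurance steps, because contamination skews high and a
fully saturated series loses more information than a saturated top plate.
Counts above the countable range are written TNTC.

The default survey battery is 100 household surveys plus four school and
four community group surveys of ~17 participants (236 respondents); 10
samples per pathway.  The generator does not simulate spatial structure,
seasonality, survey-type response biases, enumerator effects, or non-Poisson
plate overdispersion — so passing recovery tests demonstrates internal
consistency of the estimation chain under its own assumptions, not
robustness to field artifacts.

## Replicate-deployment reproducibility

`replicate_experiment` draws two fully independent deployments from one
five-pathway ground truth (a coastal urban scenario where raw produce
dominates: ~80% of adults exposed; drinking water near-universal contact at
low concentration; overdispersed drain/toilet contact; rare ocean contact;
concentration sigmas 0.8-1.0 log10) and compares adult profiles.  For desk
scale it uses 2 chains x 2,500 iterations and 1,000 MC iterations of a
500-person cohort — enough that MCMC and MC noise are negligible next to
data noise.  Characterized over seeds 1-8: the maximum between-deployment
difference in percent exposed ranged 2.4-8.3 points (drinking water, near
100% exposure, agrees almost exactly; mid-range pathways like drains are
noisiest), and the maximum dose difference ranged 0.47-1.68 log10,
exceeding 1 log10 in a quarter of seeds.  That dose bound is genuinely
stochastic at 10 samples/pathway with sigma ~1: the between-deployment
standard error of `mu` alone is ~0.45 log10, and the multi-contact dose is
additionally sensitive to the sigma estimate.  Agreement within ~10
percentage points and ~1 log10 should therefore be read as the protocol's
typical, not guaranteed, reproducibility at recommended sample sizes.

## Rendering and report

People Plots are generated directly as SVG (text-diffable): exactly 100
person icons, red count = percent exposed rounded half-up (a footnote marks
nonzero exposure under 0.5%), red shade linearly interpolated over a
configured log10-dose scale (default 0-10).  Pie charts and histograms use
matplotlib with a fixed `svg.hashsalt`; the underlying category fractions
and unit-width log10 bins are pure functions, tested independently of the
rendering.  Censored concentrations appear as distinct limit markers, never
as bars.  The Markdown report is a pure function of the analysis results
and a user-editable YAML recommendation library keyed by pathway; a
dominant pathway with no recommendation entry is an error, not a silent
omission.

## Determinism

Every stochastic component takes an explicit seed; child seeds derive from
the root via `SeedSequence` with CRC32-stable spawn keys (never Python's
salted `hash`), and all adaptation happens during burn-in, so a fixed-seed
pipeline run is byte-identical across processes and platforms.
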