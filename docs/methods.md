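# Methods

## The generative model and the four-way classification

Replicate read counts at an SNV-anchored site are treated as a proxy for
binding (or expression) intensity. Parental (F0) counts for each strain are
negative binomial, derived as a Poisson whose mean is Gamma-distributed with
shape `r` and scale `p/(1−p)`; the marginal mean is `r·p/(1−p)` and the
variance `mean·(1 + p/(1−p))`. F1 allele counts are beta-binomial given the
per-replicate total `n_j`, parameterized by the allelic mean
`m = α/(α+β)` and the concentration `c = α+β`; the totals `n_j` are treated
as ancillary (conditioned on, never modelled), since the allelic proportion —
not the total — carries the cis signal.

The four hypotheses differ only in equality constraints (see README table).
The cis constraint ties the F1 allelic mean to the F0 intensity odds: if each
F1 allele behaves like a half-dose of its parental strain, the expected
fraction of allele-A reads is `odds_A / (odds_A + odds_B)`. The conserved and
trans models pin `m = 1/2`; only the beta mean is constrained, the
concentration stays free in every model (biological replicate-to-replicate
variability of the allelic ratio is a nuisance parameter, not part of the
hypothesis).

Maximization exploits the structure: for fixed `r`, the NB likelihood in `p`
is maximized by moment matching (`p̂ = mean/(r + mean)`, closed form), so the
conserved/trans/cis–trans fits need only 1-D or 2-D numeric optimization of
the beta-binomial part (bounded search over `log c`, Nelder–Mead over
`(logit m, log c)` with a moment start and a small start grid). The cis model
couples the two data layers and is optimized jointly over
`(logit p_mu, logit p_nu, log c)` from two starts (the free-F0 solution and
an F1-implied split). Count-dependent gammaln terms are precomputed per site,
making each model evaluation O(1).

Model choice is by `BIC = k·ln N − 2·ln L̂` with `N` the number of replicate
observations (6+6+12 = 24 in the reference design); ties break toward fewer
parameters, then toward conserved. `ΔBIC` (runner-up minus winner) is
reported so downstream stages can apply confidence cuts (the inheritance
stage requires `ΔBIC > 1`).

**Operating characteristics and a known limitation.** With `N = 24` the BIC
penalty per parameter is `ln 24 ≈ 3.18`, so under a true conserved site each
one-extra-parameter competitor wins with probability
`P(χ²₁ > 3.18) ≈ 7.5%` (heavier in small samples); across the three
competitors ~15–20% of null sites receive a divergence call at the reference
design. This is a property of BIC at this replicate count, not of the
implementation: raising the penalty (e.g. tying `N` to read counts) trades
the null error for missed cis–trans calls and makes accuracy *fall* with
depth, because with site-level overdispersion `d` the information per
replicate saturates near depth `1/d` while such a penalty keeps growing. The
replicate-count convention is kept as the principled default; consumers who
need a stricter null should gate calls on `ΔBIC`. For the same saturation
reason, recovery is essentially flat across depths 50–1000 at dispersion 0.1
rather than rising toward 1.

## Preprocessing

* **Size factors** — median over sites of `count / geometric mean across
  libraries`, computed on sites positive in every library; estimated jointly
  over F0 libraries and F1 replicate totals (A+B), with each F1 factor
  applied to both alleles so allelic proportions are untouched. Exact
  invariance: scaling one library by `c` multiplies its factor *relative to
  any other library's* by `c` and changes normalized counts only by a global
  constant (each library's own reference shifts by `c^{1/L}`).
* **Filters** — keep sites with summed F0 depth ≥ 10 in at least one strain
  (a per-replicate variant is available) and ≥ 10 allele-resolved reads in
  ≥ 10 F1 replicates. Every filter logs input/output counts.
* **Thinning** — at most one SNV per 250 bp: sites are taken in order of
  decreasing total coverage (ties: smaller coordinate) and kept when no
  retained site is closer than the spacing; the result is pairwise separated,
  hence idempotent.
* **Histone marks** — SNV counts within the same peak are summed into one
  aggregate site (peak-midpoint coordinate, members recorded); an SNV under
  two overlapping peaks goes to the nearer midpoint.
* **Dispersion** — per-site method of moments pooled across strains,
  `d = (var − mean)/mean²`, a least-squares trend `d(m) = a₀ + a₁/m` fitted
  on sites with positive raw estimates, a floor of 1e-4, and `r = 1/d`. This
  replaces the local-regression fit of count-RNA-seq packages with a
  self-contained parametric trend; classification results may differ
  marginally from a local-regression fit.
* Normalized counts are real-valued; discrete likelihoods round to the
  nearest integer at the model boundary (the rounding is part of the
  contract and applied consistently).

## Inheritance of total occupancy

Parents are ordered by median replicate intensity (`pmax`/`pmin`; an exact
tie is excluded). The F1 per-replicate total (allele A + allele B, not
doubled) is compared against each parent with NB equality-constrained models
(`S_parent = S_offspring`, shared mean fitted on the pooled sample) versus
the free model, each by BIC. Both equalities winning means the offspring is
indistinguishable from both parents → excluded (`ambiguous`); one winning →
dominant toward that parent; neither → additive, and if the mean F1 total
then lies outside the parental range the site is over-/under-dominant. The
additive hypothesis is deliberately the *inequality* model (offspring differs
from both parents), not a strict midparent equality — a strict-midparent
variant is not fitted by default. A separation filter
(`|mean_A − mean_B| ≥ max(2·SD, 19)` normalized counts, SD = pooled
within-strain replicate SD) rejects sites where dominance could be an
artifact of parental similarity. Inheritance is assessed only at sites
classified cis or trans with `ΔBIC > 1`.

## Lineage-specific sites

A site is strain-specific when the allele-A proportion of replicate means
clears 0.95 (or falls below 0.05) in both generations. At such sites the F1
carries one bound allele, so a purely cis mechanism predicts F1 totals at
half the bound parent's level; the test fits NB models to the parent counts
and the *doubled* F1 totals (`2y`) with shared (cis, k=1) versus free
(cis–trans, k=2) means, BIC-selected. Doubling a count changes its variance
under a count model; the doubled form is kept deliberately as the method's
definition. The model menu at these sites contains only cis and cis–trans —
a trans-only outcome (strain-specific in F0, balanced in F1) is
unrepresentable by construction, since such sites fail the lineage cutoffs.
Compensatory vs diversifying status at both-allele-bound cis–trans sites
compares |log2 ratio| in F1 against F0 (replicate means, pseudocount 0.5);
apomorphic (gain) vs plesiomorphic (loss) polarization uses a boolean
outgroup presence flag under parsimony.

## Distance decay of cis coordination

Allelic proportions (mean over replicates of `A/(A+B)`, zero-total
replicates skipped) of partner sites are correlated (Spearman) with anchor
sites in mutually exclusive distance bins: 1 kb wide, starting 400 bp from
the anchor, both directions pooled by absolute distance, up to 400 kb; bins
with fewer than 20 pairs are reported missing. A growing-width binning
(widths 1, 2, 3, … kb) is available as an option. The null keeps anchors
fixed and redraws partner values from the genome-wide pool without
replacement, matched in pair count per bin (2.5/97.5 percentiles over
resamples form the envelope). The decay is summarized by OLS of ρ on
`ln(distance)` with a 90% CI on the slope, and the elbow of the fitted curve
is the grid point (1–50 kb, 200 points) of maximal perpendicular distance to
the chord joining the endpoints, after min-max normalizing both axes —
without normalization the answer would depend on units. For a log-linear
curve this elbow has a closed-form location (`d = span/ln(span ratio)`-ish,
≈ 12.6 kb on the 1–50 kb window) independent of slope and intercept; it
discriminates curved from straight fits (straight lines return none) rather
than re-estimating the decay scale. Profiles are computed per assay; a pooled
mode is a caller-side concatenation.

Contact enrichment counts, for each ordered class pair (A, B), interactions
whose first endpoint interval contains an A-class site and second a B-class
site (≥ 1 bp overlap); expected is `n · p_A · p_B` from marginal
endpoint-overlap rates, with an exact binomial test.

## Integration across layers

Sites are assigned to genes in a strand-aware, boundary-inclusive window
20 kb upstream / 10 kb downstream of the TSS (truncated at chromosome start,
logged). Per-class site counts are the predictors of one logistic regression
per response class (gene in class vs rest); `|Z| > 2` flags significance,
zero-variance predictors are reported non-estimable, and mean-centered odds
ratios (per predictor across the four fits) are display-only. The same
machinery relates histone marks (±2 kb windows) to site classes. Mark–gene
concordance (marks within 5 kb upstream of a TSS) and triple-assay class
sharing use one-sided exact binomial tests against products of marginal
frequencies; region enrichment (promoters/enhancers) uses the two-sided
exact binomial with `OR = (k/(n−k))/(p/(1−p))`. Mechanistic diversity per
gene is Shannon's `H' = −Σ aᵢ ln aᵢ` over the window's class proportions
(`0·ln 0 ≡ 0`, range `[0, ln 4]`), compared between expression classes by
two-sided Mann–Whitney U. Expression matching bins the log expression of the
more highly expressed parent into 20 equal-width bins and samples reference
genes per bin with replacement; targets in empty reference bins are dropped
and counted. The cis-extent summary is the Pearson correlation of log2 F0
strain ratios against log2 F1 allelic ratios (log scale chosen for symmetry;
Fisher-z 95% CI), and the effect-magnitude comparison reports the fraction
of random (site, gene) pairs where the site's |log2 allelic ratio| exceeds
the gene's (ties ½, seeded draws). Raw p-values are reported throughout; no
multiple-testing layer is applied where the underlying procedure defines
none.

## Synthetic data

The generator draws from exactly the hierarchy the classifier assumes: NB F0
counts (Gamma-Poisson), NB F1 totals at the midparent level by default
(configurable — planting the total at one parent encodes dominant
inheritance), beta-binomial F1 allele counts with the class-determined mean:
conserved/trans 0.5, cis at the F0-odds value, cis–trans at an independent
mean (default 0.65). Reference design: 6 F0 replicates per strain, 12 F1
replicates, depth 100, dispersion 0.1, strain odds 4:1 (hence a cis allelic
mean of 0.8), concentration 50 (allelic-ratio replicate SD ≈ 0.07, a
moderate, realistic overdispersion), library factors log-normal with CV 0.1.
The divergence direction is a fair coin per site — direction balance is what
the median-of-ratios normalization assumption requires, and is what real
inter-strain divergence looks like. F1 depth relative to F0 is a parameter
(`f1_depth_scale`, default 1) rather than a guess. One root seed feeds named
sub-streams (`sites`, `library`, `genome`, `landscape`, `lineage`), so any
stage can be regenerated independently and identical configs are
byte-identical on disk.

The coordination landscape plants a latent allelic shift per anchor
(normal, SD 0.2, clipped at ±0.4) that satellites inherit attenuated by
`exp(−d/scale)` plus independent noise (SD 0.05), with log-uniform distances
— under these defaults the rank correlation first halves between 1× and 3×
the decay scale. The genome context generates genes (TSS, strand, expression
classes and allele-level expression), promoter/enhancer intervals,
interaction endpoint pairs, and optionally plants class-matched extra sites
in TSS windows.

What the generator does *not* emulate: read-level artifacts (mapping bias,
GC content), linkage between neighboring sites outside the coordination
landscape, peak-calling uncertainty, and real genomic feature geometry.
Passing recovery tests therefore demonstrates correctness of the inference
under the model's own assumptions, not robustness to upstream biases — those
are declared out of scope at the counts-in interface.

## Problem sizes and numerics

Validation runs use 200 sites per class for classification recovery, 500
sites per planted mode for inheritance and lineage, 200 anchors × 10
satellites for the decay analysis, 100 resamples for null envelopes, and
2000-gene × several-hundred-replicate batches for regression calibration —
sizes at which Monte-Carlo error is a few percent and a full run takes about
a minute. Optimizer tolerances are 1e-8 (relative) with bounded parameter
transforms (logit/log, |logit| ≤ 13, log c ∈ [−3, 16]); likelihood-nesting
violations beyond 1e-6 would indicate non-convergence and are tested.
Degenerate sites (all-zero F0 or F1) are flagged `unclassified`, never
silently assigned.
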