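# Methods

## Scope and data model

The pipeline compares one protein inventory across two site arms, labelled
`A` and `B` throughout ("EPR"/"Guaymas" or any other field names are display
labels only). The atomic identification unit is the peptide-spectrum match
(PSM); protein abundance is its spectral count, i.e. the number of accepted
PSMs mapping to the protein in one site × replicate run. All tables are
UTF-8 tab-separated text with one header line; `#` lines carry the pipeline
version, seed and parameters so outputs are reproducible byte for byte.

Decoy status is an explicit boolean column rather than an accession prefix;
`apply_decoy_prefixes` folds the common `rev_`/`DECOY_` conventions onto the
flag at load time.

## PSM acceptance

Two gates precede counting:

- **Mass error** — records with |precursor error| strictly below 3.0 ppm
  are kept. The cut is applied to the absolute value because ppm error is
  signed in practice.
- **Decoy-estimated FDR** — for a candidate score threshold *t*,
  `FDR(t) = (#decoys ≥ t) / (#targets ≥ t)`, with no +1 correction and no
  q-value monotonization (the plain ratio matches the era of spectral
  counting this pipeline reproduces; a conservative +1 variant would be a
  one-line change). Every observed score is a candidate; among thresholds
  meeting the bound (default 1%) the one accepting the most targets wins,
  and acceptance ties resolve to the **largest** such threshold — the
  accepted target set is identical either way, but the reported threshold
  then carries the fewest decoys and the lowest achieved FDR. Ties at the
  threshold score are included before the bound is checked, so the result
  is order-independent. Thresholding is applied per (site, replicate) run
  by default (each LC-MS/MS run has its own score scale), with a
  whole-dataset option.

Peptide distinctness is plain string equality (no modification notation is
modelled). Unique-peptide counts are per (protein, site), pooled over the
site's replicates.

## Qualification and differential representation

Stages run in this fixed order; re-running the composite on its own
qualified subset is a no-op.

1. **Replicate presence** — a protein must have a nonzero count in every
   replicate. The default scope requires this at *both* sites, the
   strictest reading consistent with computing cross-site ratios for every
   qualified protein; `presence_scope: either` relaxes it to one site (zeros
   at the other site are then handled by the floor below).
2. **Unique peptides** — at least `min_unique = 3` distinct peptides at one
   site or the other.
3. **Outlier mask** — within each (protein, site) group, replicate counts
   farther than `k = 2` *population* standard deviations from the group
   mean are masked. Statistics are computed once over all group values
   (single pass, hence idempotent). **Note:** for a group of *n* values the
   largest attainable population z-score is √(n−1), which is √3 ≈ 1.73 for
   quadruplicates — so at the default k = 2 and 4 replicates the rule can
   never fire. It is retained because it is the stated contract, it becomes
   active for more replicates or smaller k (the tests exercise both), and
   its vacuity at n = 4 is worth knowing: single-replicate spikes survive
   into the means at the default design.
4. **Total-count normalization** — the non-reference arm (default: B) is
   rescaled by `factor = total(reference) / total(other)` over unmasked
   counts, equalizing the arms' totals. Because the factor multiplies every
   value of one arm, per-protein log2 ratios are invariant to any uniform
   rescaling of either arm's raw counts (verified to 1e-9).
5. **Zero floor** — exact zeros among the *normalized* values become 0.2
   (the stage order follows the procedure's definition; the floor's only
   role is to keep ratios finite, and qualified proteins under the default
   both-sites presence scope never need it).
6. **log2 ratio** — `log2(mean_A / mean_B)` of unmasked, floored replicate
   values. Means rather than sums are used so a masked replicate does not
   deflate one arm. The ratio is antisymmetric under swapping the arms.

Accounting is exact: identified = qualified + Σ exclusions, with one reason
per excluded protein (`missing_replicate` is assigned first, then
`too_few_unique_peptides`).

**Housekeeping check.** Constitutive proteins (e.g. RNA-polymerase
subunits, dnaK) should sit near log2 ratio 0 after normalization. The check
reports each qualified housekeeping protein's ratio, their mean and sample
SD, and passes when |mean| ≤ 0.5 and SD ≤ 1.0. The tolerances are
deliberately loose — with quadruplicate counts near 50 and overdispersed
counting noise, a single protein's ratio has an SD of roughly 0.5 even
under a true null — and the verdict is advisory: it never fails the
pipeline.

## Summaries

- **Proteome fractions** — percent of a scope's total abundance per
  protein and site, where abundance is the sum of normalized, floored,
  unmasked replicate values. Symbiont percentages are always computed
  against the symbiont-scope total so that a host-protein-rich sample
  cannot distort symbiont comparisons; host hemoglobin is evaluated against
  host proteins and total host against the combined proteome.
- **Pathway abundances** — member abundances summed per site, percent of
  the symbiont scope, and the A/B fold ratio. Pathway membership ships as
  an editable TSV (`pathway_map.tsv`) mapping display pathways to catalog
  tags; curation is user data, not code. Empty pathways are reported absent
  rather than zero-divided, and fold ratios resting on an arm where every
  member was absent pre-floor are flagged `floor_limited`.
- **COG composition** — qualified proteins split by the sign of their log2
  ratio (any magnitude strictly above the configurable threshold, default
  0: a binary split); within each direction, percent composition per COG
  letter counts each protein once regardless of its peptide count.
- **Top-N ranking** — per site by absolute abundance, ties broken by
  accession so rankings are rerun-identical; proteins in both lists are
  flagged shared, catalog host proteins flagged host.

All percent families sum to 100 within 1e-9 whenever non-empty.

## Respirometry

For a flow-through vessel, instantaneous removal is
`flow · (c_in − c_out)` (µmol h⁻¹); the uptake rate is its time average
over the steady-state window divided by pooled wet weight. Rates are
per-vessel (animals in one vessel are pooled on combined wet weight) and
signed: negative means net release. Defaults and rationale:

- `steady_fraction = 0.5` — animals acclimate before dosing, so only the
  final half of the trace is averaged; configurable.
- Control correction subtracts the empty vessel's time-averaged removal
  (unnormalized, in µmol h⁻¹) before weight normalization, removing
  wall/tube effects; the standard error propagates animal and control
  removal variances in quadrature.
- `mean_ambient` is the mean effluent concentration over the window — in a
  well-mixed perfused chamber the effluent tracks the concentration the
  animal experiences.

The concentration–response slope is ordinary least squares of rate on mean
ambient (statsmodels OLS). The linearity diagnostic is the fractional
reduction in residual sum of squares when a quadratic term is added; the
saturation flag additionally requires concave-down curvature supported by
an F-test (p < 0.05), because on short series a quadratic soaks up residual
variance by chance. The slope estimator is equivariant: scaling all
concentrations by c scales the slope by 1/c.

## Synthetic data: what it emulates, what it does not

Latent counts are negative binomial (`var = m + φ m²`, default φ = 0.2, the
field-typical overdispersion for spectral counts), 4+4 replicates, base
means log-uniform on [30, 300]. Planted log2 fold changes (≈40% of
proteins, N(0, 1)) are split **symmetrically** — half the effect up at A,
half down at B — so total-count normalization stays well-posed; a
`site_depth` option plants a global depth shift instead, to probe the
normalization itself. Ten housekeeping proteins are pinned at fold change 0
and base mean 50. Dropout zeroes a replicate with probability
`0.1 · exp(−mean/30)` (rare above mean 100); with probability 0.02 per
(protein, site) one replicate is spiked 5×. Target scores are N(8, 1),
decoys N(4, 1) at 10% of the target PSM volume; mass errors are N(0, 1.2)
ppm so a small tail exercises the 3-ppm gate. At dispersion 0 the generator
degenerates to deterministic rounded means (the noise-free limit used for
machine-precision recovery checks). Everything is driven by one
`numpy.random.default_rng(seed)`: identical seeds give byte-identical
output files.

Under these defaults the pooled median |log2 ratio − truth| over ten seeds
is ≈ 0.34 — almost entirely irreducible counting noise: at dispersion 0.2
the per-protein ratio SD is ≈ 0.47, predicting a median around 0.32, with
the unmaskable outlier spikes (see above) contributing the remainder. The
housekeeping pooled mean sits within 0.05 of zero, i.e. the normalization
is unbiased even though individual ratios scatter.

What the generator does **not** emulate: shared/degenerate peptides across
proteins (each protein has its own peptide pool, so protein inference is
trivial), score–mass-error correlation, chromatographic or batch structure,
replicate-level depth drift, and compositional coupling between proteins
beyond the shared normalization total. Passing recovery tests therefore
demonstrates correctness of the procedure under its own stated model, not
robustness to those real-data effects.

Respirometry traces obey `c_out = c_in − rate·weight/flow` with
multiplicative Gaussian noise on the outflow (default 5%), controls at rate
0 with optional linear drift. Recovery statements ("within 5% at 5% noise
over 20 seeds") refer to the mean estimate across seeds: a single 50-point
trace at 5% noise carries ≈ 4% sampling error by construction, so per-seed
agreement at 5% would be a coin flip for any estimator.

## Numerical and design choices

- Population SD (ddof 0) for the outlier rule; sample SD (ddof 1) for the
  housekeeping spread and rate standard errors.
- Normalization reference arm defaults to A and the factor multiplies B;
  both are configurable, and ratios are reference-invariant by the scale
  invariance above.
- `qualify` on an empty or fully-excluded matrix returns an empty/excluded
  table (0/0) rather than erroring; zero site totals at the normalization
  stage are an error, since the factor is undefined.
- Degenerate steady-state windows (fewer than 2 samples) fall back to the
  whole trace.
- Problem sizes in the test and acceptance runs (500-protein × 10-seed
  recovery, 50-instance oracle sweeps, 150–300-protein end-to-end runs,
  20-seed respirometry panels) were chosen to make the measured quantities
  statistically stable at desk scale.

## Known limitations

- The 2-SD outlier rule is inert at the default quadruplicate design (see
  above); spike contamination shows up in the ratio error instead.
- Total-count normalization assumes globally balanced differential
  expression; a strongly asymmetric fold-change distribution biases every
  ratio by the log2 of the residual total imbalance (the housekeeping check
  is the guard rail).
- No significance testing of differential abundance is performed — the
  log2 ratio is descriptive, as in the procedure this pipeline codifies —
  and no NSAF/emPAI-style length or saturation corrections are applied.
- Protein-level FDR, posterior error probabilities and rescoring are out of
  scope; the decoy ratio is a PSM-level estimate.
- Respirometry rates are per-vessel on pooled wet weight; per-animal rates
  are not identifiable from pooled traces.
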