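# Methods

## The analysis model

A case-control serology study measures, for each serum sample, the
AlphaLISA signal against each GST-fusion antigen and against the GST
control. All statistics operate on the **net count**
`x = fusion − gst`, which may be negative and is never clipped.

**Seropositivity cutoff.** For each marker the healthy-donor (HD)
reference gives `cutoff = mean_HD + 2·sd_HD`, with the sample SD (n−1
denominator, the standard choice for reference-interval estimation).
A sample is positive iff its net count *strictly* exceeds the cutoff;
the boundary value is negative. The strict inequality is a
deliberate, documented convention (the complement is a one-line
change); for continuous data the two conventions almost surely agree.
Cutoffs are fitted once on the HD samples of the analyzed dataset and
reused unchanged in every stratified analysis, so positivity calls
never change across strata.

**Z scores and composites.** Each marker is standardized against the
same HD reference: `z = (x − mean_HD)/sd_HD`, so the positivity cutoff
sits exactly at `z = 2`. The orientation (disease raises the score) is
chosen so that informative markers give AUC > 0.5; a per-marker
`flip` flag covers analytes where disease lowers the value. Clinical
analytes join composites the same way: CEA and CA19-9 as continuous
values standardized on HD mean/SD, anti-p53 status as a 0/1 indicator
standardized likewise. A panel's composite score is the unweighted sum
of its members' Z scores; samples missing any member are excluded
pairwise with a logged count.

**ROC and AUC.** Empirical ROC over unique score thresholds with
trapezoidal AUC; ties produce diagonal segments (midrank convention),
which makes the trapezoidal AUC identical to the Mann–Whitney win
probability `U/(n₁n₂)` — the suite asserts the identity to 1e-12 on
heavily tied fixtures, computing the two sides by independent routes
(scikit-learn threshold sweep vs an own midrank U).

**Paired AUC comparison.** The DeLong estimator from placement values:
the placement of a case is the fraction of controls scoring below it
(ties half), symmetrically for controls; the variance of
`auc_a − auc_b` combines the empirical covariance matrices of the two
placement vectors over cases and over controls. Identical score
vectors give p = 1 by convention; a zero variance estimate with
unequal AUCs is an error rather than a silent p. The stratified
paired bootstrap resamples cases and controls separately (no resample
is ever degenerate) with the same indices applied to both score
vectors; the default p-value converts the observed difference to a z
statistic with the bootstrap SE (`method="signflip"` gives the
tail-proportion variant). Defaults: 2000 replicates, explicit seed
required.

**Interval estimators.**

* Proportions (Sn, Sp, PPV, NPV): Wilson score interval. At
  `k = 0` / `k = n` the affected bound is exactly 0 / 1. A
  Brown-style boundary modification (Poisson chi-square bounds for 1–2
  successes or failures) is exposed as `brown=True` for comparison
  with commercial "Wilson-Brown" hybrids but is off by default and not
  a validated surface; published boundary cells (e.g. a specificity
  upper bound printed as 100) are reproducible only under such
  tool-specific hybrids.
* Diagnostic odds ratio: point estimate `(tp·tn)/(fp·fn)` (flagged
  infinite when `fp·fn = 0`); interval by the **Baptista–Pike mid-p
  exact conditional** construction — inversion of the
  probability-ordering (Sterne-type) test under Fisher's noncentral
  hypergeometric distribution, outcomes no more probable than the
  observed cell summed, equally probable outcomes weighted one half.
  Endpoints are found by bisection on the log-odds scale to 1e-8,
  bracketed at the conditional MLE. This construction was selected
  because it reproduces published reference intervals of this battery
  exactly at one decimal ((2.2, 141.1) and (2.1, 38.2)), where a
  central two-tailed mid-p interval does not (it gives (2.1, 284) for
  the first table). Probability-ordering confidence sets can in
  principle be disconnected; the implementation reports the component
  containing the conditional MLE. Mid-p intervals target, rather than
  guarantee, nominal coverage; the suite checks coverage ≥ 93% at
  nominal 95% on simulated 50/50 tables.

**Group-level tests.** Mann–Whitney U with midranks, normal
approximation with tie and continuity correction, switching to exact
enumeration when both groups have ≤ 8 observations without cross-group
ties. Pearson chi-square without continuity correction for positivity
vs clinical strata; a zero marginal is an error, not a silent zero.

## The synthetic cohort generator

The generator emulates what the analysis assumes about real sera, so
every pipeline stage is testable without patient data:

* **HD background**: log-normal net counts (right-skewed, as
  autoantibody titers are), scale ~300 Alpha counts, per-marker log-SD
  0.9–1.1 (a ~50-fold central 95% range, typical of bead-based
  immunoassay backgrounds). The HD tail above the mean + 2 SD cutoff
  is then 3–4%.
* **Cancer responder mixture**: with probability `responder_fraction`
  a patient's log-mean shifts up by `responder_shift`; otherwise the
  marker behaves as in HDs.
* **Dependence**: a Gaussian copula on the log scale. The bundled
  config correlates a four-marker block (CFAP70/KARS/SNX15/SOHLH1,
  ρ = 0.5) and leaves the lead candidate independent, mirroring the
  qualitative correlation structure reported for such panels.
* **Clinical analytes**: CEA and CA19-9 as log-normal responder
  mixtures with the conventional thresholds (5 ng/mL, 37 U/mL) —
  CEA calibrated to ~37% positivity and AUC ~0.69 in cancer — and
  anti-p53 status as Bernoulli (2% HD, 17% cancer). A binary anti-p53
  caps its achievable AUC near 0.58, below the ~0.70 a continuous
  titer would give; this is a known simplification.
* **Stage labels**: Dukes A/B/C/D/ND at 20/34/25/20/1%, giving the
  ~54% early / ~45% advanced / 1 ND split of the motivating study.
* **Plumbing**: GST backgrounds are drawn separately and fusion set to
  net + background, so the pipeline's subtraction step reconstructs
  the simulated net values bit-exactly. Generation is a pure function
  of the config (seed included).

**Calibration.** Because the mixture keeps the HD log-SD, both targets
have closed forms on the log scale:
`AUC = ½ + f·(Φ(δ/(σ√2)) − ½)` and
`P(positive) = (1−f)·Φ̄(z₀) + f·Φ̄(z₀ − δ/σ)`, with `z₀` the
standardized log-position of the population mean + 2 SD cutoff
(a function of σ only). `calibrate_marker` inverts a (rate, AUC) pair
deterministically: the AUC identity pins `f` as a function of `δ`,
leaving a bracketed 1-D root problem; infeasible pairs raise with the
attainable frontier. The closed forms are themselves verified in the
suite against numerical quadrature and Monte Carlo.

The bundled `crc_like` config calibrates five markers to the
positivity/AUC profile of the motivating five-antibody panel (lead
marker 11/90 ≈ 12.2% positive at AUC 0.664; the others 9–18% at AUC
0.55–0.58). Two constraints shaped the log-SD defaults: below
σ ≈ 0.95 the (12.2%, 0.664) pair is infeasible for the mixture, while
large σ makes the sample mean + 2 SD cutoff unstable at n = 94 (the
lognormal sample SD is heavy-tailed). σ = 1 balances both; the
residual consequence is that the simulated positivity *count* at study
size is overdispersed relative to binomial (SD ≈ 5 vs 3.1 at n = 90)
because the fitted cutoff varies between replicates.

**What passing tests do and do not show.** The generator reproduces
right-skew, responder structure, cross-marker correlation, stage
labels, and calibrated rates/AUCs. It does not model plate effects,
inter-assay drift, age/sex confounding, or the 1% HD positivity of the
most specific published marker (unreachable at a stable σ, see above);
conclusions about real sera beyond these structural properties are out
of reach of the suite.

## Numerical and design choices

* File I/O parses floats with Python's exact `float()` (pandas'
  `to_numeric` does not round-trip shortest-repr float64), so
  `read(write(c))` is field-identical and a fixed point in bytes.
* Unparseable optional metadata becomes missing, never zero; "N.D."
  stage strings map to the ND category and such samples stay in
  whole-cohort analyses but leave stage-stratified ones (logged).
* Clinical positivity may be supplied as calls or derived from values
  with configurable thresholds (CEA > 5 ng/mL, CA19-9 > 37 U/mL).
* The panel sweep evaluates the candidate alone, each clinical partner
  alone, and the candidate with every subset of partners, sorted by
  descending AUC with a lexicographic tie-break for determinism.
* All pipeline randomness flows from one root seed; report bundles are
  byte-identical across reruns of the same configuration, verified by
  SHA-256 digests in the manifest.
* Problem sizes in the test suite (10 000 null simulations at 90/94
  for DeLong calibration, 1000 replicates for the composite-gain
  property, 2000/2000 for generator recovery) were chosen as the
  smallest sizes at which the Monte Carlo error is well inside the
  asserted bands.

## Known limitations

* The DOR point estimate is the unconditional cross-product ratio;
  the conditional MLE consistent with the Baptista–Pike interval is
  computed internally but not reported (they differ by ~1% at the
  reference table).
* `panel_sweep` enumerates subsets of the clinical partners only; it
  is not a general best-subset search over all markers.
* No plate-layout parsing, vendor formats, survival analysis, or
  parametric (binormal) ROC smoothing.
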