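# Methods

## Model and assumptions

All material is homozygous: a recipient control (HJX74), single-segment
substitution lines (SSSLs) each carrying one donor QTL segment, and
pyramiding lines stacking 2–6 segments in the same background. With no
segregation and no heterozygotes, only additive and additive×additive
terms are identifiable, and every estimator is a linear contrast of line
means:

- single-QTL additive effect `a_i = mean(SSSL_i) − mean(P0)`;
- combination effect of an n-QTL pyramid: `Pn − P0`;
- epistasis `i = (Pn − P0) − Σ a_i = Pn + (k−1)·P0 − Σ SSSL_j`, where `k`
  is the number of contributing single-segment terms.

The second form matters for inference: the contrast is computed within
each cropping season (`i_s = Pn,s + (k−1)·P0,s − Σ SSSL_j,s`) and the
point estimate, SE, and one-sample t (df = seasons − 1) are taken across
seasons. Blocking on season absorbs season main effects and the covariance
introduced by the shared control term, and needs only season-level means —
plant-level replicates are averaged into their season first, since the
season is the replication unit of all reported SEs. An alternative
variance-propagation SE (line means treated as independent,
Welch–Satterthwaite df) is available via `method="propagation"`.

Assumptions: season values are approximately normal with common
line-to-line error; lines share all seasons; the background is uniform so
line differences are attributable to the substitution segments.

## Scales

SER is a percentage. Group comparisons (Student's t between groups,
Dunnett, Duncan letters) default to the arcsine square-root transform
`asin(sqrt(p/100))` (radians), the classical variance-stabiliser for
percentage traits. The epistasis t-test, however, defaults to the **raw**
scale: H0 `i = 0` is defined in percentage points, and under a raw-scale
additive null the transformed contrast has a deterministic nonzero offset
(the transform is concave), which would inflate the test's size. The
transformed variant remains available (`test_scale="arcsine_sqrt"`), and
all reported effects are in raw percentage points regardless of test
scale. Presentation rounding is one decimal, half away from zero, applied
only at output.

## Linked segments

Two loci can co-reside on one substitution segment (annotated
`linked_group`, e.g. the A35 and A88 segments in the packaged panel). Such
lines are ordinary 2-QTL lines. When a locus has no SSSL of its own but a
2-QTL line covers exactly its linked pair, that line contributes one
*joint* additive term while still counting two QTLs toward n; the joint
segment's internal interaction is then folded into its additive term, so
the pyramid's estimated epistasis is relative to the joint segment rather
than to the two loci separately.

## Effect-level classification

The per-locus effects are partitioned into k = 3 ordered levels
(low/moderate/high) by exact dynamic-programming 1-D least squares over
contiguous partitions of the sorted effects — deterministic, and verified
in tests against exhaustive enumeration. Ties prefer the smaller top
level; a partition whose level means are not strictly increasing (e.g.
all-equal effects) is rejected with a pointer to a smaller k.

## Group statistics

- **Dunnett's many-to-one test** uses the multivariate-t distribution of
  the maximum comparison statistic (scipy's numerical integration), the
  exact equicorrelated form for balanced designs. With one group it
  reduces to the pooled two-sample t.
- **Duncan's multiple range test**: ranked group means are compared
  stepwise against least significant ranges
  `LSR_p = q(1 − α_p, p, df) · sqrt(MSE/n_h)` with the protection level
  `α_p = 1 − (1−α)^(p−1)` applied to studentized-range quantiles (no
  hard-coded tables; quantiles are cached because each evaluation is
  expensive). Unbalanced group sizes enter through the harmonic mean
  `n_h`. A stretch of means whose range fails its LSR is declared
  homogeneous and nothing inside it is tested; maximal homogeneous
  stretches become the significance letters (shared letter = not
  significantly different; letter blocks are contiguous in rank order).
  With two groups the decision coincides with the LSD t-test.

## Focal-QTL attribution

Within an n-QTL group split into carriers and non-carriers of a focal
locus, the focal locus is credited with
`i_focal = mean_i(with) − (n−1) · mean_i(without)/n`: the non-carrier
subgroup's per-QTL epistasis stands in for the focal line's n−1 other
loci. This is an approximation — it assumes the non-focal loci interact in
carriers as they do in non-carriers — but it is the only decomposition
expressible from subgroup means alone. Subgroup differences are tested
with Welch's t on line-level i values; count-weighted subgroup means
reconstruct the group mean exactly (an identity used as a cross-check).

## Synthetic-data generator

`synthetic_data` emulates the study design: control at P0 = 29.2% SER,
per-locus additive effects defaulting to an 11-locus set in 13.3–27.3%
(mean 18.9%) consistent with the packaged summaries (the per-locus values
themselves are a reconstruction, labelled synthetic — only their
aggregates are constrained by data), 3 cropping seasons, and Gaussian
season noise of SD 3% on the raw scale. Epistasis models: `none`,
`pairwise` (programmed per-pair deviations), and `diminishing` with
`E = −c·n(n−1)/2`; the default c = 3.5%/pair is the least-squares match to
the observed group epistasis (−7.8/−14.6/−25.2/−40.4/−47.7% at n = 2–6).
Values are clipped to [0, 100] and clipping is logged: with the default
architecture the most heavily loaded 5-QTL genotype sits at an expected
99.5%, so noisy draws occasionally saturate — a real feature of percentage
traits near their ceiling, but one that breaks exact-recovery arithmetic,
which is why exactness tests use architectures that stay strictly in
range. Optional additive season offsets exercise the season-blocked test.

What passing synthetic tests shows: the estimators invert the generative
model exactly without noise, are unbiased at study-like noise, and the
t-test holds its size. What they cannot show: robustness to features the
generator omits — spatial field heterogeneity, genotype×season interaction
beyond additive offsets, non-Gaussian errors, residual background
segregation.

A note on monotonicity: with a single quadratic deficit c matched to the
observed group epistasis, the expected 5QL→6QL step of the group mean is
small (≈ 20.5 − 5c percentage points for random effect draws) and can be
negative for particular genotype compositions, so "SER rises with QTL
count" is tested as a positive rank correlation across many simulated
panels rather than strict monotonicity of a single realisation.

## Validation studies and problem sizes

`validation` (used by tests and `scripts/acceptance.py`):

- type-I error of the epistasis t-test: 2,000 simulated additive 2-QTL
  nulls (3 seasons, 3% noise), rejection rate at α = 0.05 expected in
  [0.03, 0.07];
- Dunnett family-wise error: 1,000 global-null simulations, 3 groups of 5;
- additive-effect recovery: 200 simulated full panels, mean signed bias
  expected below 0.5 percentage points (theoretical SE of one effect at
  these settings is 3·sqrt(2/3) ≈ 2.45, so the mean over 2,200 estimates
  is tightly determined).

These sizes keep the whole suite in well under a minute of simulation time
while leaving Monte-Carlo error far smaller than the acceptance bands.

## Fixtures and their provenance

The packaged genotype matrix, group SER summaries, group epistasis
summaries, and focal-subgroup summaries are transcriptions of published
group-level results; per-line raw phenotypes were never deposited, so
per-line quantities are validated synthetically instead. The 1QL group is
represented by 11 reconstructed single-QTL entries (one per locus). The
epistasis-fraction step of the reproduction report divides the
presentation-rounded per-QTL epistasis by the mean single effect, because
the published percentages are only consistent with that two-stage rounding
(from unrounded inputs two of five differ by up to 0.35).

## Known limitations

- Focal attribution inherits the non-carrier stand-in assumption above.
- The diminishing model is an aggregate caricature: observed per-QTL
  epistasis saturates near 5–6 QTLs rather than growing linearly.
- Duncan letters are computed from a pooled MSE; heteroscedastic groups
  are not specially handled.
- Group-summary mode can only reproduce aggregates computable from
  published means and counts; per-line significance is out of reach
  without the raw data.
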