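# Methods

## The partitioning model

During grain filling, wheat kernels receive assimilates from two
isotopically distinct source pools: the ear's own atmospheric CO2 fixation
(dominated by the awns) and the shoot's pooled contribution, which the
water-soluble fraction (WSF) of the peduncle integrates — current
photosynthesis of the blades, sheaths and peduncle plus remobilized
pre-anthesis stem reserves.  Because the ear's low gas permeability keeps
its intercellular CO2 low, awn assimilates are constitutively 13C-enriched
(less negative δ13C) relative to leaf assimilates.  If translocation to the
grain does not fractionate, the mature-grain δ13C is a conservative mixture
of the source signatures:

    δ13C_grain = w · δ13C_awns + (1 − w) · δ13C_B + ε ,

with B the peduncle (primary model) or the flag-leaf blade (bounding
model), and w the ear's share of grain carbon.

The mixing weight is not constant: water stress closes stomata, raises all
organ δ13C, and shifts grain filling toward the ear.  Plot water status is
proxied by the grain δ13C itself through three bins (per mil vs VPDB):

| bin | grain δ13C interval | meaning |
|---|---|---|
| most favourable  | [−27.0, −26.4] | best watered, most negative grain δ13C |
| intermediate     | (−26.4, −25.8) | gap between the two stated intervals |
| least favourable | [−25.8, −25.2] | mildest water status, least negative |

The two extreme intervals are the stated stratification; the intermediate
bin fills the gap so the assignment is total.  Values on a shared closed
endpoint belong to the extreme bin; values outside the overall support snap
to the nearest extreme bin and are flagged.

### Estimation

Within each occupied bin, w minimises the squared mixture residuals over
the bin's plots.  Writing x_i = δA_i − δB_i and y_i = δG_i − δB_i (minus
any declared translocation offset), the separable least-squares solution is

    ŵ = Σ x_i y_i / Σ x_i² ,

clipped to [0, 1] with a flag.  With a single plot this reduces to the
closed-form two-pool mass balance f = (δG − δB)/(δA − δB).  The slope-1 /
intercept-0 relation between observed and mixture-predicted grain δ13C is
then *verified*, not imposed: a through-origin regression of observed on
predicted values reports β = Σxy/Σx² and the uncentred coefficient of
determination R² = 1 − SS_res/Σy².  The uncentred convention is the proper
one for a regression through the origin (the centred convention can be
negative there); published through-origin R² values computed under other
conventions are not directly comparable.

Uncertainty on ŵ comes from a percentile bootstrap that resamples plots
with replacement within their bin (the stratification is part of the
design, so it is held fixed).  Bins with fewer than two plots report a
missing interval.  All resampling is driven by an explicit seed.

### Organ shares and the flag-leaf bound

Per bin, the ear share of grain carbon is 100·ŵ from the awns+peduncle
model and the shoot share its complement.  The awns+flag model cannot be
read the same way (the flag leaf is one shoot organ among several); instead
its flag:awn weight ratio bounds the flag leaf's own share by scaling the
ear share:

    flag share = ear share × (w_flag / w_awns) .

Shares are kept at one decimal internally and rounded half-up to integer
percent in reports.  Averages over occupied bins are reported under two
conventions — simple bin mean and plot-count-weighted mean — because the
appropriate convention depends on whether bins or plots are the unit of
inference; the package takes no position and prints both.

### Assumptions

- The WSF represents recently produced assimilates.
- Glumes are excluded as an end member: they mainly refix grain-respired
  CO2, so their signature tracks the grain rather than an independent
  source (their δ13C is carried in the profiles for sensitivity use).
- No translocation fractionation (offset 0 ‰ by default; the
  `translocation_offset` parameter makes the assumption explicit and
  testable).
- Two sources only; pre-anthesis reserves are deliberately pooled into the
  peduncle signal, not separated.

## Supporting computations

**Organ carbon budget.**  Gross photosynthesis = net CO2 uptake + dark
respiration (whole-organ µmol s⁻¹).  Accumulated carbohydrate mass
= gross × 1e−6 × daylight_hours × 3600 × active_days × 30.026 g mol⁻¹,
assuming each fixed CO2 becomes one CH2O unit; the expression is exactly
multilinear in its factors.  The flag leaf's active duration ends at the
first SPAD crossing below 20, located by linear interpolation between
weekly readings (an exact-threshold reading is the crossing; a series that
never crosses is censored at its last day and flagged).  Ear senescence is
an observed date.  The saturating-PPFD daylight duration is a sensitivity
parameter (default 10 h day⁻¹), not a measured constant.

**Light interception.**  Per-stratum interception is the exact difference
of measured PAR above and below each stratum relative to incident, top of
canopy downward, with the residual transmitted fraction below the lowest
stratum reported so the rows sum to 100%.  No extinction model is fitted
and no reflected-PAR correction is applied.

**Trial statistics.**  One-way ANOVA uses the classical sum-of-squares
decomposition with significance stars at 0.05/0.01/0.001.  Tukey HSD
pairwise tests use the studentized-range distribution with the
Tukey–Kramer standard error under unequal n; compact letters come from the
insert-and-absorb algorithm and are invariant to group relabelling.  The
grain-yield vs grain-δ13C relationship (Pearson r plus a quadratic fit) is
a water-status diagnostic only.

## The synthetic trial generator

`earshare.simulate` emulates a 6-genotype × 3-replicate (18-plot) trial:

- **Organ anchors** (WSF, ‰): flag −29.7/−30.1, peduncle −26.9/−28.2,
  awns −25.4/−26.1 for the before/after-irrigation samplings; glumes −26.5
  (before only).  Dry-matter offsets per organ are added to the
  before-irrigation anchor.  Per-plot organ SD defaults to 0.17 ‰
  (back-computed from a replicate SE of 0.1 at n = 3).
- **Water status**: a latent u ~ Uniform(0, 1) per plot shifts every organ
  by γ_organ·(u − ½), with γ of 1.2/1.8/1.5/1.4 ‰ for
  flag/peduncle/glumes/awns.  The peduncle is most responsive, mirroring
  its largest irrigation shift, and the resulting grain δ13C spans roughly
  2 ‰ across plots.
- **Weights**: the awns weight rises with stress, linearly from 0.58 to
  0.90 against the peduncle (0.82 → 0.97 against the flag leaf) by
  default.  A "binned" schedule instead assigns each plot the constant
  weight of its water-status bin; the plot's bin is chosen
  self-consistently, as the bin whose scheduled weight predicts a
  noise-free grain value lying (deepest) inside that bin's own interval — a
  monotone schedule always admits such a bin.
- **Grain**: δ13C_grain = w·δA + (1−w)·δB + offset + N(0, 0.15 ‰),
  computed from the plot's *recorded* occasion-averaged organ values, so
  the generative model matches the estimator's error structure exactly.
- Gas exchange (whole-organ rates with the flag leaf's per-area superiority
  but comparable organ totals), weekly SPAD decay crossing 20 near day 37,
  ceptometer PAR profiles (≈30/30/15/10% interception), and agronomy
  (grain yield negatively coupled to grain δ13C) are generated per plot.
- A truth sidecar records u, both true weights, the true bin and the grain
  noise per plot; together with the config it reproduces every observable,
  and equal configs yield byte-identical files.

A noise-free worked example (`generate_worked_example`) places three plots
in each extreme bin at the anchor geometry with exact scheduled weights
0.90/0.58 (awns+peduncle) and 0.97/0.82 (awns+flag); each plot's flag-leaf
value is solved from the grain mixture so both models are exact
simultaneously (the solved values fall at −29.3 … −30.5 ‰, inside the
flag-leaf range).  The plots carry a small ±0.1 ‰ spread around the
anchors so the regression and the grid-search oracle are exercised on
non-degenerate data.

### What passing tests do and do not show

The generator draws independent Gaussian organ noise around linear
water-status shifts.  Real trials add spatial field structure, genotype ×
environment interaction in the weights, occasion-correlated sampling
effects and post-photosynthetic fractionation the model assumes away.
Recovery results on synthetic data therefore validate the estimator under
the model's own assumptions, not the assumptions themselves.

Two quantitative limits worth knowing:

- **Bin occupancy at n = 18.**  Under the three-bin default, extreme bins
  sometimes hold only 2–3 plots; the per-bin weight SE then approaches
  0.06 and recovery of the scheduled extreme weights within ±0.08 was
  measured at ~94% of seeds (least favourable bin), with negligible
  estimator bias.  A two-condition design on the two stated extreme
  intervals (≈9 plots per bin) recovers both weights within ±0.08 in
  ≥97% of seeds; the acceptance suite uses that design.
- **Headline averages.**  The simple bin mean of the extreme ear shares is
  74%, the plot-weighted mean depends on occupancy; neither is the same
  computation as a published "average ear share" without the per-plot
  data, which is why both conventions are always printed.

## Problem sizes

Default test and acceptance runs use 18-plot trials; Monte-Carlo
properties use 30–200 seeds; the grid-search oracle uses a 10⁻⁴ step
(10 001 candidate weights); bootstraps use 100–1000 resamples.  The whole
suite runs in well under a minute on one core.
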