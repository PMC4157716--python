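# earshare

Non-intrusive partitioning of wheat grain carbon between **ear** and
**shoot** photosynthesis from natural-abundance carbon isotope
composition (δ¹³C) of organ assimilates.

Ear photosynthesis is a candidate trait for raising cereal yield
potential, but classical estimates of its contribution to grain filling
rely on intrusive manipulations (shading, defoliation, herbicides) that
trigger compensation in the untouched organs.  This package implements the
alternative: because the ear's low gas permeability keeps awn assimilates
constitutively ¹³C-enriched relative to leaf assimilates, the δ¹³C of
mature kernels records which source filled them.  It is written for crop
physiologists and phenotyping groups who have plot-level organ δ¹³C
(water-soluble fraction and grain dry matter) from a replicated field
trial, and want the ear/shoot/flag-leaf shares of grain carbon plus the
supporting organ carbon budgets, canopy light interception and trial
tables.

## The model

Mature-grain δ¹³C is treated as a two-end-member mixture,

δ¹³C_grain = w·δ¹³C_awns + (1 − w)·δ¹³C_B + ε,

where B is either the peduncle (whose water-soluble fraction integrates
the whole shoot's current assimilates plus pre-anthesis reserves) or the
flag-leaf blade (a bounding model).  The ear weight *w* depends on plot
water status, proxied by grain δ¹³C through three bins (more negative ⇒
better watered).  Within each bin, *w* is estimated by separable least
squares, ŵ = Σ(δG−δB)(δA−δB) / Σ(δA−δB)², clipped to [0, 1]; the slope-1,
intercept-0 relation between observed and mixture-predicted grain δ¹³C is
then verified with a through-origin regression (uncentred R²), and
uncertainty comes from a within-bin plot bootstrap.  The flag leaf's own
share of grain carbon is bounded by scaling each bin's ear share with the
flag:awn weight ratio of the second model.  See `docs/methods.md` for
assumptions, numerical conventions and the synthetic-trial generator.

## Worked example

The package ships a noise-free six-plot fixture — three plots per extreme
water-status bin at the trial's anchor δ¹³C geometry:

```python
from earshare import GrainMixingModel
from earshare.io import build_plot_profiles, profiles_to_frame
from earshare.simulate import generate_worked_example, trial_records

tables = generate_worked_example()
profiles, _ = build_plot_profiles(trial_records(tables))
frame = profiles_to_frame(profiles)

ear_model = GrainMixingModel(frame, end_member_b="peduncle").fit()
flag_model = GrainMixingModel(frame, end_member_b="flag_leaf").fit()
print(ear_model.summary())
print(ear_model.contributions(flag_model).summary())
```

```
Grain delta13C mixing model (awns vs peduncle)
================================================
plots: 6   translocation offset: +0.00 permil

             bin weight_a weight_b  n_plots  clipped  out_of_support
 most_favourable    0.580    0.420        3    False               0
    intermediate       --       --        0    False               0
least_favourable    0.900    0.100        3    False               0

through-origin slope: 1.0000 (ok)
uncentred R^2:        1.0000
residual SD:          0.000 permil (n=6)

Grain carbon contribution report
==================================
             bin  n_plots ear_share shoot_share flag_share_raw  flag_share
 most_favourable        3      58.0        42.0           12.7        13.0
    intermediate        0        --          --             --         NaN
least_favourable        3      90.0        10.0            2.8         3.0
bin mean: ear 74.0%  shoot 26.0%  flag 7.8% (~8%)
plot-weighted mean: ear 74.0%  shoot 26.0%  flag 7.8% (~8%)
awn:flag weight ratio (most favourable bin): 4.56 (~5x)
```

Reading the report: under the least favourable water status the ear
supplies 90% of grain carbon and the whole shoot only 10%; under the most
favourable status the ear still supplies 58%.  The flag leaf alone —
traditionally credited as the main source — is bounded at 3% to 13% of
grain carbon (≈8% on average), roughly five times less than the awns even
under the best water conditions.

The same analysis runs from the shell on CSV tables:

```sh
earshare simulate --seed 42 --out sim/          # synthetic 18-plot trial
earshare mix --isotopes sim/isotopes.csv --boot 1000 --seed 42 --out report/
earshare budget --gasex sim/gasex.csv --spad sim/spad.csv --out budget.csv
earshare light --par sim/par.csv --out interception.csv
earshare tables --isotopes sim/isotopes.csv --agronomy sim/agronomy.csv --out tables/
earshare run --config pipeline.yaml             # full pipeline + manifest
```

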