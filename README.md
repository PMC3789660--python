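# denscape

Two-scale analysis of den-site selection for a den-dependent carnivore in a
fragmented landscape, built as a tested, reusable Python pipeline with a
synthetic-data generator whose ground truth makes every stage verifiable by
parameter recovery.

The package is aimed at spatial ecologists analysing use/availability data:
point locations of used sites (dens) on a vector land-cover map at the
home-range scale, and matched used/available microhabitat records at the
site scale.

## The two analyses

**Home-range scale — Euclidean distance ratios.** For each den *i*, an
800 m circular buffer (~200 ha, a typical annual home range) receives 200
uniform random points, and for each of seven features *j* (six land-cover
classes and roads) a ratio is formed

    r_ij = d(den_i, feature_j) / mean_k d(random_ik, feature_j),

with d = 0 for the class containing the den. Ratios below 1 indicate
selection, above 1 avoidance. Inference combines

- a one-sample MANOVA of the ratio vectors against **1** via Hotelling's
  T² = n (r̄−1)′S⁻¹(r̄−1), reported as Pillai's trace T²/(T²+n−1) with its
  exact F transform,
- percentile bootstrap CIs (1000 reps, resampling dens) per feature,
- per-feature one-sample t-tests of r̄_j = 1, and
- relative ranking by pairwise paired t-tests, summarized as a compact
  letter display.

**Den-area scale — matched discrete choice.** Each used site plus its m = 4
available sites form a choice set; the conditional-logit probability that
alternative *j* of set *s* is the used one is

    P(j|s) = exp(x_sj'β) / Σ_k exp(x_sk'β).

Covariates (rodent-burrow count, visibility 0–15, shrub count) are z-scored;
VIF screens collinearity; a quasi-complete-separation detector explains why
the categorical den substrate is summarized descriptively instead of fitted.
A candidate model set is ranked by AICc = −2ℓ + 2K + 2K(K+1)/(n−K−1) with
Akaike weights w_i ∝ exp(−Δ_i/2); the confidence set (ΔAICc ≤ 4) is averaged
per term with unconditional SEs

    Un.SE = Σ_i w_i √(SE_i² + (β_i − β̄)²),

odds ratios exp(β̄), and Wald CIs. Predictive ability is measured by k-fold
cross-validation: delta = proportion of held-out sets whose used site is not
the top-ranked alternative.

## Worked example

Simulate a study-sized dataset (26 dens on a fragmented mosaic with strong
grassland selection; 26 choice sets with burrow and visibility effects) and
run both scales:

```
denscape simulate --seed 4 --out-dir sim
denscape homerange --dens sim/dens.csv --landscape sim/landscape.geojson \
    --seed 4 --out-dir hr
denscape denarea --sets sim/choice_sets.csv --kfold 5 --seed 4 --out-dir da
```

The home-range step prints the MANOVA and a selection table:

```
MANOVA: Pillai 0.988, F(7,19) = 230.35, P = 5.27e-17
     feature    ratio       lo       hi          t            p rank
   grassland 0.066166 0.017019 0.123130 -35.025475 9.074333e-23    A
  plantation 1.045881 0.776301 1.325357   0.324573 7.482044e-01  CDE
agricultural 1.187751 1.029698 1.358739   2.262269 3.262531e-02    E
      fallow 0.848357 0.666615 1.017748  -1.690301 1.034035e-01  BCD
    ploughed 1.083233 0.912272 1.259736   0.926495 3.630472e-01   DE
    built_up 0.825359 0.685887 0.976463  -2.268534 3.218843e-02   BC
       roads 0.621511 0.473076 0.776123  -4.820525 5.932368e-05    B
```

Grassland's mean distance ratio ≪ 1 with a bootstrap CI excluding 1 and the
only "A" rank letter: dens sit far closer to grassland than random
expectation, and significantly closer than to any other feature (road
attraction, also built into the truth, shows up as the next-best letter).
The den-area step prints the AICc ranking, averaged odds ratios and the CV
error (abridged):

```
                                                    model  K     loglik      AICc  delta_AICc       weight
                              rodent_burrows + visibility  2 -21.749920 48.021579    0.000000 5.508714e-01
                rodent_burrows + shrub_count + visibility  3 -21.289220 49.669349    1.647770 2.416804e-01
rodent_burrows + visibility + rodent_burrows x visibility  3 -21.454079 49.999067    1.977488 2.049483e-01
...
                     term   wt_beta    un_se  odds_ratio       lo        hi
           rodent_burrows  1.801203 0.467155    6.056930 2.424389 15.132225
               visibility  1.458863 0.497119    4.301068 1.623380 11.395475
              shrub_count -0.312123 0.337259    0.731891 0.377891  1.417513
rodent_burrows:visibility  0.336273 0.447609    1.399720 0.582142  3.365529
k-fold CV prediction error (delta) = 0.346
```

Odds ratios well above 1 for burrow count and visibility recover the
built-in selection for prey-rich, high-visibility sites; shrub count and
the interaction have CIs spanning 1, as their small true effects warrant.
Delta is the held-out misclassification rate (chance level 0.8 with four
available alternatives per set).

## Layout

- `src/denscape/geospatial.py` — planar geometry engine (buffers, uniform
  disc sampling, containment, nearest-feature distances, GeoJSON I/O)
- `src/denscape/landscape.py` — synthetic mosaics, den placement and
  choice-set generation with known truth
- `src/denscape/homerange.py` — distance ratios, MANOVA, bootstrap,
  t-tests, ranking
- `src/denscape/denarea.py` — conditional logit, VIF, AICc/weights, model
  averaging, separation detection, k-fold CV
- `src/denscape/pipeline.py`, `src/denscape/cli.py` — orchestration,
  manifests, `denscape` CLI
- `docs/methods.md` — models, assumptions, parameter choices, limitations
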