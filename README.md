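# chronocall

Circadian rhythm modeling and chronotype clustering of telephone call
activity.

## The problem

The times at which a person places telephone calls carry a circadian
signature: most people concentrate their outgoing calls in one or two
daily activity periods, and whether the dominant period falls in the
morning or the evening is a behavioral expression of their chronotype.
For older adults especially, call detail records (CDRs) — the
operator-logged metadata of each call — offer a passive, objective,
long-horizon window onto these social rhythms, with potential value for
monitoring disruptions such as nocturnal phase shifts.

`chronocall` implements the full statistical-learning pipeline for this
kind of analysis, aimed at researchers in digital phenotyping and
behavioral epidemiology:

1. **Preprocessing** — keep outgoing calls only, select the
   calendar-month-aligned window in which the most participants were
   simultaneously active, and retain only persons with ≥ 1 outgoing
   call in *every* month of that window.
2. **Rhythm modeling** — pool each person's calls onto one composite
   24-hour day; compute the empirical hourly frequencies
   f_i(t) = n_i(t) / Σ_t n_i(t); fit a K-component Gaussian mixture
   model (GMM) to the raw call times-of-day by
   expectation–maximization. By default the mixture is *wrapped*
   (circular, period 24 h), so a 2 AM activity peak is modeled without
   edge artifacts.
3. **Goodness of fit** — a one-sample Kolmogorov–Smirnov test of the
   observed times against the fitted mixture CDF (P > .05 ⇒ the model
   cannot be rejected), plus per-hour squared errors between empirical
   and modeled bin frequencies.
4. **Chronotype** — each mixture component is one activity period
   (peak hour μ_k, spread σ_k, mixing proportion π_k); periods are
   ranked by descending π_k to find when the person is most socially
   active.
5. **Clustering** — each person becomes the 2-D point
   (primary peak, secondary peak); k-means (Lloyd's algorithm with
   k-means++ seeding, implemented in-package) partitions the cohort,
   and with k = 2 the cluster with the earlier primary-peak centroid is
   labeled *morningness*, the other *eveningness*.

Because real CDR datasets are private, the package ships a synthetic
cohort generator with exact ground truth (wrapped-mixture call times,
Poisson daily counts, staggered enrollment and designed dropouts), so
every stage can be validated against known parameters.

## Worked example

Run the whole pipeline on the default simulated cohort (26 persons,
12 months; 21 always-active, 5 designed dropouts):

```bash
chronocall run --seed 42 --outdir demo
```

`demo/preprocess_summary.csv` shows the activity filter at work —
26 enrolled, 21 retained, with a realistic spread of call volumes:

```
              statistic   value
    participants_before    26.0
     participants_after    21.0
   total_outgoing_calls 17192.0
    calls_per_person_q1   587.0
calls_per_person_median   749.0
    calls_per_person_q3  1011.0
```

`demo/fits.csv` holds each person's fitted mixture and its KS P value.
The generator gave morning-archetype persons peaks at 10 h and 18 h
with π₁ = 0.7; the EM recovers them to within a few minutes, and no fit
is rejected (all P ≫ .05):

```
person_id    mu1  sigma1   pi1    mu2  sigma2   pi2  ks_p
      m01  9.990   1.419 0.731 17.954   1.537 0.269 0.993
      m02  9.907   1.452 0.687 17.836   1.606 0.313 0.755
      m03  9.892   1.454 0.694 18.095   1.499 0.306 0.999
      m04 10.160   1.503 0.718 18.033   1.441 0.282 0.999
```

`demo/centroids.csv` shows the bipartite clustering: morning-dominant
persons sit near (10, 18), evening-dominant near (18, 10) — the same
two peak hours in opposite dominance order:

```
 cluster     x     y       label
       0  9.97 17.99 morningness
       1 17.99  9.95 eveningness
```

Other artifacts: `empirical_profiles.csv` / `model_profiles.csv` /
`squared_errors.csv` (the persons × 24 h heat-map matrices),
`ranked_modes.csv`, `clusters.csv`, `ground_truth.csv`, and
`manifest.json` (config + versions). Subcommands `simulate`, `fit`
(modeling only) and `cluster` (from an existing fits table) run the
stages separately; the same functionality is available as a library
(`chronocall.fit_gmm`, `chronocall.run_pipeline`, ...).

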