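# Methods

## Model

Each person's outgoing-call times-of-day, pooled over the observation
window onto a single 24-hour cycle, are modeled as draws from a
K-component wrapped Gaussian mixture

p(x) = Σ_k π_k Σ_{j∈ℤ} φ(x + 24j; μ_k, σ_k²),  x ∈ [0, 24),

with mixing proportions π_k (Σπ_k = 1), peak hours μ_k ∈ [0, 24) and
spreads σ_k in hours. K = 2 by default: human diurnal call activity is
assumed to have two broad periods — one morning, one evening — which
may be phase-shifted (including into the night) in individual cases.
Each component is read as one daily *activity period*; π_k is the share
of the person's calls that period accounts for, and ranking periods by
π_k yields the person's morningness–eveningness ordering. A BIC-based
choice of K over {1..4} (`select_k_bic`) is available but off by
default, since the two-period structure is the modeling hypothesis, not
a quantity to be re-estimated per person.

Wrapping matters whenever a peak sits near midnight: a linear Gaussian
fitted to calls clustered around 2 AM splits the mass at the 0/24 edge
and biases both the mean and the variance. A plain linear-Gaussian mode
(`wrapped=False`) is kept for comparison with analyses that ignore
circularity.

## EM on the circle

The wrapped mixture is fitted by EM with the image index j treated as a
latent variable alongside the component label: responsibilities are
computed over (k, j) pairs with j ∈ [−J, J], and the M-step updates
μ_k and σ_k² from the unwrapped values x + 24j before reducing μ_k
modulo 24. J is chosen so that the neglected tail mass is below 10⁻¹²
(J = 2 for the spreads that occur here; it grows automatically with
σ). Log-likelihoods use log-sum-exp throughout.

Numerical choices:

- **Initialization** — k-means++ seeding on the circle (circular
  distance), per-cluster circular means/variances as starting values;
  best of `n_init = 10` restarts by final log-likelihood.
- **Convergence** — relative log-likelihood increment below
  `tol = 1e-6`, at most `max_iter = 500` iterations.
- **Variance floor** — σ_k² ≥ 10⁻³ h², preventing degenerate collapse
  onto repeated timestamps.
- **Determinism** — all restarts draw from one seeded generator;
  components are reported sorted by ascending mean.
- **Degenerate inputs** — fitting requires at least K distinct values;
  a K=1 linear fit reduces exactly to the closed-form MLE (sample mean,
  /n variance).
- **Input granularity** — raw fractional call times are used when
  sub-hour resolution exists; hour-only data are placed at slot
  midpoints (t + 0.5) to avoid artificial ECDF ties at integers.

## Goodness of fit

A one-sample Kolmogorov–Smirnov test compares the observed times with
the fitted mixture CDF (for wrapped fits, the circular CDF measured
from midnight). D is evaluated on both sides of every ECDF jump; the
P value uses the asymptotic Kolmogorov distribution, and the model is
rejected when P ≤ α = .05. Two caveats are intentional properties of
the replicated procedure rather than oversights: the parameters were
estimated from the same data (which biases D downward, making
non-rejection easier), and no finite-sample correction is applied. The
per-hour squared errors (f_i(t) − f̂_i(t))², with f̂ the integral of the
fitted density over each hourly bin, accompany the test as a
localization of misfit. A `binned=True` variant runs the KS on
hour-discretized times instead of raw times.

## Preprocessing

"Active in a month" means ≥ 1 outgoing call in that calendar month.
The common observation window is the calendar-month-aligned interval of
the requested length maximizing the number of persons active in every
one of its months, ties going to the earliest start. Persons failing
the every-month criterion inside the chosen window are dropped;
per-person call-count quartiles use linear interpolation between order
statistics. Multiple devices of one person are merged by person id
before any filtering; timestamps are taken in one local timezone as
recorded, with no DST correction.

## Chronotype ranking and clustering

Activity periods are ranked by descending π_k; proportions within 10⁻⁹
are treated as tied and the earlier peak hour wins, so rankings are
reproducible. For K > 2 the two highest-weight periods define the
embedding. Each person maps to (primary peak, secondary peak) in
*dominance order* — this is what distinguishes a morning-dominant from
an evening-dominant person who share the same two peak hours; a
clock-order embedding would collapse them. The period spreads σ_k are
deliberately excluded from the embedding: they describe period
duration, not timing, and including them would let call-volume
concentration leak into the chronotype distance.

k-means is Lloyd's algorithm with k-means++ seeding, best of
`n_init = 20` restarts by inertia, empty clusters repaired by reseeding
to the farthest point. The default distance is plain Euclidean on hour
coordinates; a circular-aware metric (hours mapped to scaled sin/cos
pairs on the torus) is available via `metric="circular"` for cohorts
with peaks straddling midnight. With k = 2 the cluster whose centroid
has the earlier primary-peak coordinate is labeled morningness — the
label is a property of the centroids, not of cluster indices, and is
assigned only here, never by a per-person clock threshold.

## Synthetic cohorts

The generator emulates the structure of a small observational CDR
study: `n_morning = 11` morning-dominant and `n_evening = 10`
evening-dominant always-active persons plus `n_partial = 5` dropouts,
over 12 months. Call times come from the wrapped mixture with peaks at
10 h and 18 h, σ = 1.5 h, and dominant share π = 0.7 (mirrored for
evening types) — the midmorning/early-evening bimodality reported for
older adults. Daily outgoing counts are Poisson with mean 2 calls/day
(≈ 730/year, near the per-person median such studies report), with a
log-normal per-person rate multiplier (σ_log = 0.4) so that the
cohort's call-volume quartiles show a realistic spread. Partial persons
alternate between late enrollment (1–3 months) and one interior silent
month, guaranteeing by construction that preprocessing drops exactly
them. Token incoming traffic (incoming:outgoing ≈ 0.1) exercises the
direction filter; durations are log-normal and analytically inert.

What the generator does *not* emulate — weekday/weekend and seasonal
structure, within-day rate inhomogeneity beyond the mixture itself,
contact-network structure, device-specific behavior — bounds what
passing tests show: they validate the estimation and clustering
machinery under a correctly specified bimodal model, not robustness to
the full messiness of operator data.

## Validation problem sizes

The test suite validates parameter recovery on 100–200 simulated
individuals at 500 calls each (recovered peaks within ±0.5 h and π
within ±0.05 for ≥ 95% of individuals; KS rejection rate ≤ 10% at
α = .05 under the correctly specified model), EM against a brute-force
grid search on 40-point samples, k-means against exhaustive
2-partition enumeration at n ≤ 8, and the nocturnal case (2 AM peak)
under the wrapped model. These sizes give stable Monte-Carlo margins
while keeping the full suite fast.

## Known limitations

- The KS P value is anti-conservative in principle (estimated
  parameters); it replicates common practice rather than a corrected
  test such as a parametric-bootstrap KS.
- Euclidean clustering of hour coordinates distorts distances across
  midnight; use `metric="circular"` for nocturnal-heavy cohorts.
- Pooling all calls onto one composite day assumes rhythm stationarity
  over the window; drifting chronotypes are averaged, not detected.
- The morningness/eveningness labels are relative to the cohort (they
  come from bipartite clustering), not anchored to clock-time criteria.
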