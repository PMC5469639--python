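# Methods

## The problem and the model

`homepatterns` builds per-participant behaviour models from unannotated
passive-infrared (PIR) motion-sensor streams collected in ordinary homes.
The setting is ambient-assisted living: three PIR sensors (bedroom,
bathroom, lounge) plus optional door/fridge contact switches record
timestamped activations; no activity labels exist and none are assumed.
The analysis is "blind" — cohort membership (older persons, OP, versus
persons with cognitive impairments, CI) is used only a posteriori, to
validate clusters found without it.

The day is tiled by seven fixed *times of day* (ToD): Night 23:00–05:59,
Early Morning 06:00–09:59, Late Morning 10:00–11:59, Early Afternoon
12:00–13:59, Afternoon 14:00–16:59, Evening 17:00–19:59, Late Evening
20:00–22:59. Windows are half-open `[start, next start)`, so the printed
minute-resolution end labels ("…–5:59") denote "up to but excluding the
next start". Because the night window spans midnight, events are
attributed to a *logical day* — the calendar date of (timestamp − 6 h) —
so each analysis day runs 06:00→06:00 and owns one unbroken night.
Timestamps are naive local wall-clock times; daylight-saving shifts are
ignored, since the behaviour of interest is clock-time behaviour.

Each (room, phase, logical day) cell yields two features:

* **busyness** m — the event count, an aggregate movement measure that
  deliberately avoids recognising individual activities;
* **TE** (time between events) — with event times T_1 ≤ … ≤ T_m measured
  in seconds from the phase's clock start,

      TE = Σ_{i=1}^{m−2} [(T_{i+2} − T_{i+1}) + (T_{i+1} − T_i)] / (2m)
         = [(T_m − T_2) + (T_{m−1} − T_1)] / (2m).

  The denominator is read as 2m under the whole sum; this is the only
  reading that yields a finite summary for all m ≥ 3, and the telescoped
  closed form above is used as an independent oracle in tests. For m < 3
  no rhythm is measurable and TE falls back to the phase length in
  seconds: silence must read as maximally *slow*, not indistinguishable
  from frantic activity. TE is in seconds throughout.

That is 3 rooms × 7 phases × 2 families = 42 features per logical day.
Participant-level vectors take the per-day mean (M) and sample (n−1)
standard deviation (SD) of each feature over a day set, restricted to one
of five schemas: night-only (12 columns), full 24 h (84), or one room as
an independent block (28 each). Day order is randomized before the 70/30
train/test split; the training-set size is round-half-up(0.7 n), which
reproduces all four published pairs (78→55, 57→40, 36→25, 22→15 days).

## Pipeline stages

**ToD separability.** Each (day, phase) pair becomes a 6-feature sample
(busyness + TE per room) labelled by its phase; a one-vs-rest linear SVM
(C = 1, features z-scored on training statistics) is trained on the train
days and per-phase F-scores (F = 2PR/(P+R), zero-division → 0) are
computed on the test days. Sweeping dataset sizes 78/57/36/22 days probes
how much data a stable baseline needs. On the default synthetic cohorts
the night phase scores highest and the midday phases lowest — daytime
carer visits are systematic noise, nights are undisturbed.

**Reduction.** Columns with |Pearson ρ| > 0.85 against an earlier kept
column are dropped greedily in schema order (deterministic keep-first;
constant columns are dropped first with a warning). PCA is computed on
the correlation matrix (z-scored input) because the Kaiser rule's
eigenvalue-1 cutoff presupposes unit-variance features; components with
eigenvalue > 1 are retained (at least one, in the degenerate case where
none exceeds it), with the sign convention that each component's
largest-magnitude loading is positive.

**Sammon map.** The retained scores are projected to 2-D by minimizing
Sammon stress E = (1/Σδ) Σ (δ_ij − d_ij)²/δ_ij, which privileges small
input distances δ. Implementation: gradient descent with step-halving
(stress is monotonically non-increasing), PCA initialization with a
seeded random fallback, tol 1e−9, 500 iterations, duplicate-row pairs
excluded from the stress with a warning. Map distances are rescaled to a
similarity matrix Simi ∈ [0,1] by min–max normalization over the
*off-diagonal* entries; including the zero diagonal would pin the minimum
at 0 and the values would no longer span the unit interval.

**Clustering.** k = 2 throughout — every analysis contrasts two groups.
K-Means is Lloyd's algorithm (scikit-learn, best of 10 seeded restarts).
The SOM is a minimal 1×2 grid trained online for 500 epochs with a
Gaussian neighbourhood, learning rate 0.5→0.01 and radius 1→0.01, both
linearly decayed; a point's cluster is its best-matching unit. Unseen
rows are assigned to the nearest prototype (Euclidean), ties to the lower
index — the single tie-break convention used package-wide. Validity is
scored by the Dunn index (single-linkage separation / complete-linkage
diameter, the classic variant; singleton diameter 0, all-singleton
undefined) and the mean silhouette (s = (b−a)/max(a,b), singletons
score 0); both are checked against O(N²) brute-force references and the
silhouette additionally against scikit-learn.

**Validation.** Cluster ids are anonymous, so of the two possible
cluster→cohort mappings the one maximizing accuracy is taken (accuracy
therefore ≥ 0.5 even for uninformative clusterings). From the matched
2×2 confusion (rows OP/CI, columns clusters): accuracy = trace/N,
sensitivity = OP recall, specificity = CI recall, and per-cluster
precisions. Both recall and precision conventions are reported because
published practice mixes them; display values are rounded half-up to two
decimals while full precision is retained internally.

## The synthetic generator

No public dataset with this structure exists, so a simulator provides the
study conditions. Per (logical day, room, phase) it draws a homogeneous
Poisson process at the cohort profile's rate (events/hour), superposes
one planned daily visit burst per configured window (lounge events at
180/h for 20–30 min in the Late-Morning and Afternoon phases — the
carer/family visits that make midday noisy), and finally thins each
room's stream forward-sequentially so consecutive events are ≥ 8 s apart,
matching the PIR retrigger blind time. With fragmentation f > 1 night
events instead arrive in bursts of mean size f (burst count Poisson with
mean λ/f, within-burst gaps exponential with 20 s mean), leaving the
expected count unchanged while making nights choppy.

Default profiles: OP nights are quiet (bedroom 6/h, bathroom 1.5/h,
lounge 0.5/h, no fragmentation); CI nights are active and fragmented
(bedroom 20/h, bathroom 6/h, f = 2.5), reflecting the sleep-fragmentation
literature that motivates night-time as the baseline period. Daytime
rates overlap between cohorts (house-wide roughly 40–60 events/h, within
the published 50–400+ span), so the night is the discriminative period by
design. Each participant additionally draws one mean-1 lognormal rate
multiplier per (room, phase) with σ = 0.35: real residents differ in
tempo, and without such within-cohort variance every feature is collinear
with the cohort contrast, which is both unrealistic and degenerate for
correlation-based filtering. Sub-seeds are derived per participant by
counter from the master seed, so extending a cohort never changes
existing streams.

What the generator does *not* emulate: multi-occupancy, weekday/weather
structure, contact-sensor semantics, sensor dropout, or long-term drift
in a resident's behaviour. Passing tests therefore show that the pipeline
recovers the planted cohort structure under Poisson-like activity with
realistic heterogeneity — not that it would recover clinical cohorts from
arbitrary real homes.

## Reproducibility and problem sizes

A pipeline run is a pure function of its `RunConfig`: the master seed is
fanned out per stage through SHA-256, every artifact is written with a
config snapshot, and a manifest records content hashes (re-running a
config is byte-identical). Default study conditions are 5 OP + 5 CI
participants; 55 days for clustering analyses and 78 days (55 train / 23
test) where the size sweep or a held-out test set is involved. The
cohort-recovery surface in the tests and the acceptance script averages
20 independently seeded replicates of the full
simulate→features→reduce→cluster→match chain.

## Known limitations

* The Dunn and silhouette values on synthetic data are much higher than
  values typical of real cohorts — the planted separation is clean.
* The greedy correlation filter is order-dependent by design; a different
  column order can keep a different (equally valid) survivor set.
* The SOM is a 1×2 network; it is a competitive-learning counterpart to
  2-means, not a topographic map, and larger grids with U-matrix analysis
  are out of scope.
* With only N ≈ 10–17 participants, PCA eigenvalue estimates and the
  Kaiser cutoff are noisy; retained component counts vary across seeds.
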