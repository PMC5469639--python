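# homepatterns

Label-free behavioural phenotyping from home motion sensors.

`homepatterns` is for researchers and care-technology engineers working in
ambient-assisted living who must extract behaviour patterns from
*unannotated* passive-infrared (PIR) motion-sensor streams — the realistic
setting where nobody labels months of sensor data from dozens of homes.
From three PIR sensors per dwelling (bedroom, bathroom, lounge) it builds
per-participant behaviour models, clusters residents by behavioural
similarity without any clinical information, and only afterwards validates
the clusters against clinical cohort labels (older persons, OP, versus
persons with cognitive impairments, CI).

## The model

The day is tiled into seven times of day (ToD), phase 1 being the night
window 23:00–05:59; events are attributed to a *logical day* running
06:00→06:00 so nights are never split. Each (room, phase, day) cell is
summarised by two features — the event count ("busyness", m) and the time
between events,

    TE = Σ_{i=1}^{m−2} [(T_{i+2} − T_{i+1}) + (T_{i+1} − T_i)] / (2m),

with TE = phase length when m < 3 — giving 42 features per day and, after
per-participant mean/SD aggregation, 12 (night), 84 (24 h) or 28
(per-room) participant-level features. The pipeline then:

1. scores each ToD's distinguishability with a one-vs-rest linear SVM
   (per-phase F-measure) across dataset sizes 78/57/36/22 days;
2. prunes correlated features (|ρ| > 0.85), applies Kaiser-rule PCA
   (eigenvalue > 1) and clusters participants into two groups with
   K-Means and a 1×2 self-organizing map, scored by the Dunn and
   silhouette indices;
3. projects participants to 2-D by Sammon mapping and rescales map
   distances to a similarity matrix Simi ∈ [0, 1];
4. matches clusters to cohorts (best of the two possible mappings) and
   reports accuracy, sensitivity (OP recall), specificity (CI recall) and
   per-cluster precision.

A two-cohort synthetic home simulator (homogeneous Poisson per room and
phase, fragmented CI nights, daytime carer-visit bursts, 8-s sensor blind
time, per-participant rate heterogeneity) provides fully specified study
conditions, so every stage is testable end to end. See
`docs/methods.md` for the full account.

## Worked example

Simulate 5 OP + 5 CI participants for 55 days and run the night-time
analysis:

```python
from homepatterns import (SimulationSpec, simulate_cohorts, day_feature_frame,
                          aggregate_participants, pearson_filter, pca_kaiser,
                          kmeans_fit, som_fit, dunn_index, silhouette_mean,
                          match_clusters, cohort_metrics)

spec = SimulationSpec(n_op=5, n_ci=5, n_days=55, seed=7)
streams, labels = simulate_cohorts(spec)
frames = {s.user_id: day_feature_frame(s) for s in streams}
cohorts = dict(zip(labels["user_id"], labels["cohort"]))

matrix = aggregate_participants(frames, "night12")   # 10 x 12
reduced, dropped = pearson_filter(matrix)
pca = pca_kaiser(reduced)

km = kmeans_fit(pca.scores, k=2, seed=0)
conf = match_clusters(dict(zip(pca.scores.index, km.train_assignments)),
                      cohorts)
print(cohort_metrics(conf, "night", "KM").rounded())
print(dunn_index(pca.scores, km.train_assignments),
      silhouette_mean(pca.scores, km.train_assignments))
```

Output (seed 7):

```
night features kept: 5/12, components retained: 1
KM  confusion [[5, 0], [0, 5]]  accuracy 1.0  sensitivity 1.0  specificity 1.0
SOM confusion [[5, 0], [0, 5]]  accuracy 1.0  sensitivity 1.0  specificity 1.0
Dunn 1.413  silhouette 0.840
```

Reading: 7 of the 12 night features were dropped as collinear, one
principal component carried the night-activity contrast, and both
clustering methods recovered the two cohorts exactly — the confusion
matrix rows are the true cohorts (OP, CI), columns the matched clusters.
Dunn > 1 means the clusters are farther apart than their widest member
spread; silhouette 0.84 means points sit far closer to their own cluster
than to the other.

The same run from the shell:

```sh
homepatterns simulate --n-op 5 --n-ci 5 --days 78 --seed 7 --out data/
homepatterns run-all --out run/ --seed 7
```

which writes day-feature tables, the separability sweep, the Sammon map
and similarity matrix, cluster validity indices, and the validation table
(one KM and one SOM row per analysis: night, full 24 h, bedroom,
bathroom, lounge) under `run/`, plus a manifest of content hashes —
re-running the same config reproduces every artifact byte for byte.

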