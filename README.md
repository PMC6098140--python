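# hentrack

Individual laying hens housed in large commercial aviaries move among the
house's functional areas — wintergarden, litter, and the tiered levels
holding feed, water, and nestboxes — in strikingly hen-specific daily
patterns. `hentrack` quantifies that individuality: given 1 Hz
zone-registration logs (zone codes 1–5, one sample per second per hen),
it builds fixed-window daily datasets ("hen-days"), extracts
transition-count features, and asks how reliably hen-days can be assigned
back to the individual hen. It is aimed at precision-livestock and animal
behaviour researchers working with zone-level tracking data.

Because such tracking datasets are rarely public, the package includes a
first-class synthetic flock simulator — an inhomogeneous semi-Markov
model with hen-specific dwell-time and destination parameters, oviposition
rhythms, and pophole-gated wintergarden access — so the entire analysis
chain is testable end to end.

## Methods at a glance

For each hen-day the six summary variables are the visit counts
$v_1,\dots,v_5$ into zones 1–5 plus the daily total $T=\sum_z v_z$.
Three classifiers are applied:

* **LDA** — an equal-covariance Gaussian classifier with hen identity as
  the class. With pooled within-class covariance $\Sigma$ and class means
  $\mu_k$, posteriors are
  $p(k\mid x) \propto \pi_k \exp\left(-\tfrac12 (x-\mu_k)^\top
  \Sigma^{-1} (x-\mu_k)\right)$, evaluated by resubstitution. Variables
  are chosen by backward elimination with re-entry on the share of
  discriminatory power $\operatorname{tr}(W^{-1}B)$ (5 % threshold).
* **HC** — agglomerative clustering of the six-variable vectors under the
  `ward.D` convention: the Lance–Williams update with Ward coefficients
  applied to unsquared Euclidean distances.
* **DTW + HC** — banded dynamic time warping between the per-second zone
  series (Sakoe–Chiba band, 10 % of series length; symmetric unit steps;
  |Δzone| local cost), then `ward.D` clustering of the dissimilarity
  matrix.

For the clustering methods, dendrograms are cut into $n$ to $n+2$ groups
($n$ = number of hens) and each hen scores the largest number of her days
landing in one group; the overall consistency pools these counts over all
hen-days.

## Worked example

```python
import hentrack as ht

profiles = ht.default_profiles(rng_seed=1)          # 13 archetype hens
logs = ht.simulate_flock(profiles, n_days=7, master_seed=1)
hendays = ht.build_hen_days(logs)                   # 91 hen-days, 54,000 s each
feats = [ht.summarize(hd) for hd in hendays]

model, lda_report = ht.evaluate_lda(feats)
print(model.selected_vars)                          # ('z2', 'z3', 'z5', 'total')
print(f"LDA  {lda_report.overall_pct:.1f}%")        # LDA  100.0%

tree = ht.ward_linkage(ht.feature_distances(feats))
_, hc_report = ht.best_grouping(tree)
print(f"HC   {hc_report.overall_pct:.1f}%")         # HC   92.3%

D = ht.dtw_matrix(hendays, ht.DTWConfig(downsample_s=60))   # 91 x 91
_, dtw_report = ht.best_grouping(ht.ward_linkage(D))
print(f"DTW  {dtw_report.overall_pct:.1f}%")        # DTW  89.0%
```

The three percentages are overall grouping consistencies: the share of
the 91 simulated hen-days assigned to (LDA) or grouped with (HC, DTW)
their own hen. On this seed the discriminant model recovers every
hen-day, feature clustering misgroups 7 of 91, and the
time-warping route — which compares the full daily occupancy
trajectories rather than daily counts — misgroups 10.

The same pipeline is available from the shell:

```
hentrack all --out runs/demo --seed 1
```

which writes the feature table, flock summary, dissimilarity matrix,
linkage trees, per-method consistency reports, and figures (per-day
location rasters, per-hen box plots, annotated dendrograms).

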