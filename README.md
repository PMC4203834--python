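# platesort

Reading, filtering, summarizing, statistically testing and plotting of
per-object data from **COPAS** and **BioSorter** large-particle flow
cytometers sampling 96-well microtiter plates.

These instruments measure every object (a *C. elegans* larva, a mosquito
larva, a zebrafish embryo, ...) that passes the flow cell and write one
tab-delimited text line per object: well coordinate, sort status, time of
flight (TOF, a proxy for length), integrated extinction (EXT, optical
density) and up to three fluorescence channels.  A single plate yields
thousands of records that are awkward to clean, aggregate and compare by
hand.  `platesort` turns those files into tidy per-well summaries and runs
the quality-control statistics a plate screener needs, for researchers
doing high-throughput organismal phenotyping and dose-response screens.

## What it does

- **Parse / write** instrument files with automatic header-dialect
  detection (column-name synonyms, user-extensible), dropping and counting
  malformed lines instead of failing.
- **Filter** non-organism records two ways: inclusive min/max cutoffs on
  TOF and EXT, and a per-device **bubble classifier** — an RBF support-vector
  machine on standardized features (TOF, EXT, fluorescence, EXT/TOF ratio)
  trained from the two-plate protocol (one plate of pure organisms with the
  bubble trap engaged, one of pure bubbles with the trap disengaged), with
  Platt-scaled probabilities so each object gets P(bubble) ∈ [0, 1].
- **Normalize** integrated channels by object length: `norm_x = x / TOF`,
  so optical density and fluorescence are comparable across object sizes.
- **Summarize** each well: population size *n* and mean, variance, median,
  quantiles (10/25/75/90 by default), min and max per trait, optionally for
  log-transformed traits; remove wells (blank-to-NA or drop) and fill
  missing wells so every summary has the full 8×12 geometry.
- **Test for edge effects**: a two-sided Wilcoxon rank-sum test comparing a
  per-well statistic between the 36 outer-ring wells and the 60 interior
  wells.  For pooled sample sizes ≤ 20 without ties the p-value is exact
  (full enumeration of the null rank-sum distribution); otherwise a
  tie-corrected normal approximation with continuity correction is used.
- **Correlate** traits over wells (pairwise-complete Pearson or Spearman),
  within one plate or between two plates matched by well.
- **Summarize dose-response** layouts given 96-element strain and dose
  vectors: per-well points and per-(strain, dose) means.
- **Plot** well-wise scatter/histogram grids, heatmaps, cross-plate
  box/bar comparisons, correlation matrices and dose-response curves
  (PNG/SVG/PDF).
- **Simulate** instrument files with controlled structure (bubble
  contamination, empty wells, edge gradients, strain×dose effects) for
  testing and power studies.

## The statistics at the core

For well sets *E* (edge, |E| = 36) and *C* (center, |C| = 60) and a
per-well statistic $s_w$ (default the well mean of a trait), the
edge-effect test computes the rank-sum $W = \sum_{w \in E} R(s_w)$ over
the pooled midranks and the two-sided p-value

$$p = \min\bigl(1,\; 2\min(P_0(W \le w),\, P_0(W \ge w))\bigr),$$

with $P_0$ the exact permutation null when $n_1 + n_2 \le 20$ and tie-free,
else the normal approximation with variance
$\tfrac{n_1 n_2}{12}\bigl(n_1 + n_2 + 1 - \sum_j (t_j^3 - t_j) / ((n_1+n_2)(n_1+n_2-1))\bigr)$
and a 0.5 continuity correction.  Wells — not raw objects — are the
exchangeable units, so pooled per-object records are never compared
directly (that would pseudo-replicate).

## Worked example

```python
import platesort as ps

# a synthetic plate: 8% bubble contamination, wells C3 and F8 left empty
scenario = ps.PlateScenario(seed=11, bubble_fraction=0.08, empty_wells=("C3", "F8"))
plate, truth = ps.generate_plate(scenario, path="plate.txt")
print("records:", len(plate), " true bubbles:", truth.n_bubbles)

# train the bubble classifier from the two-plate protocol
obj, bub = ps.generate_training_pair(ps.PlateScenario(seed=12))
clf = ps.train_bubble_classifier(obj, bub, random_state=0)
print(f"held-out accuracy: {clf.holdout_accuracy_:.3f}")

clean, flagged = ps.classify_bubbles(plate, clf, mode="drop")
print("flagged as bubbles:", flagged)

summary = ps.fill_wells(ps.summarize_plate(ps.normalize(clean)))
row = summary.data.set_index("well").loc["A1"]
print(f"A1: n={row['n']:.0f} mean_tof={row['mean_tof']:.1f} mean_norm_ext={row['mean_norm_ext']:.3f}")

report = ps.edge_effect_test(summary, trait="tof")
r = report.results["tof"]
print(f"edge-effect p (mean_tof): {r.p_value:.3f}")
```

Output:

```
records: 2824  true bubbles: 226
held-out accuracy: 1.000
flagged as bubbles: 226
A1: n=30 mean_tof=293.4 mean_norm_ext=0.503
edge-effect p (mean_tof): 0.399
```

The classifier flags exactly the 226 contaminating bubbles; well A1 holds
30 organisms of mean length ≈ 293 TOF units with a per-length optical
density ≈ 0.5 (the generator's EXT/TOF ratio); and the edge-effect test
finds no position effect on this null plate (p = 0.40).

The same pipeline is available from the shell:

```bash
platesort simulate --scenario scenario.yaml -o plate.txt
platesort train-svm --objects objects.txt --bubbles bubbles.txt -o model.json
platesort filter plate.txt --svm model.json --mode drop > clean.txt
platesort summarize clean.txt --fill > summary.tsv
platesort edge summary.tsv --all
platesort plot clean.txt --kind scatter -o tof_vs_ext.png
```

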