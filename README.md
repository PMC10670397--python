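# neosleep

Sleep-state classification for preterm infants from cardiorespiratory
signals and video-based actigraphy.

Preterm infants in the NICU spend most of their time asleep, and the
balance of active sleep (AS, REM-like), quiet sleep (QS, non-REM-like) and
wake is a marker of neurodevelopment — but the gold standard,
polysomnography, is too obtrusive for fragile infants. This package
implements an unobtrusive alternative built on signals the bedside monitor
and a camera already provide: per 30-s epoch it extracts **91 features** —
34 cardiac (HRV band powers incl. extended sHF/uHF bands, line length,
deceleration statistics, sample-entropy family, Lempel–Ziv complexity),
41 respiratory (rate, breath-by-breath correlation, spectral, amplitude,
flow/volume, regularity), 8 cardiorespiratory-interaction features
(visibility-graph network statistics of the respiratory amplitude sampled
at each R peak) and 8 motion features from video actigraphy — and
classifies epochs into {AS, QS, CTW} (CTW = caretaking + wake) with an
extremely-randomized-trees ensemble. Evaluation follows small-cohort
clinical practice: leave-one-subject-out cross-validation, SMOTE balancing
applied strictly inside each training fold, Cohen's kappa / sensitivity /
precision / specificity / AUC, and Gini feature importances.

Because the clinical recordings such studies rest on are not shareable, the
package ships a first-class synthetic-recording simulator
(`neosleep.synthetic`) that generates state-annotated ECG heartbeats,
respiratory effort and motion traces with the documented physiological
structure (QS: slow steady heart rate, regular breathing, stillness; AS:
faster variable heart rate, irregular deep breathing; CTW: wake-like
cardiorespiratory pattern plus heavy movement; state mix AS 72 % / QS 12 % /
CTW 16 %). Every pipeline stage is tested against it, and the core
statistics (SampEn, ApEn, LZ76, visibility graphs, assortativity,
clustering, kappa, AUC) are verified exactly against independent
brute-force implementations. See `docs/methods.md` for models, parameter
defaults and limitations.

## Worked example

```python
from neosleep import SimConfig, simulate_cohort, assemble_features
from neosleep.modeling import run_task

cfg = SimConfig(seed=7, duration_epochs=60)          # 60 epochs = 30 min/subject
recs = simulate_cohort(cfg, n_subjects=4)
matrix = assemble_features(recs)                     # epochs x (91 features + labels)

report = run_task(matrix, "ECG-Resp-CRI-Motion", "3class", seed=7)
print({k: round(v, 2) for k, v in report.per_fold_kappa.items()})
print(f"mean kappa {report.mean_kappa:.2f} +/- {report.sd_kappa:.2f}")
print(report.pooled_cm)
```

prints

```
{'S1': 0.96, 'S2': 0.96, 'S3': 0.87, 'S4': 0.95}
mean kappa 0.94 +/- 0.04
[[171   0   1]
 [  0  36   0]
 [  6   0  26]]
```

Each subject is held out once; its kappa measures chance-corrected
agreement between predicted and annotated states on that unseen subject.
The pooled confusion matrix (rows = true AS/QS/CTW) shows where epochs are
confused — here a few CTW epochs are mistaken for AS, the hardest
distinction for cardiorespiratory features, which motion features largely
resolve. On noise-free synthetic data kappas are far higher than on real
NICU recordings; the directional comparisons between feature sets, not the
absolute values, are the meaningful output. The top-ranked importances in
this run (`report.importance`) are motion features (`motion_sum`,
`motion_p95`, `motion_sd`), reflecting their role in separating CTW from
sleep.

A command-line interface wraps the same stages:

```bash
neosleep simulate --out data/ --seed 1 --subjects 8 --epochs 120
neosleep extract  --in data/ --out features.csv
neosleep evaluate --features features.csv --out reports/ --seed 1
neosleep registry --out feature_registry.csv
```

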