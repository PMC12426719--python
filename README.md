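# hypnodense

Hypnodensity-based characterisation of sleep structure. Where a hypnogram
assigns one sleep stage to each 30-s epoch, a hypnodensity keeps the full
per-epoch probability distribution produced by an automated classifier.
This package computes and compares:

- **Ambiguity** — the normalized Shannon entropy of each epoch's
  probability vector (`-(1/log K) Σ p_i log p_i`): 0 for a one-hot epoch,
  1 for a uniform one. Over 4 stages, values above 0.5 require at least
  three stages with non-zero probability, and values above 0.79
  (= log 3 / log 4) require all four.
- **Transition continuity** — 1 minus the total-variation distance between
  the probability vectors flanking a stage transition: 1 means no
  distributional change, 0 means maximal change.
- **Bout durations** — run lengths of the hypnogram, a sleep-stability
  measure.
- **Agreement** — Cohen's kappa and per-class F1/sensitivity/PPV between a
  manual reference and automated stagings.
- **Group statistics** — Mann–Whitney U with rank-biserial effect size
  (exact by enumeration for small tie-free samples), Welch t-tests,
  Friedman test with post-hocs, all jointly corrected with
  Benjamini–Hochberg at a configurable FDR (default 10%).

A synthetic cohort generator (first-order Markov stage dynamics, Dirichlet
probability vectors with tunable spread, cross-transition blending,
REM-probability leakage and a noisy simulated manual scorer) makes the
whole analysis testable offline, including a preset contrast between an
"RBD-like" and an "OSA-like" group.

## CLI

```bash
# simulate a 20+20-subject cohort with the built-in presets
hypnodense simulate --out cohort/ --seed 7 --subjects 20 --epochs 960

# custom groups: name=preset (or name=path/to/profile.yaml)
hypnodense simulate --out cohort/ --group early=rbd_like --group late=osa_like

# run the full analysis; writes agreement.csv, bouts.csv, ambiguity.csv,
# continuity.csv, tests.csv (the jointly BH-adjusted report) and run.log
hypnodense analyze --cohort cohort/manifest.json --out analysis/ --fdr 0.10

# print the test table
hypnodense report --tests analysis/tests.csv --significant-only
```

File formats are plain text: hypnograms as one label per line or
`epoch,stage` CSV; hypnodensities as `epoch,W,N1+N2,N3,R` CSV; cohorts as
a JSON/YAML manifest pointing at per-subject files.

## Library

```python
import hypnodense as hd

cohort = hd.simulate_cohort(
    {"rbd_like": hd.rbd_like(), "osa_like": hd.osa_like()},
    n_subjects=20, n_epochs=960, seed=7,
)
report, tables = hd.run_all(cohort, hd.AnalysisConfig(fdr=0.10))
for r in report.results:
    if r.significant:
        print(r.label, r.p_adjusted, r.effect_size)
```

Lower-level pieces (`ambiguity`, `transition_continuity`, `extract_bouts`,
`cohens_kappa`, `bh_adjust`, …) are importable directly; see the module
docstrings.

## Conventions

- Argmax staging breaks ties by stage-set order (W > N1+N2 > N3 > R); an
  externally scored hypnogram can be supplied alongside a hypnodensity
  instead.
- Continuity uses the two epochs immediately flanking the boundary
  (t and t+1). Natural log throughout the entropy (the normalized ratio is
  base-free); 0·log 0 = 0.
- Stage-specific ambiguity pooling groups epochs by the *classifier's own*
  staging, never the manual one.
- Hypnodensity rows off by ≤ 1e−6 are renormalized silently, ≤ 1e−3 with a
  log entry (CSV rounding), beyond that rejected.
- Per-subject kappa is summarized as mean ± SD across subjects; edge bouts
  at recording start/end are counted.
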