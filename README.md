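# phenofreeze

Behavioural phenotyping of conditioned freezing for trait-anxiety research.

After auditory aversive conditioning, mice re-exposed to the tone (a
memory-retrieval session scored in 24 × 30-s bins) freeze strongly at tone
onset, but individuals diverge as the tone continues: *phasic* responders
return toward baseline while *sustained* responders keep freezing through the
late bins. The sustained response is stable across repeated retrievals and
correlates with classical anxiety tests, which makes it usable as a behavioural
marker of an anxiety endophenotype. `phenofreeze` packages that analysis for
behavioural neuroscientists working from binned freezing exports (e.g. video
tracking output) and for anyone who wants a tested, scriptable version of the
pipeline:

- **Decay-curve modelling.** Freezing during the tone window (bins 13–24,
  re-indexed t = 0…11) is modelled as `y(t) = y0 · e^(−b·t)` and fitted by
  ordinary least squares on the log scale, `log y(t) = log y0 − b·t`. The decay
  rate `b`, the onset level `y0`, and mean sustained freezing (bins 18–24) are
  the per-animal features.
- **Model-based clustering.** A two-component Gaussian mixture fitted by EM
  (restart control, per-iteration log-likelihood traces, BIC) splits each
  cohort into phasic and sustained responders; greedy forward/backward
  variable selection scores feature subsets by the BIC difference between the
  two-component and one-component fits.
- **Shifter classification.** Animals re-clustered at the second retrieval are
  labelled consistent or shifter (sustained→phasic: safety learning;
  phasic→sustained: threat generalisation).
- **Extreme-responder selection** by freezing profile or by open-field
  periphery time among consistent animals, as done before tissue profiling.
- **Trait statistics.** Significance-masked Pearson correlation matrices,
  pooled-SD Cohen's d, Welch/pooled t tests, pooled-OLS extinction slopes
  across retrievals, per-bin variance profiles, and the |z| > 2.81 outlier
  screen.
- **Gene-set overlap.** Fisher's exact test of two gene lists against an
  explicit universe, with Haldane-corrected odds ratios.
- **Synthetic cohorts.** A seeded generator producing freezing sessions,
  anxiety metrics and ground truth with the structure above — bimodal
  sustained freezing, sex effect, extinction, shifters — so the whole pipeline
  is testable end to end.

## Worked example

```python
import phenofreeze as pf

cfg = pf.SyntheticConfig(seed=17)                 # 48 animals per sex
sessions_df, metrics, truth = pf.generate_cohort(cfg)
sessions = pf.frame_to_sessions(sessions_df)

assignments, models = pf.cluster_cohort(sessions, session_label="MR1", seed=17)
print(assignments.label.value_counts())
```

Running `python examples/02_cluster_phenotypes.py` (the script around the
snippet) prints:

```
96 animals at MR1: 56 sustained, 40 phasic
  female: phasic centre (sust 26.2%, b 0.14) | sustained centre (sust 80.4%, b 0.01) | BIC 610.8
  male: phasic centre (sust 11.6%, b 0.28) | sustained centre (sust 74.1%, b 0.02) | BIC 601.8
agreement with generator truth: 100.0%
```

i.e. the mixture recovers, per sex, a phasic component (low late-tone
freezing, fast decay) and a sustained component (high late-tone freezing,
near-zero decay), and on this seed every animal is assigned to its generating
phenotype. The other scripts in `examples/` walk through curve fitting,
shifter classification and responder selection, the trait statistics, and the
gene-set overlap test, each printing a short interpretation of its numbers.

A thin CLI mirrors the library for shell use:

```sh
phenofreeze simulate-cohort --seed 5 --out data/
phenofreeze fit --input data/sessions.csv --session MR1 --output fits.csv
phenofreeze cluster --features fits.csv --seed 17 --output assignments.csv
```

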