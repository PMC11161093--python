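"""Trait statistics around the phenotypes.

On a six-retrieval synthetic cohort: the masked Pearson correlation
matrix between anxiety metrics and sustained freezing, the per-sex
effect size (Cohen's d) of sustained freezing, pooled-OLS extinction
slopes of both freezing components, the per-bin variance profile, and
the z-score outlier screen.
"""

import numpy as np
import pandas as pd

import phenofreeze as pf

cfg = pf.SyntheticConfig(seed=5, sessions=tuple(f"MR{i}" for i in range(1, 7)))
sessions_df, metrics, _ = pf.generate_cohort(cfg)
sessions = pf.frame_to_sessions(sessions_df)

# correlation of MR1 sustained freezing with the anxiety-test metrics
fits = pf.fits_to_frame(pf.fit_cohort([s for s in sessions if s.session == "MR1"]))
table = metrics.merge(fits[["animal_id", "sustained_mean"]], on="animal_id")
table = table.rename(columns={"sustained_mean": "MR1_sustained"}).drop(columns="animal_id")
corr = pf.pearson_matrix(table, alpha=0.05)
shown = corr.to_frames()[0].where(pd.DataFrame(corr.mask, index=corr.variables,
                                               columns=corr.variables))
print("Pearson r with MR1 sustained freezing (blank = p >= 0.05):")
print(shown["MR1_sustained"].drop("MR1_sustained").round(2).to_string())

# effect size of sustained freezing between the phenotypes, per sex
asg, _ = pf.cluster_cohort(sessions, session_label="MR1", seed=5)
sexes = {s.animal_id: s.sex for s in sessions}
merged = asg.merge(fits, on="animal_id").assign(sex=lambda d: d.animal_id.map(sexes))
for sex in ("female", "male"):
    sub = merged[merged.sex == sex]
    d = pf.cohens_d(sub.loc[sub.label == "sustained", "sustained_mean"],
                    sub.loc[sub.label == "phasic", "sustained_mean"])
    print(f"\nCohen's d of sustained freezing, {sex}s: {d:.2f}")

# extinction across MR1..MR6, pooled OLS per component
for comp in ("phasic", "sustained"):
    res = pf.extinction_slope(sessions, component=comp)
    print(f"{comp} extinction slope: {res.slope:.2f} %/retrieval "
          f"(p = {res.p_value:.2g}, {res.n_points} points)")

var, peak = pf.variance_by_bin([s for s in sessions if s.session == "MR1"])
print(f"\nMR1 freezing variance peaks at bin {peak} "
      f"(variance {var[peak - 1]:.0f}); individual differences emerge late "
      "in the CS window.")

values = metrics["oft_periphery_s"].to_numpy()
n_out = int(pf.zscore_screen(values).sum())
print(f"outlier screen on OFT periphery time: {n_out} of {values.size} flagged "
      f"at |z| > {pf.ZSCORE_THRESHOLD}")
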