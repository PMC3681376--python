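# thermocomplexity

Complexity analysis of continuously monitored body temperature for
discriminating causes of systemic inflammation in the ICU.

Fever is usually treated as a snapshot — febrile or not — but a 24-hour
temperature curve sampled every 10 seconds carries dynamics: oscillations
attributed to neurogenic (0.025–0.05 Hz), metabolic/endothelial
(0.00625–0.025 Hz) and slower ultradian inputs on skin blood flow. Critical
illness tends to "decomplexify" these rhythms: patients with septic shock
show near-periodic, low-variability temperature signals, while noninfectious
systemic inflammation (SIRS) stays broadband and irregular. This package
implements the full analysis chain that turns that observation into a
classifier, for researchers working with continuous-monitoring physiological
time series:

- **Preprocessing** — artifact repair by linear interpolation, mean removal
  (`sign_m`), linear detrending (`sign_mdetr`).
- **Wavelet features** — an exact Fourier-domain Meyer filter bank over nine
  dyadic scales; per scale the wavelet energy
  `WE(s_i) = Σ_j w²(s_i,j)/L_i` and wavelet entropy
  `WEn(s_i) = −Σ_j p_j log p_j`, `p_j = w²(s_i,j)/Σ_j w²(s_i,j)`; plus a
  Meyer continuous transform with energy/entropy over four physiological
  bands and the whole time–scale map (10 features).
- **Multiscale entropy** — sample entropy `SampEn(m=2, r=0.15·SD)` on
  coarse-grained series at scale factors τ = 1..36, and its sum `sumEn`.
- **Statistics** — Lilliefors screening, pairwise Wilcoxon rank-sum,
  Kruskal–Wallis with Dunn/Bonferroni multiple comparisons, Spearman ρ
  against SOFA severity, one-way ANOVA.
- **Clustering** — Euclidean dissimilarity matrices over feature subsets,
  2-cluster k-means, intraclass/interclass distances, clustering cost, and
  agreement with the SIRS-vs-infected split.
- **Classification** — random-subset wrapper feature selection scored by
  leave-one-out balanced accuracy of a linear discriminant, per group pair.
- **Synthetic cohorts** — a generator producing 24-h, 0.1-Hz surrogate
  recordings with band-structured oscillations, group-dependent regularity,
  0.05 °C sensor quantization, artifacts and realistic between-subject
  variation, so the whole chain is testable without patient data.

Estimator classes (`WaveletFeatureExtractor`, `MultiscaleEntropyTransformer`,
`WrapperLDAClassifier`, `TwoClusterKMeans`, `LinearDiscriminant`) follow the
scikit-learn protocol and compose with its pipelines and model selection.

## Worked example

```python
from thermocomplexity import (
    SyntheticCohortConfig, default_profiles, generate_cohort,
    extract_feature_table, kruskal_wallis, WrapperConfig, pairwise_classify,
)

cfg = SyntheticCohortConfig(n_per_group=8, seed=7)      # 24 h at 0.1 Hz
cohort = generate_cohort(default_profiles(), cfg)        # SIRS/sepsis/shock
table = extract_feature_table(cohort, variants=("sign_mdetr",),
                              include_mse=False)

print(table.groupby("group")["WEn_s6"].median().round(3))
h, p, _ = kruskal_wallis(table["WEn_s6"], table["group"])
print(f"Kruskal-Wallis on WEn_s6: H = {h:.2f}, p = {p:.4f}")

report = pairwise_classify(table, WrapperConfig(n_iterations=200, seed=7),
                           variants=("sign_mdetr",))
print(report[["pair", "features", "accuracy"]].round(3))
```

prints

```
SIRS            4.079
sepsis          2.842
septic_shock    2.216
Kruskal-Wallis on WEn_s6: H = 15.54, p = 0.0004
                  pair                features  accuracy
        SIRS vs sepsis               CWTentro4     1.000
  SIRS vs septic_shock       CWTentro3, CWTen1     1.000
sepsis vs septic_shock WE_s4, CWTentro3, WE_s3     0.812
```

Read: the scale-6 wavelet entropy (10–21-minute ultradian oscillations,
`WEn_s6`) drops monotonically from SIRS through sepsis to septic shock —
broadband irregular thermoregulation in noninfectious inflammation,
near-periodic low-complexity dynamics in shock — and the group difference is
significant by Kruskal–Wallis. The wrapper then selects ultradian-band
entropy features (`CWTentro3/4`, the continuous-wavelet entropies of the
lower-metabolic/ultradian bands) and separates SIRS from both infected
groups perfectly in leave-one-out cross-validation at this cohort size; the
sepsis-vs-shock pair, two stages of the same infectious process, is the
hardest, at 81% accuracy.

The same chain runs from the shell:

```bash
thermocomplexity simulate --n-per-group 5 --seed 1 --outdir cohort/
thermocomplexity features cohort/manifest.csv --out features.csv
thermocomplexity stats features.csv
thermocomplexity cluster features.csv --seed 1
thermocomplexity classify features.csv --iterations 1000 --seed 1
# or everything from a YAML config:
thermocomplexity run-all config.yaml --seed 1
```

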