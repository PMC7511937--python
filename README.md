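# thermoliver

Unsupervised detection of fatty liver disease status from surface
thermography.

Fatty liver disease (NAFLD/NASH) changes hepatic perfusion and
inflammation, and in small animals these changes reach the skin surface
as increased *spatial* temperature heterogeneity over the liver region.
`thermoliver` implements an image-analysis pipeline that turns weekly
infrared temperature maps of a mouse cohort into an automatic disease
call, with no labels used for training:

1. **Texture features.** For a rectangular region of interest, the map
   is rounded to 0.1 °C, min-shifted and scaled to non-negative integer
   levels (one level = 0.1 °C). Nine statistics are extracted in fixed
   order: mean and population variance of the raw temperatures,
   skewness (m₃/m₂^{3/2}), Pearson kurtosis (m₄/m₂²), Shannon entropy
   in bits, and four statistics of the gray-level co-occurrence matrix
   at a horizontal offset of 20 px — contrast Σ(i−j)²p(i,j),
   homogeneity Σp(i,j)/(1+|i−j|), energy Σp(i,j)², and correlation
   Σ(i−μ_r)(j−μ_c)p(i,j)/(σ_r σ_c).
2. **t-SNE, from its defining equations.** Gaussian conditionals
   p_{j|i} = exp(−‖x_i−x_j‖²/2σ_i²) / Σ_{k≠i} exp(−‖x_i−x_k‖²/2σ_i²)
   with σ_i found by bisection against a target perplexity,
   symmetrized as p_ij = (p_{i|j}+p_{j|i})/2N; Student-t similarities
   q_ij = (1+‖y_i−y_j‖²)^{−1} normalized over all pairs; coordinates
   y_i ∈ ℝ² found by gradient descent on C = KL(P‖Q).
3. **k-means (k = 2)** on the embedding, Lloyd iterations until the
   partition stabilizes, best of several seeded initializations.
4. **Detection rate**: the fraction of mice whose cluster matches their
   true group under the best cluster-to-label permutation. Feature sets
   of consecutive weeks are concatenated per mouse (week 2 alone → 9
   dimensions, weeks 2–3 → 18, …), so the call sharpens as the disease
   progresses.

Because the underlying animal images are not publicly deposited, the
package ships a first-class synthetic cohort generator
(`thermoliver.synthetic`) that reproduces the statistical structure the
analysis relies on — correlated Gaussian heterogeneity fields whose
amplitude and correlation length differ by group — so the whole
pipeline is testable end to end. A per-feature exact Mann–Whitney test
(`compare_groups`) covers the group-comparison analysis.

## Worked example

```python
from thermoliver import (EmbeddingConfig, SyntheticCohortSpec, concatenate_weeks,
                         detection_rate, kmeans, simulate_weekly_tables, tsne)

spec = SyntheticCohortSpec(seed=7)           # 5 control + 5 diseased mice, weeks 2-5
tables = simulate_weekly_tables(spec)        # nine features per mouse per week
X, mouse_ids, groups = concatenate_weeks(tables, through_week=3)   # 10 × 18
emb = tsne(X, EmbeddingConfig(seed=7))
assignments, centroids, _ = kmeans(emb.coords, k=2, seed=7)
res = detection_rate(assignments, groups)
print(res.n_correct, res.detection_rate)     # -> 10 1.0
```

Running `python examples/04_weekly_detection.py` prints

```
week 2: 10/10 mice correct (rate 1.00, 9-dim input)
week 3: 10/10 mice correct (rate 1.00, 18-dim input)
week 4: 10/10 mice correct (rate 1.00, 27-dim input)
week 5: 10/10 mice correct (rate 1.00, 36-dim input)
```

i.e. on a strong-effect synthetic cohort the unsupervised pipeline
recovers every mouse's disease status from thermography alone. The
other scripts in `examples/` walk through cohort simulation, feature
extraction (e.g. seed-7 week-3 maps give variance 0.10 °C² for a
control vs 0.54 °C² for a diseased mouse, entropy 3.69 vs 4.89 bits,
homogeneity 0.35 vs 0.19), and the exact rank-sum group comparison
(p = 0.0079 = 2/252 for fully separated features at n = 5 + 5).

A thin CLI mirrors the library:

```sh
thermoliver simulate --out cohort --seed 7
thermoliver features --images cohort/manifest.csv --out features.csv
thermoliver cluster  --features features.csv --weeks 2..5 --seed 7 --out result.json
thermoliver run      --manifest cohort/manifest.csv --weeks 2..5 --seed 7 --out out/
thermoliver compare  --features features.csv --week 5
thermoliver figures  --report out/report.json --out figs/
```

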