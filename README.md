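# worktraj

Typologies of lifetime employment trajectories and their association with a
binary health outcome — a sequence-analysis pipeline for life-course
epidemiology.

Retrospective life-calendar surveys record one employment state per year of
a respondent's life (full-time, part-time, self-employed, unemployed,
home/family, retired, in education, other). `worktraj` turns such data into
a typology of working lives and asks whether trajectory type predicts an
ever-diagnosed outcome such as cancer:

1. **Sequences** — align each subject's states to ages [16, 65), a 49-state
   sequence; drop incomplete histories.
2. **Dissimilarity** — pairwise Hamming distance, d(x, y) = #{t : x_t ≠ y_t},
   timing-sensitive because no shifting is allowed.
3. **Clustering** — deterministic PAM (partitioning around medoids) on the
   distance matrix; the number of trajectory types k maximizes the Average
   Silhouette Width, ASW = mean over subjects of
   s(i) = (b(i) − a(i)) / max(a(i), b(i)).
4. **Typology** — chronograms (state distribution by age per cluster),
   modal state paths, composition tables.
5. **Association** — logistic regression of the outcome on trajectory-type
   indicators versus a reference type, adjusted for baseline age, birth
   cohort (war / Great Depression / no crisis), BMI, smoking, chronic
   conditions, physical activity and attrition; odds ratios with 95% Wald
   CIs, OR_j = exp(β_j).

Because the harmonized life-history surveys this mirrors are
access-restricted, a synthetic-cohort generator (trajectory templates +
state noise + a known logistic outcome model) makes every stage runnable
and testable without any download. It is intended for epidemiologists and
social scientists prototyping sequence-analysis studies, and as a tested
reference implementation of the Hamming → PAM → ASW → logistic pipeline.

## Worked example

Generate a women-like cohort of 8 trajectory types (400 subjects per type,
5% state noise) in which the "Mainly full-time" type carries a true odds
ratio of 1.7 for the outcome, then run the full pipeline:

```python
import numpy as np
import pandas as pd
from worktraj import (SyntheticConfig, generate_panel, generate_covariates,
                      generate_outcomes, hamming_matrix, select_k,
                      fit_trajectory_outcome_model, make_association_table)

cfg = SyntheticConfig.default("female", n_per_cluster=400, noise_rate=0.05, seed=7)
cfg.outcome_model["log_or_cluster"]["Mainly full-time"] = np.log(1.7)
panel, true_labels = generate_panel(cfg)

D = hamming_matrix(panel)
best, profile = select_k(D, k_min=2, k_max=10)
print(f"selected k = {best.k}, ASW = {best.asw:.3f}")

covariates = generate_covariates(true_labels, cfg)
outcome = generate_outcomes(true_labels, covariates, cfg)
result = fit_trajectory_outcome_model(
    outcome, true_labels.reset_index(drop=True), covariates,
    reference="Mainly home/family",
)
print(make_association_table(result).to_string(index=False))
```

Output:

```
selected k = 8, ASW = 0.837
                           trajectory       OR (95%CI)
                   Mainly home/family             Ref.
Full-time or home/family to part time 0.98 (0.64–1.50)
             Home/family to full-time 0.86 (0.56–1.33)
                     Mainly full-time 1.75 (1.19–2.57)
      Mainly full-time to home/family 1.05 (0.69–1.59)
               Mainly self-employment 1.12 (0.74–1.70)
                  Mainly unemployment 0.83 (0.53–1.28)
                                Other 0.79 (0.51–1.23)
```

The ASW-driven search recovers the 8 generating types; the adjusted OR for
"Mainly full-time" (1.75, CI 1.19–2.57) recovers the configured 1.7, and
the types generated with no effect sit near 1 with CIs covering it.

## Command line

The same pipeline is scriptable from a YAML config:

```bash
worktraj simulate  --config config.yaml   # cohort CSVs + manifest
worktraj cluster   --config config.yaml   # ASW profile, assignments, chronograms
worktraj associate --config config.yaml   # Table of ORs vs the reference
worktraj report    --config config.yaml   # one-page markdown summary
```

```yaml
# config.yaml
seed: 11
outdir: out/
simulate: {gender: female, n_per_cluster: 200, noise_rate: 0.05}
k_range: [2, 10]
reference: Mainly home/family
```

`cluster` also accepts real data: point `input.panel` at a wide CSV
(`subject_id, gender, birth_year, age_16 … age_64`); `associate` reads a
coded covariate CSV and a binary outcome CSV (with an optional cancer-site
column, filterable via `--site`).

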