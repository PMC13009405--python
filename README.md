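# discourselsm

Scoring and lesion-symptom mapping of spoken discourse in post-stroke
aphasia.

Assessing how informative a person's connected speech is usually means
transcribing a picture-description sample and hand-coding every word —
the Correct Information Unit (CIU) protocol takes up to an hour per
minute of speech. **Content Word Fluency (CWF)** is a transcription-less
alternative: a rater ticks a pre-specified checklist of target words
(any inflection, listed synonyms, re-use in later phrases; immediate
repetitions and perseverations excluded) while the person speaks. This
package implements both measures, the psychometrics used to validate
the checklist, and the lesion analytics used to ask whether the two
measures share a neural basis:

- `discourselsm.transcripts` — deterministic, auditable CWF scoring
  (rule-table lemmatizer, synonym matching, repetition/perseveration
  exclusions) and flag-driven CIU counting; TSV and CHAT-lite readers.
- `discourselsm.irt` — 1PL/2PL/3PL item-response models by EM marginal
  maximum likelihood (Gauss–Hermite quadrature), likelihood-ratio model
  comparison, the limited-information **M2** goodness-of-fit statistic,
  and Wright (item–person) map tables. With k items the 1PL uses
  k + 1 parameters (k difficulties + one common slope), so at k = 17:
  LRT df = 16 (vs 2PL) and 33 (vs 3PL), M2 df = 17·18/2 − 18 = 135.
- `discourselsm.stats` — Pearson and partial correlation (residualize
  on covariates, df = n − 2 − q), pooled-variance t-test
  (df = n_a + n_b − 2), and the psycholinguistic OLS regression of
  summed item production on word class, length, frequency and
  imageability.
- `discourselsm.lesionmap` — ≥10 % lesion-coverage filter, lesion-size
  residualization, sparse canonical-correlation lesion-symptom mapping
  (hard-sparsity projection, 4-fold cross-validated correlation,
  negative-weight display), streamline disconnection maps (voxel-wise
  disconnected-streamline fraction, binarized at 50 %), tract lesion
  percentages |lesion ∩ tract| / |tract| with partial correlations, and
  the AIC-based predictive validity comparison (difference > 100 ⇒ two
  distinct maps).
- `discourselsm.synthdata` — a synthetic-cohort generator (Rasch item
  production, lesion blobs whose load in a critical region depresses
  ability, tract atlas, streamline template) so the whole pipeline is
  testable without any data download.
- `discourselsm.pipeline` — one-config orchestration of all stages with
  a manifest for byte-identical re-runs; `discourselsm.cli` exposes
  `discourse-lsm simulate|score|irt|lsm|disconnect|tracts|pvc|run`.

## Worked example

Run the full pipeline on a simulated 76-participant cohort:

```python
from discourselsm.pipeline import RunConfig, run_pipeline

report = run_pipeline(RunConfig(simulate={"n_participants": 76},
                                out_dir="demo_out", seed=11))
```

Selected numbers this run prints (`demo_out/report.json`):

| quantity | value | meaning |
|---|---|---|
| r(CWF, #CIU) | 0.93 (p < 1e-30) | checklist score tracks hand-coded informativeness |
| t(anomic vs Broca), df | 8.1, 56 | fluent subtypes produce more content words |
| 1PL vs 2PL LRT | χ²(21) = 21.8, p = 0.41 | common-slope Rasch model suffices |
| M2 | 267.1, df = 230, p = 0.05 | Rasch model not rejected at α = .05 |
| voxel LSM CV correlation | 0.04 (p = 0.37) | binary-mask LSM finds no reliable map |
| disconnection LSM CV corr. | 0.27 (p = 0.01) | disconnection map predicts CWF out of fold |
| PVC AIC difference | −834 → `single_map` | CWF and #CIU share one lesion map |
| FAT partial r (CWF) | −0.35 | the tract routed through the critical region |

The qualitative pattern — behavioural convergence of the two measures, a
Rasch-consistent checklist, no significant voxel-lesion map but a
significant disconnection map, one shared map for both measures, and a
frontal-tract association — is the structure the generator is built to
emulate.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's acceptance quantities from scratch: it
simulates a 17-item dichotomous production cohort, fits the
one-parameter logistic model by EM, computes the limited-information M2
statistic, and reports the degrees of freedom the M2 operation derives,
writing `{"t1": {"value": ..., "n": ...}}` to the requested path.
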