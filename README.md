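# neuroscore

Scalar neural scores of concept knowledge computed from item-level fMRI
activity patterns, exercised end to end on synthetic cohorts with planted
category structure.

Three per-subject, per-run scores are implemented:

- **Informational-network score** (primary): a whole-brain searchlight
  computes a 24-item dissimilarity matrix (DM) at every location; DMs whose
  centers fall inside the top-2% univariate activation mask are grouped by
  multiscale-bootstrap hierarchical clustering (approximately-unbiased
  cluster p-values) into statistically reliable *informational networks*;
  each network's average DM is embedded in 2-D by classical MDS and decoded
  with a radial-kernel SVM against 3-way category labels; the score is the
  best network's decoding accuracy.
- **Searchlight-RSA score**: mean Fisher-z Spearman agreement between local
  DMs and an expert dissimilarity model over locations with z ≥ 2 (subjects
  with no surviving location are flagged dropped).
- **Univariate score**: mean contrast z over the top-2% positive-z voxels.

A statistical validation layer (Welch t-tests, linear mixed-effects models
with crossed random intercepts for subject and test type, likelihood-ratio
model comparisons), a group localization utility and a seeded synthetic-fMRI
simulator round out the pipeline. The simulator plants task-active blobs,
informational blobs whose item patterns encode category structure scaled by
a latent per-subject expertise `e ∈ [0, 1]`, an orthogonal visual-similarity
dimension crossing the categories, and behavioral accuracies correlated
with `e` — so every downstream stage is testable without any data download.

## Package layout

| module | contents |
| --- | --- |
| `neuroscore.dissim` | condensed DM data model, correlation distances, Spearman DM similarity, Fisher z, DM averaging, synthetic expert model, TSV I/O |
| `neuroscore.synthdata` | cohort simulator, random responder, HRF forward model for time series |
| `neuroscore.firstlevel` | item-level GLM (OLS), contrast z-maps, robust-range mask |
| `neuroscore.searchlight` | spherical in-mask neighborhoods, per-center DMs |
| `neuroscore.netclust` | average-linkage clustering of DM stacks, multiscale-bootstrap AU p-values, network cutting |
| `neuroscore.scoring` | the three neural scores, classical/nonmetric MDS, radial-SVM decoding |
| `neuroscore.validation` | Welch t, mixed models, likelihood-ratio comparisons |
| `neuroscore.localize` | group localization maps, standard-mesh vertex arithmetic |
| `neuroscore.pipeline` / `neuroscore.cli` | config, orchestration, CLI |

## CLI

```bash
# full pipeline: simulate -> score -> validate -> localize
neuroscore run --seed 1 --out results/demo

# stage by stage
neuroscore simulate --seed 1 --out results/cohort
neuroscore score --method all \
    --betas results/cohort/betas \
    --mask results/cohort/brain_mask.nii.gz \
    --expert results/cohort/expert_dm.tsv \
    --categories results/cohort/expert_categories.tsv \
    --out results/scores.tsv
neuroscore validate --scores results/scores.tsv \
    --behavior results/cohort/behavior.tsv --out results/validation.json
neuroscore localize --contributing contributing.json \
    --groups results/cohort/ground_truth_expertise.tsv \
    --mask results/cohort/brain_mask.nii.gz --out results/loc
```

All commands accept `--config <json>` (schema-checked; unknown keys
rejected); every artifact directory gets a provenance block with the config
hash and package version. Results are deterministic under the config seed
(per-subject bootstrap seeds are derived from it).

## Tests

```bash
python -m pytest tests/            # unit + property + acceptance (~2.5 min)
```

`tests/test_acceptance.py` holds the end-to-end criteria (oracle equivalence
of searchlight DMs, AU-clustering recovery of planted partitions, expertise
recovery and the univariate/infonet method dissociation on simulated
cohorts, statistical calibration of the tests).

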