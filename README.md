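# oudtraj

Opioid use disorder (OUD) rarely follows a single arc: people move from
first exposure into disorder, from disorder into remission, and too often
from remission back into relapse. `oudtraj` is a toolkit for modelling those
three transitions from longitudinal concept-event streams (EHR-style coded
conditions, drug exposures, survey responses) and for turning genetic
evidence about OUD into a ranked list of candidate therapies. It is aimed at
biostatisticians and computational epidemiologists who work with
OMOP-flavoured extracts and want a reproducible, testable pipeline they can
exercise end-to-end on synthetic data before touching protected records.

## What it computes

**Multi-stage survival pipeline.** For each person the package derives three
time-to-event records with end-of-data censoring — onset (cohort entry to
first qualifying OUD event), remission (last OUD event to a remission code)
and relapse (remission to the next OUD event). Every concept contributes
five time-indexed features evaluated at risk-set time *t* on a start–stop
(counting-process) layout: counts in the trailing 30/90/365-day windows
(`cnt_30d`, `cnt_90d`, `cnt_365d`), the cumulative count (`cum`), and days
since the last occurrence (`days_since_last`); count features enter the
model as log(1 + count). Each transition is fit with an L1-penalized Cox
proportional-hazards model on the counting-process partial likelihood
(Breslow ties), the penalty chosen by K-fold cross-validation over persons.
Fits are repeated over data shards and aggregated into each feature's
selection frequency and mean hazard ratio HR = exp(β) among selecting runs;
features are prioritized by (frequency, |ln HR|). A compact summary-feature
analysis refits an unpenalized model and reports HR, Wald 95% CI, and
Benjamini–Hochberg FDR-adjusted q-values.

**Therapy knowledge graph.** A directed weighted graph over
{OUD} ∪ genes ∪ pathways ∪ drugs. Disease→gene weights come from a
piecewise evidence score a_g (replication count 0.5 + 0.3·r; cross-ancestry
flag 1.0; OUD-only flag 0.8; MTAG flag 0.5; fine-mapping posterior
0.2 + posterior; p-rank ln(3 + rank/e); else a small floor ε), capped at
c_max. Pathways holding ≥ m_min seed genes bridge their other members with
a γ-penalized bonus b_p = γ·Σ w_direct / |M_p|. Gene→drug weights combine a
clipped pChEMBL potency term with fixed increments for mechanism
(antagonist +0.2, agonist +0.1) and development status (phase ≥ 3 +0.3,
approved +0.7, BBB-permeable +0.2, research-only −0.5). After row
normalization, drugs are ranked by Personalized PageRank
r = αPᵀr + (1−α)s with restarts on the OUD node, and the output table
carries supporting genes (direct / bridged / non-seed), bridging pathways
and key annotations, with optional merging of ingredient-versus-salt
aliases.

**Synthetic cohorts.** `oudtraj.simulate` generates sparse, irregular event
streams (person-level gamma frailty × block-wise log-normal intensity) and
draws the three transitions from proportional-hazards models with *known
planted coefficients* on exactly the windowed features the pipeline
computes — so parameter recovery, null behaviour and the whole ranking
stack are testable without any data access agreement.

## Worked example

```python
from oudtraj.simulate import SimConfig, simulate_cohort_events, OUD_CONCEPT, REMISSION_CONCEPT
from oudtraj.phenotyping import derive_transitions
from oudtraj.features import FeatureSpec, build_design
from oudtraj.survival import (fit_penalized_cox_shard, aggregate_shards,
                              prioritize_features, shard_persons)

cfg = SimConfig(n_persons=1000, seed=3)      # plants +1.0 on cond1_cnt_30d for onset
events, truth = simulate_cohort_events(cfg)
recs = derive_transitions(events, {OUD_CONCEPT}, {REMISSION_CONCEPT}, end_of_data=730)
print(recs.groupby("transition")["event"].agg(["count", "sum"]))
#             count  sum
# transition
# onset         997  318
# relapse       169   75
# remission     317  169

onset = recs[recs.transition == "onset"]
predictors = events[~events.concept_id.isin({OUD_CONCEPT, REMISSION_CONCEPT})]
design = build_design(predictors, onset, FeatureSpec(horizon_days=730))
results = [
    fit_penalized_cox_shard(design[design.person_id.isin(p)], K=5, seed=i,
                            transition="onset", shard_id=i)
    for i, p in enumerate(shard_persons(onset.person_id.unique(), 2, seed=0))
]
print(prioritize_features(aggregate_shards(results), min_frequency=0.5, top_n=5))
#        feature  selection_count  n_shards  mean_HR
#  cond1_cnt_30d                1         2 1.832957
# noise4_cnt_90d                1         2 1.158501
```

The planted 30-day condition-count feature tops the aggregation with a mean
hazard ratio of 1.83 per log(1 + count) unit (true value e^1·attenuation
toward 2.7 at full selection; a 500-person shard selects it in one of two
shards here — at n=2000 it is selected in ≥ 90% of replicates, which is
what the acceptance suite verifies). The same flow drives the CLI:

```bash
oudtraj all --out-dir run/ --seed 2 --n-persons 1000
oudtraj kg --gene-evidence run/gene_evidence.tsv --pathways run/pathways.gmt \
           --drug-targets run/drug_targets.tsv --out run/ranked_drugs.tsv --alias-mode merge
head -4 run/ranked_drugs.tsv
# rank  drug_id  drug_name  score      supporting_genes  gene_labels  supporting_pathways  approved  bbb
# 1     D1       drug1      0.0490503  G7                direct                            1         0
# 2     D3       drug3      0.0404756  G1                direct                            1         1
# 3     D7       drug7      0.0270052  G8                direct                            0         1
```

Scores are the drugs' Personalized-PageRank mass (they sum, with gene and
disease mass, to 1); the `supporting_genes` / `gene_labels` columns say
through which gene each drug connects to OUD and whether that gene carries
direct evidence or was pathway-bridged. Every run writes a `manifest.json`
with SHA-256 hashes of all outputs; identical config + seed reproduces
identical hashes.

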