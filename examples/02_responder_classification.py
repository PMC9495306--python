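"""Stratify patients into treatment Responders / Non-Responders.

Five binary patient-vs-control classifiers (2 SVMs + 3 one-nearest-neighbour
models) are trained on baseline clinical features z-scored across the pooled
sample.  Each patient's post-treatment feature vector — normalized with the
frozen baseline parameters — is then voted on: a majority of "control" votes
means the patient's symptom profile has moved into the healthy range, i.e.
they responded to treatment.
"""

from sklearn.metrics import balanced_accuracy_score

from strata_ifc import CohortSpec, classify_m2, generate_clinical, train_ensemble

# Synthetic cohort at the study's published conditions: 50 controls, 53
# patients (36 true Responders reverting fully to control-level symptoms at
# follow-up, 17 Non-Responders reverting only 20%).
cohort = generate_clinical(CohortSpec(rng_seed=20))
m1 = cohort[cohort.timepoint == "M1"]
m2 = cohort[(cohort.timepoint == "M2") & (cohort.group == "patient")]

ensemble = train_ensemble(m1)
labels = classify_m2(ensemble, m2)

counts = labels.final.value_counts()
print(f"predicted: {counts.get('Responder', 0)} Responders, "
      f"{counts.get('NonResponder', 0)} Non-Responders")

truth = m2.set_index("subject_id")["subgroup_truth"]
bacc = balanced_accuracy_score(truth.loc[labels.final.index], labels.final)
print(f"balanced accuracy vs ground truth: {bacc:.3f}")
# With feature separations this large (d ~ 1.4-3.6) the majority vote
# recovers the planted subgroups essentially perfectly (>= 0.85 expected).

print("\nvote breakdown (first 5 patients):")
print(labels.votes.head().to_string(index=False))
# Each row shows the five member votes; >= 3 "control" votes -> Responder.
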