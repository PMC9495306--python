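"""Screen for group-different connectivity, then test treatment normalization.

Stage 1 compares baseline connectivity maps between controls and all patients
(one-tailed pooled t at alpha = 0.001, extent threshold k = 5) to find
hypoconnected regions.  Stage 2, inside those regions only, requires BOTH a
Group-x-Time interaction (Responders' change exceeds Non-Responders') AND a
significant within-Responder increase — the minimum-t conjunction — with
Bonferroni FWE correction over the small search volume.
"""

import numpy as np

from strata_ifc import (
    CohortSpec,
    TimeSeriesSpec,
    generate_clinical,
    generate_timeseries,
    medication_effect,
    screen_group_difference,
    seed_to_voxel_map,
    summarize_effect,
)

cohort = generate_clinical(CohortSpec(rng_seed=1))
spec = TimeSeriesSpec(rng_seed=2)  # r: controls 0.5, patients 0.1, Responders normalize at M2
ts = generate_timeseries(spec, cohort)
zmaps = {k: seed_to_voxel_map(v, ts.seed_mask).z for k, v in ts.data.items()}

m1 = cohort[cohort.timepoint == "M1"]
hc = [zmaps[(s, "M1")] for s in m1.loc[m1.group == "control", "subject_id"]]
pat = m1[m1.group == "patient"]
pat_m1 = [zmaps[(s, "M1")] for s in pat.subject_id]

mask = screen_group_difference(hc, pat_m1, direction="hypo", alpha=0.001, extent_k=5)
planted = ts.effect_mask
print(f"screening: {mask.n_voxels} hypoconnected voxels "
      f"({(mask.mask & planted).sum()}/{planted.sum()} of the planted region)")

truth = pat.set_index("subject_id")["subgroup_truth"]
resp = [s for s in pat.subject_id if truth[s] == "Responder"]
nonresp = [s for s in pat.subject_id if truth[s] == "NonResponder"]
result = medication_effect(
    [zmaps[(s, "M1")] for s in resp], [zmaps[(s, "M2")] for s in resp],
    [zmaps[(s, "M1")] for s in nonresp], [zmaps[(s, "M2")] for s in nonresp],
    mask,
)
print("\nconjunction clusters (FWE p < 0.05 within the search volume):")
print(result.cluster_table().to_string(index=False))
# Expect one cluster covering the planted region: the minimum-t statistic is
# significant only where the interaction AND the Responder increase both hold.

cells = {
    ("HC", "M1"): hc,
    ("Responder", "M1"): [zmaps[(s, "M1")] for s in resp],
    ("Responder", "M2"): [zmaps[(s, "M2")] for s in resp],
    ("NonResponder", "M1"): [zmaps[(s, "M1")] for s in nonresp],
    ("NonResponder", "M2"): [zmaps[(s, "M2")] for s in nonresp],
}
print("\nmean Fisher z over significant voxels (bar-chart table):")
print(summarize_effect(result, cells).round(3).to_string(index=False))
# Responders' M2 mean approaches the control level (~atanh(0.5) = 0.55)
# while Non-Responders stay at their baseline (~atanh(0.1) = 0.10):
# connectivity "normalizes" only in the treatment-responsive subgroup.
assert np.isfinite(result.t_conjunction[result.mask]).all()
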