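"""Denoise a synthetic resting-state run and map seed-to-voxel connectivity.

A toy 4D run is simulated in which an 8-voxel seed region and a 30-voxel
effect region share a latent signal tuned to a seed-effect correlation of
0.5.  The run is cleaned (linear detrend + 0.008-0.09 Hz band-pass at
TR = 2.4 s) and correlated against the seed-mean time course; the map holds
Fisher-z values z = atanh(r).
"""

import numpy as np
import pandas as pd

from strata_ifc import DenoiseConfig, TimeSeriesSpec, denoise, generate_timeseries, seed_to_voxel_map

cohort = pd.DataFrame(
    {"subject_id": ["s0"], "group": "control", "subgroup_truth": "", "timepoint": "M1"}
)
spec = TimeSeriesSpec(r_hc=0.5, rng_seed=5)  # 12x12x8 grid, 180 volumes, TR 2.4 s
ts = generate_timeseries(spec, cohort)
run = ts.data[("s0", "M1")]

clean = denoise(run, DenoiseConfig(), confounds=None, tr=spec.tr)
cm = seed_to_voxel_map(clean, ts.seed_mask, subject_id="s0", timepoint="M1")

z_effect = cm.z[ts.effect_mask].mean()
z_background = cm.z[~(ts.seed_mask | ts.effect_mask)].mean()
print(f"mean Fisher z in effect region:     {z_effect:.3f}  (target atanh(0.5) = {np.arctanh(0.5):.3f})")
print(f"mean Fisher z elsewhere:            {z_background:.3f}  (no shared signal -> ~0)")
print(f"degenerate voxels flagged:          {int(cm.flags.sum())}")
# The effect-region z sits near atanh(0.5) ~ 0.55 while background voxels
# hover around zero — the connectivity signal survives the denoising chain.
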