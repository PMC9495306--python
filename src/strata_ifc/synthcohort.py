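"""Synthetic clinical cohorts and toy resting-state datasets.

The study this pipeline targets — stimulant-naive adult ADHD patients scanned
before (M1) and after (M2) six weeks of methylphenidate, plus healthy controls
scanned once — cannot share its data.  This module generates cohorts with the
statistical structure the downstream analysis assumes, so every stage is
testable end to end without a download:

* clinical feature tables whose group means/SDs default to the published
  baseline characteristics of the 53-patient / 50-control sample, with a
  patient subgroup ("Responders", 36 by default) whose M2 features revert
  toward control levels;
* per-subject 4D voxel time series in which a seed region and an effect region
  share a latent signal mixed so the expected seed-mean-to-effect-voxel
  correlation hits a group/timepoint target — lower in patients than controls
  at baseline, rising back to control levels at M2 only in Responders.

Both generators are deterministic given their ``rng_seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from strata_ifc.clinstats import FEATURE_COLUMNS

__all__ = [
    "CohortSpec",
    "TimeSeriesSpec",
    "CohortTimeSeries",
    "generate_clinical",
    "generate_timeseries",
    "DEFAULT_FEATURE_PARAMS",
]

#: Default per-feature (mean_hc, sd_hc, mean_pat, sd_pat) at baseline:
#: DSM-IV symptom counts and CAARS DSM subscale scores for healthy controls
#: (n=50) and adult ADHD patients (n=53).
DEFAULT_FEATURE_PARAMS: dict[str, tuple[float, float, float, float]] = {
    "DSM_IV_A1": (0.22, 0.51, 7.01, 1.25),
    "DSM_IV_A2": (0.32, 0.77, 4.74, 2.49),
    "CAARS_DSM_IA_S": (5.24, 3.41, 19.11, 4.18),
    "CAARS_DSM_HYI_S": (4.72, 3.29, 14.72, 5.89),
    "CAARS_DSM_ADHD_S": (9.96, 5.84, 33.60, 8.50),
    "CAARS_DSM_IA_O": (4.58, 3.55, 16.79, 5.07),
    "CAARS_DSM_HYI_O": (4.70, 3.97, 12.23, 6.32),
    "CAARS_DSM_ADHD_O": (9.28, 6.56, 29.00, 9.33),
}


@dataclass
class CohortSpec:
    """Design of a synthetic clinical cohort.

    ``reversion`` maps subgroup name -> how far that subgroup's M2 feature
    means move from the patient mean toward the control mean (1 = full
    normalization, 0 = no change).  ``feature_correlation`` adds a common
    subject factor across features (CAARS subscales correlate in reality);
    0 keeps features independent.
    """

    n_hc: int = 50
    n_patients: int = 53
    responder_fraction: float = 36 / 53
    feature_params: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_FEATURE_PARAMS)
    )
    reversion: dict[str, float] = field(
        default_factory=lambda: {"Responder": 1.0, "NonResponder": 0.2}
    )
    feature_correlation: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hc < 2:
            raise ValueError(f"n_hc must be >= 2, got {self.n_hc}")
        if self.n_patients < 2:
            raise ValueError(f"n_patients must be >= 2, got {self.n_patients}")
        if not (0.0 <= self.responder_fraction <= 1.0):
            raise ValueError(f"responder_fraction must lie in [0,1], got {self.responder_fraction}")
        for name, (mh, sh, mp, sp) in self.feature_params.items():
            if sh < 0 or sp < 0:
                raise ValueError(f"feature_params[{name!r}]: SDs must be nonnegative")
        for name, rho in self.reversion.items():
            if not (0.0 <= rho <= 1.0):
                raise ValueError(f"reversion[{name!r}] must lie in [0,1], got {rho}")
        if not (0.0 <= self.feature_correlation < 1.0):
            raise ValueError("feature_correlation must lie in [0,1)")

    @property
    def n_responders(self) -> int:
        return int(round(self.responder_fraction * self.n_patients))


def generate_clinical(spec: CohortSpec) -> pd.DataFrame:
    """Generate a clinical feature table.

    Returns a long-format table with columns ``subject_id``, ``group``
    (control/patient), ``subgroup_truth`` (Responder/NonResponder for
    patients, empty for controls), ``timepoint`` (M1/M2) and the feature
    columns.  Controls appear at M1 only (scanned once by design); patients at
    M1 and M2.  M1 features are drawn from the group normal distributions; the
    M2 mean of a patient subgroup is ``mean_pat + reversion*(mean_hc -
    mean_pat)`` per feature, with the patient SD retained.
    """
    rng = np.random.default_rng(spec.rng_seed)
    features = list(spec.feature_params)
    n_resp = spec.n_responders
    subgroups = ["Responder"] * n_resp + ["NonResponder"] * (spec.n_patients - n_resp)

    def draw(n: int, means: np.ndarray, sds: np.ndarray) -> np.ndarray:
        k = len(features)
        rho = spec.feature_correlation
        common = rng.standard_normal((n, 1))
        unique = rng.standard_normal((n, k))
        z = np.sqrt(rho) * common + np.sqrt(1.0 - rho) * unique
        return means + sds * z

    hc_means = np.array([spec.feature_params[f][0] for f in features])
    hc_sds = np.array([spec.feature_params[f][1] for f in features])
    pat_means = np.array([spec.feature_params[f][2] for f in features])
    pat_sds = np.array([spec.feature_params[f][3] for f in features])

    rows: list[pd.DataFrame] = []

    hc = pd.DataFrame(draw(spec.n_hc, hc_means, hc_sds), columns=features)
    hc.insert(0, "subject_id", [f"hc{i:03d}" for i in range(spec.n_hc)])
    hc.insert(1, "group", "control")
    hc.insert(2, "subgroup_truth", "")
    hc.insert(3, "timepoint", "M1")
    rows.append(hc)

    pat_ids = [f"pat{i:03d}" for i in range(spec.n_patients)]
    m1 = pd.DataFrame(draw(spec.n_patients, pat_means, pat_sds), columns=features)
    m1.insert(0, "subject_id", pat_ids)
    m1.insert(1, "group", "patient")
    m1.insert(2, "subgroup_truth", subgroups)
    m1.insert(3, "timepoint", "M1")
    rows.append(m1)

    # M2: subgroup means revert toward the control means by the subgroup's
    # reversion fraction; draws are independent of M1 (no within-subject
    # autocorrelation is modelled).
    m2_vals = np.empty((spec.n_patients, len(features)))
    for sg in spec.reversion:
        idx = np.flatnonzero(np.array(subgroups) == sg)
        if idx.size == 0:
            continue
        rho = spec.reversion[sg]
        means_sg = pat_means + rho * (hc_means - pat_means)
        m2_vals[idx] = draw(idx.size, means_sg, pat_sds)
    m2 = pd.DataFrame(m2_vals, columns=features)
    m2.insert(0, "subject_id", pat_ids)
    m2.insert(1, "group", "patient")
    m2.insert(2, "subgroup_truth", subgroups)
    m2.insert(3, "timepoint", "M2")
    rows.append(m2)

    return pd.concat(rows, ignore_index=True)


def _as_bool_mask(mask, grid_shape: tuple[int, int, int]) -> np.ndarray:
    """Accept a boolean grid or a sequence of voxel indices; return a bool grid."""
    arr = np.asarray(mask)
    if arr.dtype == bool and arr.shape == tuple(grid_shape):
        return arr
    out = np.zeros(grid_shape, dtype=bool)
    arr = np.atleast_2d(arr)
    if arr.shape[-1] == 3 and arr.ndim == 2:
        out[tuple(arr.T)] = True
    else:
        out.flat[np.asarray(mask, dtype=int).ravel()] = True
    return out


def _default_seed_mask(grid_shape):
    m = np.zeros(grid_shape, dtype=bool)
    m[0:2, 0:2, 0:2] = True  # 8-voxel corner block
    return m


def _default_effect_mask(grid_shape):
    m = np.zeros(grid_shape, dtype=bool)
    x, y, z = grid_shape
    m[x // 2 : x // 2 + 5, y // 2 : y // 2 + 6, z // 2] = True  # 30-voxel slab
    return m


@dataclass
class TimeSeriesSpec:
    """Design of the toy resting-state dataset.

    Acquisition defaults mirror the emulated protocol: 180 volumes at
    TR = 2.4 s.  The four ``r_*`` fields are the target seed-mean-to-effect-
    voxel Pearson correlations per group/timepoint; the defaults plant baseline
    hypoconnectivity in patients (0.1 vs 0.5) with full normalization in
    Responders at M2 and none in Non-Responders.  Targets are calibrated at
    ``noise_sd = 1``.
    """

    n_volumes: int = 180
    tr: float = 2.4
    grid_shape: tuple[int, int, int] = (12, 12, 8)
    seed_mask: np.ndarray | None = None
    effect_mask: np.ndarray | None = None
    r_hc: float = 0.5
    r_pat_m1: float = 0.1
    r_resp_m2: float = 0.5
    r_nonresp_m2: float = 0.1
    noise_sd: float = 1.0
    drift_amplitude: float = 0.0
    seed_loading: float = 0.8
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_volumes < 20:
            raise ValueError(f"n_volumes must be >= 20, got {self.n_volumes}")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        if self.seed_mask is None:
            self.seed_mask = _default_seed_mask(self.grid_shape)
        else:
            self.seed_mask = _as_bool_mask(self.seed_mask, self.grid_shape)
        if self.effect_mask is None:
            self.effect_mask = _default_effect_mask(self.grid_shape)
        else:
            self.effect_mask = _as_bool_mask(self.effect_mask, self.grid_shape)
        if not self.seed_mask.any() or not self.effect_mask.any():
            raise ValueError("seed_mask and effect_mask must be non-empty")
        if (self.seed_mask & self.effect_mask).any():
            raise ValueError("seed_mask and effect_mask must be disjoint")
        for name in ("r_hc", "r_pat_m1", "r_resp_m2", "r_nonresp_m2"):
            if not abs(getattr(self, name)) < 1:
                raise ValueError(f"{name} must satisfy |r| < 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not (0 < self.seed_loading <= 1):
            raise ValueError("seed_loading must lie in (0,1]")

    def target_r(self, group: str, subgroup: str, timepoint: str) -> float:
        if group == "control":
            return self.r_hc
        if timepoint == "M1":
            return self.r_pat_m1
        return self.r_resp_m2 if subgroup == "Responder" else self.r_nonresp_m2


@dataclass
class CohortTimeSeries:
    """All simulated 4D runs of a cohort, keyed by (subject_id, timepoint)."""

    data: dict[tuple[str, str], np.ndarray]
    seed_mask: np.ndarray
    effect_mask: np.ndarray
    grid_shape: tuple[int, int, int]
    tr: float

    def write_nifti(self, out_dir: str | Path) -> list[Path]:
        """Write each run as ``<subject>_<timepoint>.nii`` with TR in pixdim[4],
        plus the two masks; returns the paths written."""
        import nibabel as nib

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        affine = np.eye(4)
        for (sid, tp), arr in self.data.items():
            img = nib.Nifti1Image(arr.astype(np.float32), affine)
            img.header["pixdim"][4] = self.tr
            img.header.set_xyzt_units(xyz="mm", t="sec")
            p = out_dir / f"{sid}_{tp}.nii"
            nib.save(img, p)
            paths.append(p)
        for name, mask in (("seed_mask", self.seed_mask), ("effect_mask", self.effect_mask)):
            p = out_dir / f"{name}.nii"
            nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), p)
            paths.append(p)
        return paths


def generate_timeseries(spec: TimeSeriesSpec, cohort: pd.DataFrame) -> CohortTimeSeries:
    """Simulate one 4D run per cohort row (subject x timepoint).

    Seed and effect voxels share a white latent signal L(t): a seed voxel is
    ``w_s*L + noise_sd*sqrt(1-w_s^2)*eps`` and an effect voxel
    ``w_e*L + noise_sd*sqrt(1-w_e^2)*eta`` with independent white noise per
    voxel.  With ``noise_sd = 1`` the correlation between the *seed mean* and
    an effect voxel is ``w_s*w_e / sqrt(w_s^2 + (1-w_s^2)/m)`` for an m-voxel
    seed, so ``w_e`` is solved in closed form from the group/timepoint target
    r.  Background voxels are white noise plus an optional linear drift.
    """
    seed = spec.seed_mask
    effect = spec.effect_mask
    m = int(seed.sum())
    w_s = spec.seed_loading
    # Correlation of the seed mean with the latent, accounting for averaging
    # of the per-voxel noise over the m seed voxels (at noise_sd = 1).
    c_seed = w_s / np.sqrt(w_s**2 + (1.0 - w_s**2) / m)

    rng = np.random.default_rng(spec.rng_seed)
    T = spec.n_volumes
    drift = spec.drift_amplitude * np.linspace(-0.5, 0.5, T)
    background = ~(seed | effect)

    data: dict[tuple[str, str], np.ndarray] = {}
    for row in cohort.itertuples(index=False):
        r_target = spec.target_r(row.group, row.subgroup_truth, row.timepoint)
        w_e = r_target / c_seed
        if not abs(w_e) < 1:
            raise ValueError(
                f"target r={r_target} unreachable with seed_loading={w_s} and {m} seed voxels"
            )
        latent = rng.standard_normal(T)
        arr = np.empty(spec.grid_shape + (T,))
        arr[background] = spec.noise_sd * rng.standard_normal((int(background.sum()), T)) + drift
        arr[seed] = w_s * latent + spec.noise_sd * np.sqrt(1 - w_s**2) * rng.standard_normal(
            (m, T)
        )
        n_eff = int(effect.sum())
        arr[effect] = w_e * latent + spec.noise_sd * np.sqrt(1 - w_e**2) * rng.standard_normal(
            (n_eff, T)
        )
        data[(row.subject_id, row.timepoint)] = arr
    return CohortTimeSeries(
        data=data,
        seed_mask=seed,
        effect_mask=effect,
        grid_shape=spec.grid_shape,
        tr=spec.tr,
    )
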