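"""Group inference: directed screening maps and conjunction of medication effects.

The inference logic runs in two stages.

**Screening** compares seed connectivity maps between healthy controls and the
entire patient group with a voxelwise pooled two-sample t-test, one-tailed per
direction (hypoconnectivity: controls > patients; hyperconnectivity: patients
> controls), at an unadjusted alpha (default 0.001, derived a priori from a
power analysis), plus a cluster extent threshold (default k = 5,
18-connectivity) to discard spurious voxels.  Surviving voxels define the
small search volume for stage two.

**Conjunction** tests, inside the screening mask, whether connectivity
normalizes under treatment specifically in Responders.  The 2x2
(Group x Time, Time within subject) factorial is expressed through change
scores Delta_i = z_M2 - z_M1: the interaction is a pooled two-sample t of
Responder vs Non-Responder Delta, the simple effect a one-sample t of
Responder Delta against zero, both signed toward normalization (for a
hypoconnectivity mask, positive = connectivity increases).  The conjunction
statistic is the minimum of the two t values, its uncorrected p the maximum
of the two one-tailed p values (conjunction null: both effects null).
Family-wise error across the mask is controlled by Bonferroni (default) or by
a permutation max-T null that simultaneously sign-flips change scores and
permutes subgroup labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from strata_ifc.ifc import ConnectivityMap

__all__ = [
    "ScreeningMask",
    "ClusterInfo",
    "ConjunctionResult",
    "screen_group_difference",
    "medication_effect",
    "summarize_effect",
]

# 18-neighbourhood in 3D: faces + edges, no corners.
_STRUCT_18 = ndimage.generate_binary_structure(3, 2)


def _stack(maps) -> np.ndarray:
    """Stack ConnectivityMaps or arrays into (n_subjects, x, y, z)."""
    arrs = [m.z if isinstance(m, ConnectivityMap) else np.asarray(m, dtype=float) for m in maps]
    shapes = {a.shape for a in arrs}
    if len(shapes) != 1:
        raise ValueError(f"grid mismatch across maps: {sorted(shapes)}")
    return np.stack(arrs)


def _pooled_two_sample_t(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, int]:
    """Voxelwise pooled two-sample t (a minus b) over axis 0; returns (t, df)."""
    n1, n2 = a.shape[0], b.shape[0]
    df = n1 + n2 - 2
    v1 = a.var(axis=0, ddof=1)
    v2 = b.var(axis=0, ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (a.mean(axis=0) - b.mean(axis=0)) / denom
    return np.where(np.isfinite(t), t, 0.0), df


def _one_sample_t(a: np.ndarray) -> tuple[np.ndarray, int]:
    n = a.shape[0]
    sd = a.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = a.mean(axis=0) / (sd / np.sqrt(n))
    return np.where(np.isfinite(t), t, 0.0), n - 1


@dataclass
class ScreeningMask:
    """Directed group-difference search volume for one seed."""

    direction: str  # "hyper" (patients > controls) or "hypo" (controls > patients)
    alpha: float
    extent_k: int
    mask: np.ndarray  # 3D bool, surviving voxels
    cluster_labels: np.ndarray  # 3D int, 0 outside clusters
    t_map: np.ndarray  # signed toward the tested direction
    df: int

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def n_clusters(self) -> int:
        return int(self.cluster_labels.max())


@dataclass
class ClusterInfo:
    """One FWE-significant conjunction cluster."""

    label: int
    extent: int
    peak_ijk: tuple[int, int, int]
    peak_t: float
    peak_z: float  # z-equivalent of the uncorrected conjunction p at the peak
    peak_p_fwe: float
    cohens_d: float


@dataclass
class ConjunctionResult:
    """Voxelwise conjunction statistics within the screening mask."""

    mask: np.ndarray  # 3D bool search volume
    t_interaction: np.ndarray  # 3D, NaN outside mask
    t_simple: np.ndarray
    t_conjunction: np.ndarray
    p_uncorrected: np.ndarray  # conjunction p = max of component one-tailed p
    p_fwe: np.ndarray
    clusters: list[ClusterInfo] = field(default_factory=list)
    fwe_method: str = "bonferroni"
    n_responders: int = 0
    n_nonresponders: int = 0
    empty_search_volume: bool = False

    @property
    def significant(self) -> np.ndarray:
        """3D bool of voxels with FWE-corrected p below the stored threshold."""
        return self._significant

    def cluster_table(self) -> pd.DataFrame:
        rows = [
            {
                "cluster": c.label,
                "x": c.peak_ijk[0],
                "y": c.peak_ijk[1],
                "z": c.peak_ijk[2],
                "z_value": c.peak_z,
                "p_fwe": c.peak_p_fwe,
                "extent": c.extent,
                "d": c.cohens_d,
            }
            for c in self.clusters
        ]
        return pd.DataFrame(
            rows, columns=["cluster", "x", "y", "z", "z_value", "p_fwe", "extent", "d"]
        )


def screen_group_difference(
    maps_hc,
    maps_adhd_m1,
    direction: str = "hypo",
    alpha: float = 0.001,
    extent_k: int = 5,
) -> ScreeningMask:
    """Directed voxelwise screen of controls vs the entire patient group.

    The pooled two-sample t is signed toward the tested direction (``hypo``:
    controls minus patients; ``hyper``: patients minus controls), thresholded
    at the one-tailed ``alpha``, and connected components (18-connectivity)
    smaller than ``extent_k`` voxels are removed.  Masks for opposite
    directions are disjoint by construction for alpha < 0.5.
    """
    if direction not in ("hyper", "hypo"):
        raise ValueError(f"direction must be 'hyper' or 'hypo', got {direction!r}")
    hc = _stack(maps_hc)
    pat = _stack(maps_adhd_m1)
    if hc.shape[1:] != pat.shape[1:]:
        raise ValueError(f"grid mismatch: {hc.shape[1:]} vs {pat.shape[1:]}")
    if hc.shape[0] < 2 or pat.shape[0] < 2:
        raise ValueError("need >= 2 subjects per group")
    if direction == "hypo":
        t, df = _pooled_two_sample_t(hc, pat)
    else:
        t, df = _pooled_two_sample_t(pat, hc)
    t_crit = stats.t.isf(alpha, df)
    above = t > t_crit

    labels, n = ndimage.label(above, structure=_STRUCT_18)
    if n:
        sizes = np.bincount(labels.ravel())
        small = np.flatnonzero(sizes < extent_k)
        keep = above & ~np.isin(labels, small[small > 0])
    else:
        keep = above
    labels, _ = ndimage.label(keep, structure=_STRUCT_18)
    return ScreeningMask(
        direction=direction,
        alpha=alpha,
        extent_k=extent_k,
        mask=keep,
        cluster_labels=labels,
        t_map=t,
        df=df,
    )


def medication_effect(
    maps_r_m1,
    maps_r_m2,
    maps_nr_m1,
    maps_nr_m2,
    mask: ScreeningMask,
    fwe_method: str = "bonferroni",
    fwe_alpha: float = 0.05,
    n_perm: int = 5000,
    rng_seed: int = 0,
) -> ConjunctionResult:
    """Conjunction test of treatment-specific normalization within the mask.

    Map lists must be subject-aligned between M1 and M2 within each subgroup
    (the i-th M1 map and i-th M2 map belong to the same subject).  Voxels with
    FWE-adjusted conjunction p below ``fwe_alpha`` are grouped into clusters
    with peak statistics and an effect size d derived from the interaction t.
    """
    if fwe_method not in ("bonferroni", "permutation"):
        raise ValueError(f"unknown fwe_method {fwe_method!r}")
    shape = mask.mask.shape
    if mask.n_voxels == 0:
        empty = np.full(shape, np.nan)
        res = ConjunctionResult(
            mask=mask.mask,
            t_interaction=empty,
            t_simple=empty.copy(),
            t_conjunction=empty.copy(),
            p_uncorrected=empty.copy(),
            p_fwe=empty.copy(),
            clusters=[],
            fwe_method=fwe_method,
            empty_search_volume=True,
        )
        res._significant = np.zeros(shape, dtype=bool)
        return res

    r1, r2 = _stack(maps_r_m1), _stack(maps_r_m2)
    n1_, n2_ = _stack(maps_nr_m1), _stack(maps_nr_m2)
    if r1.shape != r2.shape or n1_.shape != n2_.shape:
        raise ValueError("each subject needs both an M1 and an M2 map")
    for arr in (r1, n1_):
        if arr.shape[1:] != shape:
            raise ValueError("grid mismatch between maps and screening mask")

    sign = 1.0 if mask.direction == "hypo" else -1.0  # toward normalization
    vox = mask.mask
    d_r = sign * (r2 - r1)[:, vox]  # (n_R, m)
    d_nr = sign * (n2_ - n1_)[:, vox]
    n_r, n_nr = d_r.shape[0], d_nr.shape[0]
    m = vox.sum()

    t_int, df_int = _pooled_two_sample_t(d_r, d_nr)
    t_sim, df_sim = _one_sample_t(d_r)
    t_conj = np.minimum(t_int, t_sim)
    p_int = stats.t.sf(t_int, df_int)
    p_sim = stats.t.sf(t_sim, df_sim)
    p_unc = np.maximum(p_int, p_sim)

    if fwe_method == "bonferroni":
        p_fwe = np.minimum(1.0, m * p_unc)
    else:
        p_fwe = _permutation_max_t(d_r, d_nr, t_conj, n_perm, rng_seed)

    def grid(flat_vals, fill=np.nan):
        g = np.full(shape, fill)
        g[vox] = flat_vals
        return g

    sig_flat = p_fwe < fwe_alpha
    sig = np.zeros(shape, dtype=bool)
    sig[vox] = sig_flat

    clusters: list[ClusterInfo] = []
    labels, n_clust = ndimage.label(sig, structure=_STRUCT_18)
    t_conj_grid = grid(t_conj)
    t_int_grid = grid(t_int)
    p_unc_grid = grid(p_unc, fill=1.0)
    p_fwe_grid = grid(p_fwe, fill=1.0)
    for lab in range(1, n_clust + 1):
        members = labels == lab
        extent = int(members.sum())
        tc = np.where(members, t_conj_grid, -np.inf)
        peak = np.unravel_index(np.argmax(tc), shape)
        peak_p = float(p_unc_grid[peak])
        clusters.append(
            ClusterInfo(
                label=lab,
                extent=extent,
                peak_ijk=tuple(int(i) for i in peak),
                peak_t=float(t_conj_grid[peak]),
                peak_z=float(stats.norm.isf(max(peak_p, 1e-300))),
                peak_p_fwe=float(p_fwe_grid[peak]),
                cohens_d=float(t_int_grid[peak] * np.sqrt(1.0 / n_r + 1.0 / n_nr)),
            )
        )
    clusters.sort(key=lambda c: c.peak_t, reverse=True)

    res = ConjunctionResult(
        mask=vox,
        t_interaction=t_int_grid,
        t_simple=grid(t_sim),
        t_conjunction=t_conj_grid,
        p_uncorrected=p_unc_grid,
        p_fwe=p_fwe_grid,
        clusters=clusters,
        fwe_method=fwe_method,
        n_responders=n_r,
        n_nonresponders=n_nr,
    )
    res._significant = sig
    return res


def _permutation_max_t(
    d_r: np.ndarray, d_nr: np.ndarray, t_conj_obs: np.ndarray, n_perm: int, rng_seed: int
) -> np.ndarray:
    """max-T FWE p-values for the conjunction statistic.

    Each permutation enforces the full conjunction null: every subject's
    change-score vector is sign-flipped with probability 1/2 (null of no
    within-Responder change) and subgroup labels are permuted (null of no
    interaction), then the min-t map is recomputed and its maximum recorded.
    """
    rng = np.random.default_rng(rng_seed)
    all_d = np.concatenate([d_r, d_nr], axis=0)
    n = all_d.shape[0]
    n_r = d_r.shape[0]
    max_t = np.empty(n_perm)
    for b in range(n_perm):
        flips = rng.choice([-1.0, 1.0], size=n)[:, None]
        perm = rng.permutation(n)
        d = all_d[perm] * flips
        t_int, _ = _pooled_two_sample_t(d[:n_r], d[n_r:])
        t_sim, _ = _one_sample_t(d[:n_r])
        max_t[b] = np.minimum(t_int, t_sim).max()
    # Add-one estimator keeps p > 0.
    exceed = (max_t[None, :] >= t_conj_obs[:, None]).sum(axis=1)
    return (1.0 + exceed) / (1.0 + n_perm)


def summarize_effect(
    result: ConjunctionResult, maps_by_cell: dict[tuple[str, str], list]
) -> pd.DataFrame:
    """Mean and SEM of Fisher-z over the significant voxels, per group cell.

    ``maps_by_cell`` maps (group, timepoint) — e.g. ("Responder", "M1"),
    ("HC", "M1") — to that cell's connectivity maps.  Produces a
    bar-chart-ready table with one row per cell.
    """
    sig = result.significant
    if not sig.any():
        raise ValueError("no significant voxels to summarize")
    rows = []
    for (group, timepoint), maps in maps_by_cell.items():
        arr = _stack(maps)[:, sig]  # (n_subjects, n_sig_voxels)
        subject_means = arr.mean(axis=1)
        n = len(subject_means)
        rows.append(
            {
                "group": group,
                "timepoint": timepoint,
                "mean_z": float(subject_means.mean()),
                "sem_z": float(subject_means.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
                "n": n,
                "n_voxels": int(sig.sum()),
            }
        )
    return pd.DataFrame(rows)
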