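"""Post-preprocessing connectivity: denoising and seed-to-voxel Fisher-z maps.

Operates on already-preprocessed 4D data (realignment, normalization and
smoothing are upstream and out of scope).  The denoising chain follows the
anatomical-component (aCompCor) approach in a fixed order: nuisance
regression (principal components of noise-tissue signal, motion regressors,
one-hot outlier-scan indicators) -> linear detrend -> band-pass filter
(default 0.008-0.09 Hz).  The band-pass is a hard frequency-domain mask of
the real FFT: deterministic and exactly matching the stated band.

Connectivity is the Pearson correlation of the seed-mask mean time course
with every voxel, Fisher z-transformed (atanh) with r clamped to
+/-(1 - 1e-7) so maps stay finite; degenerate voxels are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "DenoiseConfig",
    "ConnectivityMap",
    "extract_noise_components",
    "regress_confounds",
    "denoise",
    "seed_to_voxel_map",
    "load_nifti_run",
    "R_CLAMP",
]

R_CLAMP = 1.0 - 1e-7


@dataclass
class DenoiseConfig:
    """Denoising parameters.

    ``band`` is the retained frequency interval in Hz; must satisfy
    0 <= low < high < Nyquist = 1/(2 TR).  ``confound_components`` names the
    nuisance sets and how many principal components each contributes
    (defaults mirror the aCompCor convention: 10 white-matter + 5 CSF
    components, 12 motion regressors, plus outlier-scan indicators).
    """

    band: tuple[float, float] = (0.008, 0.09)
    detrend: bool = True
    confound_components: dict[str, int] = field(
        default_factory=lambda: {"wm": 10, "csf": 5, "motion": 12}
    )

    def validate(self, tr: float) -> None:
        low, high = self.band
        nyquist = 1.0 / (2.0 * tr)
        if not (0.0 <= low < high < nyquist):
            raise ValueError(
                f"band {self.band} must satisfy 0 <= low < high < Nyquist={nyquist:.4f} Hz"
            )


@dataclass
class ConnectivityMap:
    """Fisher-z seed-to-voxel map for one subject/seed/timepoint."""

    subject_id: str
    seed_id: str
    timepoint: str
    z: np.ndarray  # 3D grid of Fisher-z values
    flags: np.ndarray  # 3D bool: degenerate voxels (zero variance or clamped r)

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.z.shape

    def write_nifti(self, path: str | Path, affine: np.ndarray | None = None) -> Path:
        import nibabel as nib

        img = nib.Nifti1Image(self.z.astype(np.float32), np.eye(4) if affine is None else affine)
        nib.save(img, path)
        return Path(path)


def _to_voxels_by_time(ts: np.ndarray) -> tuple[np.ndarray, tuple[int, ...]]:
    """Flatten an (x,y,z,t) or (voxels,t) array to (voxels, t)."""
    ts = np.asarray(ts, dtype=float)
    if ts.ndim == 2:
        return ts, (ts.shape[0],)
    if ts.ndim == 4:
        spatial = ts.shape[:3]
        return ts.reshape(-1, ts.shape[-1]), spatial
    raise ValueError(f"expected a (voxels,t) or (x,y,z,t) array, got ndim={ts.ndim}")


def extract_noise_components(ts: np.ndarray, noise_mask, n_components: int) -> np.ndarray:
    """Top principal-component time series of the signal under a noise mask.

    Each masked voxel's time series is mean-centered, and the singular value
    decomposition of the voxels-by-time submatrix yields the component time
    courses (rows of V^T, unit norm, mutually orthogonal), ordered by
    explained variance.  Returns an (n_components, t) array.
    """
    flat, spatial = _to_voxels_by_time(ts)
    mask = np.asarray(noise_mask, dtype=bool)
    if mask.shape == spatial:
        idx = np.flatnonzero(mask.ravel())
    else:
        idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ValueError("noise mask is empty")
    sub = flat[idx] - flat[idx].mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(sub, full_matrices=False)
    rank = int(np.sum(s > s[0] * max(sub.shape) * np.finfo(float).eps)) if s.size else 0
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds rank {rank} of masked data")
    return vt[:n_components]


def bandpass_mask_fft(ts: np.ndarray, low_hz: float, high_hz: float, tr: float) -> np.ndarray:
    """Band-pass by zeroing real-FFT bins outside [low_hz, high_hz]."""
    flat, spatial = _to_voxels_by_time(ts)
    T = flat.shape[-1]
    freqs = np.fft.rfftfreq(T, d=tr)
    keep = (freqs >= low_hz) & (freqs <= high_hz)
    spec = np.fft.rfft(flat, axis=-1)
    spec[:, ~keep] = 0.0
    out = np.fft.irfft(spec, n=T, axis=-1)
    return out.reshape(spatial + (T,)) if len(spatial) == 3 else out


def regress_confounds(ts: np.ndarray, confounds: np.ndarray | None) -> np.ndarray:
    """Per-voxel OLS residual against [intercept, confound columns].

    Residuals are exactly orthogonal to every retained confound column, and
    the operation is idempotent: re-regressing the same confounds changes
    nothing.  A rank-deficient confound matrix has its collinear columns
    dropped with a warning.
    """
    import warnings

    flat, spatial = _to_voxels_by_time(ts)
    T = flat.shape[-1]

    design_cols = [np.ones(T)]
    if confounds is not None and np.size(confounds) > 0:
        conf = np.atleast_2d(np.asarray(confounds, dtype=float))
        if conf.shape[0] != T:
            conf = conf.T
        if conf.shape[0] != T:
            raise ValueError(f"confound matrix must have {T} rows, got shape {conf.shape}")
        design_cols.append(conf)
    X = np.column_stack(design_cols)

    # Drop collinear columns via rank-revealing QR (pivoted through SVD check).
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        warnings.warn(
            f"confound matrix rank-deficient (rank {rank} < {X.shape[1]} columns); "
            "dropping collinear columns",
            stacklevel=2,
        )
        keep: list[int] = []
        for j in range(X.shape[1]):
            cand = X[:, keep + [j]]
            if np.linalg.matrix_rank(cand) > len(keep):
                keep.append(j)
        X = X[:, keep]

    beta, *_ = np.linalg.lstsq(X, flat.T, rcond=None)
    resid = flat - (X @ beta).T
    return resid.reshape(spatial + (T,)) if len(spatial) == 3 else resid


def denoise(
    ts: np.ndarray,
    config: DenoiseConfig,
    confounds: np.ndarray | None,
    tr: float,
) -> np.ndarray:
    """Clean voxel time series: confound regression -> detrend -> band-pass.

    The fixed order applies :func:`regress_confounds` first (OLS residual
    against intercept + confounds), then a linear detrend, then the hard-mask
    FFT band-pass.  Note the later stages are separate projections: the final
    output is orthogonal to the *filtered* confounds, not bin-for-bin to the
    raw ones.  Returns an array of the input shape.
    """
    config.validate(tr)
    resid, spatial = _to_voxels_by_time(regress_confounds(ts, confounds))
    T = resid.shape[-1]

    if config.detrend:
        t = np.arange(T, dtype=float)
        t = (t - t.mean()) / np.sqrt(np.sum((t - t.mean()) ** 2))
        slope = resid @ t
        resid = resid - np.outer(slope, t)
        resid = resid - resid.mean(axis=1, keepdims=True)

    out = bandpass_mask_fft(resid, config.band[0], config.band[1], tr)
    return out.reshape(spatial + (T,)) if len(spatial) == 3 else out


def seed_to_voxel_map(
    ts_clean: np.ndarray,
    seed_mask,
    subject_id: str = "",
    seed_id: str = "seed",
    timepoint: str = "",
) -> ConnectivityMap:
    """Fisher-z map of the seed-mean time course against every voxel.

    r is the Pearson correlation of the seed-mask mean time course with each
    voxel; z = atanh(r) with r clamped to +/-(1-1e-7).  Zero-variance voxels
    get z = 0 and are flagged, as are clamped (seed-degenerate) voxels.
    """
    flat, spatial = _to_voxels_by_time(ts_clean)
    if flat.shape[-1] < 3:
        raise ValueError("need at least 3 time points")
    mask = np.asarray(seed_mask, dtype=bool)
    idx = np.flatnonzero(mask.ravel() if mask.shape == spatial else mask)
    if idx.size == 0:
        raise ValueError("seed mask is empty")

    seed_tc = flat[idx].mean(axis=0)
    seed_tc = seed_tc - seed_tc.mean()
    seed_norm = np.sqrt(np.sum(seed_tc**2))
    if seed_norm == 0:
        raise ValueError("seed mean time course has zero variance")

    centered = flat - flat.mean(axis=1, keepdims=True)
    vox_norm = np.sqrt(np.sum(centered**2, axis=1))
    zero_var = vox_norm == 0
    vox_norm[zero_var] = 1.0
    r = (centered @ seed_tc) / (vox_norm * seed_norm)
    r[zero_var] = 0.0

    clamped = np.abs(r) > R_CLAMP
    r = np.clip(r, -R_CLAMP, R_CLAMP)
    z = np.arctanh(r)
    z[zero_var] = 0.0
    flags = zero_var | clamped

    if len(spatial) == 3:
        z = z.reshape(spatial)
        flags = flags.reshape(spatial)
    return ConnectivityMap(
        subject_id=subject_id, seed_id=seed_id, timepoint=timepoint, z=z, flags=flags
    )


def load_nifti_run(path: str | Path, tr_override: float | None = None) -> tuple[np.ndarray, float]:
    """Load a 4D NIfTI run; TR from pixdim[4] unless overridden."""
    import nibabel as nib

    img = nib.load(str(path))
    tr = float(img.header["pixdim"][4]) if tr_override is None else float(tr_override)
    if tr <= 0:
        raise ValueError(f"no usable TR in {path}; pass tr_override")
    return np.asarray(img.dataobj, dtype=float), tr
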