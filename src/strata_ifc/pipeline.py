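"""End-to-end orchestration: synthesis -> classification -> connectivity -> inference.

One YAML config drives a full run.  In ``simulation`` mode the synthetic
cohort generator supplies both the clinical table and the imaging data; in
``data`` mode a clinical CSV and a directory of per-subject 4D NIfTI runs are
read instead.  The stage order mirrors the analysis stream: responder
classification from clinical scales first, then seed-to-voxel connectivity,
then screening and conjunction inference grouped by the *predicted* labels.

All randomness flows from one root seed, expanded per stage, so a single
integer reproduces a whole run; the manifest records per-artifact checksums
to make that verifiable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from strata_ifc.clinstats import FEATURE_COLUMNS, table_report
from strata_ifc.groupinfer import (
    medication_effect,
    screen_group_difference,
    summarize_effect,
)
from strata_ifc.ifc import DenoiseConfig, denoise, load_nifti_run, seed_to_voxel_map
from strata_ifc.respclass import classify_m2, train_ensemble
from strata_ifc.synthcohort import CohortSpec, TimeSeriesSpec, generate_clinical, generate_timeseries

__all__ = ["PipelineConfig", "RunManifest", "ValidationReport", "run_pipeline", "validate_inputs"]

log = logging.getLogger("strata_ifc")


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (one YAML document)."""

    mode: str = "simulation"
    out_dir: str = "strata_ifc_out"
    seed: int = 0
    synth_clinical: dict = field(default_factory=dict)
    synth_timeseries: dict = field(default_factory=dict)
    denoise_enabled: bool = True
    denoise: dict = field(default_factory=dict)
    screening: dict = field(default_factory=lambda: {"alpha": 0.001, "extent_k": 5, "directions": ["hypo", "hyper"]})
    conjunction: dict = field(default_factory=lambda: {"fwe_method": "bonferroni", "fwe_alpha": 0.05, "n_perm": 5000})
    data: dict = field(default_factory=dict)
    write_nifti: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("simulation", "data"):
            raise ValueError(f"mode must be 'simulation' or 'data', got {self.mode!r}")
        alpha = self.screening.get("alpha", 0.001)
        if not (0 < alpha <= 1):
            raise ValueError(f"screening alpha must lie in (0,1], got {alpha}")
        fa = self.conjunction.get("fwe_alpha", 0.05)
        if not (0 < fa < 1):
            raise ValueError(f"conjunction fwe_alpha must lie in (0,1), got {fa}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        synth = raw.pop("synth", {})
        kwargs = dict(raw)
        kwargs["synth_clinical"] = synth.get("clinical", {})
        kwargs["synth_timeseries"] = synth.get("timeseries", {})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(kwargs) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    config_hash: str
    package_version: str
    root_seed: int
    stage_seeds: dict[str, int]
    checksums: dict[str, str]
    timestamps: dict[str, float]

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seeds(root: int, names: tuple[str, ...]) -> dict[str, int]:
    ss = np.random.SeedSequence(root)
    children = ss.spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)}


def validate_inputs(config: PipelineConfig, clinical: pd.DataFrame | None = None) -> ValidationReport:
    """Check the clinical table (and, in data mode, referenced paths).

    Rules: every feature column present with no missing values; patients have
    both an M1 and an M2 row; controls have an M1 row and — by study design
    (controls scanned at baseline only) — an M2 row draws a warning.
    """
    rep = ValidationReport()
    if config.mode == "data":
        for key in ("clinical_csv", "imaging_dir", "seed_mask"):
            p = config.data.get(key)
            if p is None:
                rep.errors.append(f"data mode requires data.{key}")
            elif not Path(p).exists():
                rep.errors.append(f"data.{key} does not exist: {p}")
        if clinical is None and config.data.get("clinical_csv") and Path(config.data["clinical_csv"]).exists():
            clinical = pd.read_csv(config.data["clinical_csv"])
    if clinical is None:
        return rep

    for col in ("subject_id", "group", "timepoint", *FEATURE_COLUMNS):
        if col not in clinical.columns:
            rep.errors.append(f"clinical table missing column {col!r}")
    if rep.errors:
        return rep
    if clinical[list(FEATURE_COLUMNS)].isna().any().any():
        rep.errors.append("missing values in feature columns")
    for sid, sub in clinical.groupby("subject_id"):
        tps = set(sub["timepoint"])
        group = sub["group"].iloc[0]
        if group == "patient":
            if "M1" not in tps:
                rep.errors.append(f"patient {sid} missing M1 clinical row")
            if "M2" not in tps:
                rep.errors.append(f"patient {sid} missing M2 clinical row")
        else:
            if "M2" in tps:
                rep.warnings.append(f"control {sid} has an M2 row (controls are baseline-only)")
    return rep


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute all stages and write artifacts under ``config.out_dir``.

    Artifacts: ``cohort.csv`` (simulation mode), ``table1.csv``,
    ``labels.csv``, ``screening_<direction>.npz``, ``conjunction_clusters.csv``,
    ``effect_summary.csv``, ``summary.md`` and ``manifest.json``.  Any stage
    failure raises with the stage name; completed artifacts are preserved.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed, ("clinical", "timeseries", "permutation"))
    checksums: dict[str, str] = {}
    timestamps: dict[str, float] = {}
    stage = "setup"

    def record(path: Path) -> None:
        checksums[path.name] = _sha256(path)

    try:
        # --- stage: clinical data -------------------------------------------
        stage = "clinical"
        t0 = time.time()
        if config.mode == "simulation":
            cspec = CohortSpec(rng_seed=seeds["clinical"], **config.synth_clinical)
            clinical = generate_clinical(cspec)
            p = out / "cohort.csv"
            clinical.to_csv(p, index=False)
            record(p)
        else:
            clinical = pd.read_csv(config.data["clinical_csv"])
        rep = validate_inputs(config, clinical)
        for w in rep.warnings:
            log.warning("[validate] %s", w)
        if not rep.ok:
            raise ValueError(f"input validation failed: {rep.errors}")
        m1 = clinical[clinical["timepoint"] == "M1"]
        p = out / "table1.csv"
        table_report(m1).to_csv(p, index=False)
        record(p)
        timestamps[stage] = time.time() - t0
        log.info("[clinical] %d subjects (%d patients)", m1["subject_id"].nunique(),
                 (m1["group"] == "patient").sum())

        # --- stage: responder classification --------------------------------
        stage = "classify"
        t0 = time.time()
        ensemble = train_ensemble(m1)
        m2 = clinical[(clinical["timepoint"] == "M2") & (clinical["group"] == "patient")]
        labels = classify_m2(ensemble, m2)
        p = out / "labels.csv"
        labels.to_csv(p)
        record(p)
        timestamps[stage] = time.time() - t0
        final = labels.final
        log.info("[classify] %d Responders / %d Non-Responders",
                 (final == "Responder").sum(), (final == "NonResponder").sum())

        # --- stage: connectivity --------------------------------------------
        stage = "connectivity"
        t0 = time.time()
        if config.mode == "simulation":
            tspec = TimeSeriesSpec(rng_seed=seeds["timeseries"], **config.synth_timeseries)
            ts = generate_timeseries(tspec, clinical)
            runs = ts.data
            seed_mask = ts.seed_mask
            tr = ts.tr
        else:
            runs, seed_mask, tr = _load_data_runs(config, clinical)
        dn = DenoiseConfig(**config.denoise)
        zmaps: dict[tuple[str, str], np.ndarray] = {}
        for (sid, tp), arr in runs.items():
            clean = denoise(arr, dn, None, tr) if config.denoise_enabled else arr
            cm = seed_to_voxel_map(clean, seed_mask, subject_id=sid, timepoint=tp)
            zmaps[(sid, tp)] = cm.z
        timestamps[stage] = time.time() - t0
        log.info("[connectivity] %d maps on grid %s", len(zmaps), next(iter(zmaps.values())).shape)

        # --- stage: inference -----------------------------------------------
        stage = "inference"
        t0 = time.time()
        hc_ids = m1.loc[m1["group"] == "control", "subject_id"]
        pat_ids = m1.loc[m1["group"] == "patient", "subject_id"]
        maps_hc = [zmaps[(s, "M1")] for s in hc_ids]
        maps_pat_m1 = [zmaps[(s, "M1")] for s in pat_ids]
        resp_ids = [s for s in pat_ids if final.get(s) == "Responder"]
        nonresp_ids = [s for s in pat_ids if final.get(s) == "NonResponder"]

        conj_rows = []
        summary_lines = [
            "# strata-ifc run summary", "",
            f"- mode: {config.mode}; seed: {config.seed}",
            f"- Responders: {len(resp_ids)}; Non-Responders: {len(nonresp_ids)}; controls: {len(maps_hc)}",
        ]
        scr_cfg = config.screening
        conj_cfg = config.conjunction
        for direction in scr_cfg.get("directions", ["hypo", "hyper"]):
            mask = screen_group_difference(
                maps_hc, maps_pat_m1, direction=direction,
                alpha=scr_cfg.get("alpha", 0.001), extent_k=scr_cfg.get("extent_k", 5),
            )
            np.savez(out / f"screening_{direction}.npz", mask=mask.mask,
                     t_map=mask.t_map, cluster_labels=mask.cluster_labels)
            record(out / f"screening_{direction}.npz")
            summary_lines.append(
                f"- screening ({direction}): {mask.n_voxels} voxels in {mask.n_clusters} clusters"
            )
            if mask.n_voxels == 0 or not resp_ids or not nonresp_ids:
                continue
            result = medication_effect(
                [zmaps[(s, "M1")] for s in resp_ids], [zmaps[(s, "M2")] for s in resp_ids],
                [zmaps[(s, "M1")] for s in nonresp_ids], [zmaps[(s, "M2")] for s in nonresp_ids],
                mask,
                fwe_method=conj_cfg.get("fwe_method", "bonferroni"),
                fwe_alpha=conj_cfg.get("fwe_alpha", 0.05),
                n_perm=conj_cfg.get("n_perm", 5000),
                rng_seed=seeds["permutation"],
            )
            ct = result.cluster_table()
            ct.insert(0, "direction", direction)
            conj_rows.append(ct)
            summary_lines.append(
                f"- conjunction ({direction}): {len(result.clusters)} FWE-significant cluster(s)"
            )
            if result.significant.any():
                cells = {
                    ("HC", "M1"): maps_hc,
                    ("Responder", "M1"): [zmaps[(s, "M1")] for s in resp_ids],
                    ("Responder", "M2"): [zmaps[(s, "M2")] for s in resp_ids],
                    ("NonResponder", "M1"): [zmaps[(s, "M1")] for s in nonresp_ids],
                    ("NonResponder", "M2"): [zmaps[(s, "M2")] for s in nonresp_ids],
                }
                eff = summarize_effect(result, cells)
                eff.insert(0, "direction", direction)
                p = out / f"effect_summary_{direction}.csv"
                eff.to_csv(p, index=False)
                record(p)
        clusters = (
            pd.concat(conj_rows, ignore_index=True)
            if conj_rows
            else pd.DataFrame(columns=["direction", "cluster", "x", "y", "z", "z_value", "p_fwe", "extent", "d"])
        )
        p = out / "conjunction_clusters.csv"
        clusters.to_csv(p, index=False)
        record(p)
        timestamps[stage] = time.time() - t0

        p = out / "summary.md"
        p.write_text("\n".join(summary_lines) + "\n")
        record(p)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    from strata_ifc import __version__

    manifest = RunManifest(
        config_hash=config.config_hash(),
        package_version=__version__,
        root_seed=config.seed,
        stage_seeds=seeds,
        checksums=checksums,
        timestamps=timestamps,
    )
    manifest.write(out / "manifest.json")
    return manifest


def _load_data_runs(config: PipelineConfig, clinical: pd.DataFrame):
    """Data mode: load per-subject 4D runs ``<subject>_<timepoint>.nii[.gz]``."""
    import nibabel as nib

    imaging_dir = Path(config.data["imaging_dir"])
    seed_mask = np.asarray(nib.load(str(config.data["seed_mask"])).dataobj) > 0
    tr_override = config.data.get("tr")
    runs: dict[tuple[str, str], np.ndarray] = {}
    tr = None
    for row in clinical[["subject_id", "timepoint"]].drop_duplicates().itertuples(index=False):
        matches = sorted(imaging_dir.glob(f"{row.subject_id}_{row.timepoint}.nii*"))
        if not matches:
            raise FileNotFoundError(
                f"no run for subject {row.subject_id} timepoint {row.timepoint} in {imaging_dir}"
            )
        arr, run_tr = load_nifti_run(matches[0], tr_override)
        if tr is None:
            tr = run_tr
        runs[(row.subject_id, row.timepoint)] = arr
    return runs, seed_mask, tr
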