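"""End-to-end study pipeline: cohort on disk → fusion reports.

Per subject and phase the pipeline registers each echo method onto the
CMR reference, re-fits all surfaces to the common template in the CMR
cardiac frame, computes per-AHA-segment mean surface distances, global
volumetric indices (BSA-indexed) and, when an image volume is present,
per-segment relative signal intensity; cohort-level agreement
statistics (Bonferroni-corrected paired t, ICC(A,k), two- and
multi-method Bland-Altman) are written as CSV and JSON.

All outputs are deterministic for a given configuration and seed;
timestamps appear only in the log file.
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .geometry import build_frame
from .indices import SubjectInfo, volumetric_report
from .intensity import normalize_intensity, segment_mean_intensity
from .io import (
    read_landmarks,
    read_mesh,
    read_volume,
    write_landmarks,
    write_mesh,
    write_volume,
)
from .phantom import PhantomSubject
from .regional import assign_aha_segments, mean_surface_distance
from .registration import PhaseData, register_subject
from .stats import bland_altman_multi, bland_altman_two, icc_a_k, paired_t
from .template import fit_surface

__all__ = ["StudyConfig", "run_pipeline", "write_cohort", "load_subject_data"]

PHASES = ("ED", "ES")
log = logging.getLogger("lvfusion")

_INDICES = ("edv", "esv", "ef", "lvm", "edvi", "esvi", "lvmi")
_FLOAT_FMT = "%.10g"


class StudyConfig(BaseModel):
    """Pipeline configuration (units: mm, ml, g, degrees)."""

    cohort_dir: str
    out_dir: str
    methods: List[str] = Field(default_factory=lambda: ["echoA", "echoB", "echoC"])
    n_u: int = 24
    n_v: int = 24
    lambda_smooth: float = 1.0
    cap_u: float = 0.90
    refine: bool = True
    max_iter: int = 100
    tol: float = 1e-4
    rms_threshold: float = 5.0
    density: float = 1.05
    alpha: float = 0.05
    bonferroni_m: int = 3
    intensity: bool = False
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "StudyConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            return cls(**yaml.safe_load(text))
        return cls(**json.loads(text))


# --------------------------------------------------------- disk layout

def write_cohort(subjects: List[PhantomSubject], meta: pd.DataFrame, cohort_dir,
                 mesh_format: str = "ply", volumes: bool = False,
                 segment_intensity: Optional[dict] = None) -> None:
    """Write a phantom cohort in the on-disk layout the pipeline reads.

    ``cohort_dir/<subject>/<modality>/<phase>_<surface>.<ext>`` plus
    per-phase landmark JSON and a cohort-level metadata CSV.
    """
    from .phantom import make_echo_volume

    cohort_dir = Path(cohort_dir)
    cohort_dir.mkdir(parents=True, exist_ok=True)
    ext = mesh_format.lstrip(".")
    for subj in subjects:
        modalities = {"cmr": subj.cmr}
        modalities.update(subj.echo)
        for modality, phases in modalities.items():
            mdir = cohort_dir / subj.subject_id / modality
            mdir.mkdir(parents=True, exist_ok=True)
            for phase, data in phases.items():
                write_mesh(mdir / f"{phase}_endo.{ext}", data.endo)
                write_mesh(mdir / f"{phase}_epi.{ext}", data.epi)
                write_landmarks(mdir / f"{phase}_landmarks.json", data.landmarks)
        if volumes:
            vol = subj.volume
            if vol is None:
                vol = make_echo_volume(subj, segment_intensity or {})
            write_volume(cohort_dir / subj.subject_id / "volume.mha", vol)
    meta.to_csv(cohort_dir / "cohort.csv", index=False, float_format=_FLOAT_FMT)


def load_subject_data(subject_dir: Path, modality: str) -> Dict[str, PhaseData]:
    mdir = Path(subject_dir) / modality
    out = {}
    for phase in PHASES:
        endo_path = next(mdir.glob(f"{phase}_endo.*"))
        epi_path = next(mdir.glob(f"{phase}_epi.*"))
        out[phase] = PhaseData(
            endo=read_mesh(endo_path, surface_tag="endo", phase=phase),
            epi=read_mesh(epi_path, surface_tag="epi", phase=phase),
            landmarks=read_landmarks(mdir / f"{phase}_landmarks.json"),
        )
    return out


# ------------------------------------------------------------ pipeline

def _process_subject(subject_id: str, cmr: Dict[str, PhaseData],
                     echo_by_method: Dict[str, Dict[str, PhaseData]],
                     bsa: float, volume, cfg: StudyConfig):
    """All per-subject computation; returns row lists for the report tables."""
    msd_rows, vol_rows, reg_rows, int_rows = [], [], [], []
    subject = SubjectInfo(subject_id=subject_id, bsa=bsa)

    frames = {ph: build_frame(cmr[ph].landmarks) for ph in PHASES}
    # endo apex extent from the landmarks; epi from the CMR epi data (the
    # epicardial apex lies beyond the endocardial one).  Both modalities
    # share each tag's extent so fitted nodes correspond.
    extents = {}
    for ph in PHASES:
        lm = cmr[ph].landmarks
        extents[(ph, "endo")] = float(
            np.linalg.norm(lm.apical_centroid - lm.basal_centroid)
        )
        extents[(ph, "epi")] = float(
            np.max((cmr[ph].epi.vertices - frames[ph].origin) @ frames[ph].e_long)
        )

    def fit(points, phase, tag):
        return fit_surface(
            points, frames[phase], n_u=cfg.n_u, n_v=cfg.n_v,
            lambda_smooth=cfg.lambda_smooth, apex_extent=extents[(phase, tag)],
            surface_tag=tag, phase=phase,
        )

    cmr_fit = {
        ph: {tag: fit(getattr(cmr[ph], tag).vertices, ph, tag) for tag in ("endo", "epi")}
        for ph in PHASES
    }
    labels = {
        ph: {tag: assign_aha_segments(cmr_fit[ph][tag], cap_u=cfg.cap_u) for tag in ("endo", "epi")}
        for ph in PHASES
    }
    rep = volumetric_report(
        cmr_fit["ED"]["endo"], cmr_fit["ES"]["endo"], cmr_fit["ED"]["epi"],
        method="cmr", subject=subject, density=cfg.density,
    )
    vol_rows.append({"subject": subject_id, "method": "cmr",
                     **{k: getattr(rep, k) for k in _INDICES}})

    for method, echo in echo_by_method.items():
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            regs = register_subject(
                echo, cmr, refine=cfg.refine, max_iter=cfg.max_iter,
                tol=cfg.tol, rms_threshold=cfg.rms_threshold,
            )
        for w in caught:
            log.warning("%s/%s: %s", subject_id, method, w.message)
        echo_fit = {}
        for reg in regs:
            ph = reg.phase
            reg_rows.append({
                "subject": subject_id, "method": method, "phase": ph,
                "rms_residual_mm": reg.rms_residual,
                "n_iterations": reg.n_iterations,
                "converged": reg.converged,
                "rotation_deg": reg.total.rotation_angle_deg(),
                "translation_mm": float(np.linalg.norm(reg.total.translation)),
            })
            echo_fit[ph] = {
                tag: fit(reg.total.apply(getattr(echo[ph], tag).vertices), ph, tag)
                for tag in ("endo", "epi")
            }
            for tag in ("endo", "epi"):
                report = mean_surface_distance(
                    cmr_fit[ph][tag], echo_fit[ph][tag], labels[ph][tag]
                )
                for seg in sorted(report.msd):
                    msd_rows.append({
                        "subject": subject_id, "method": method, "phase": ph,
                        "surface": tag, "segment": seg,
                        "msd_mm": report.msd[seg], "n_p": report.n_p[seg],
                    })
        rep = volumetric_report(
            echo_fit["ED"]["endo"], echo_fit["ES"]["endo"], echo_fit["ED"]["epi"],
            method=method, subject=subject, density=cfg.density,
        )
        vol_rows.append({"subject": subject_id, "method": method,
                         **{k: getattr(rep, k) for k in _INDICES}})

    if volume is not None and cfg.intensity:
        norm = normalize_intensity(volume)
        report = segment_mean_intensity(
            norm, cmr_fit["ED"]["endo"], cmr_fit["ED"]["epi"], cap_u=cfg.cap_u
        )
        for seg in sorted(report.mean_pct):
            int_rows.append({
                "subject": subject_id, "segment": seg,
                "mean_intensity_pct": report.mean_pct[seg],
                "voxel_count": report.voxel_count[seg],
            })
    return msd_rows, vol_rows, reg_rows, int_rows


def _cohort_stats(vol_df: pd.DataFrame, cfg: StudyConfig) -> list:
    """Paired t / ICC / Bland-Altman for every index and echo method."""
    rows = []
    alpha_corr = cfg.alpha / cfg.bonferroni_m
    wide = {idx: vol_df.pivot(index="subject", columns="method", values=idx)
            for idx in _INDICES}
    for idx in _INDICES:
        tab = wide[idx].dropna(axis=1, how="all").dropna()
        if "cmr" not in tab.columns or len(tab) < 3:
            continue
        for method in cfg.methods:
            if method not in tab.columns:
                continue
            x = tab[method].to_numpy()
            y = tab["cmr"].to_numpy()
            try:
                t = paired_t(x, y, alpha_corrected=alpha_corr)
                rows.append({
                    "index": idx, "comparison": f"{method}-cmr", "statistic": "paired_t",
                    "estimate": t.mean_difference, "sd": t.sd_difference,
                    "t": t.t_statistic, "p": t.p_value, "significant": t.significant,
                    "lower": None, "upper": None, "n": t.n,
                })
            except ValueError as exc:
                log.warning("paired t for %s %s skipped: %s", idx, method, exc)
            icc = icc_a_k(np.column_stack([y, x]))
            ba = bland_altman_two(x, y)
            rows.append({
                "index": idx, "comparison": f"{method}-cmr", "statistic": "icc_a_k",
                "estimate": icc.icc, "sd": None, "t": None, "p": None,
                "significant": None, "lower": None, "upper": None, "n": icc.n_subjects,
            })
            rows.append({
                "index": idx, "comparison": f"{method}-cmr", "statistic": "bland_altman",
                "estimate": ba.bias, "sd": ba.sd_difference, "t": None, "p": None,
                "significant": None, "lower": ba.loa_lower, "upper": ba.loa_upper,
                "n": ba.n,
            })
        echo_cols = [m for m in cfg.methods if m in tab.columns]
        if len(echo_cols) >= 2:
            icc = icc_a_k(tab[echo_cols].to_numpy())
            rows.append({
                "index": idx, "comparison": "+".join(echo_cols), "statistic": "icc_a_k",
                "estimate": icc.icc, "sd": None, "t": None, "p": None,
                "significant": None, "lower": None, "upper": None, "n": icc.n_subjects,
            })
        if len(echo_cols) >= 3:
            ba = bland_altman_multi(tab[echo_cols].to_numpy())
            for j, m in enumerate(echo_cols):
                rows.append({
                    "index": idx, "comparison": f"{m}-mean", "statistic": "bland_altman_multi",
                    "estimate": float(ba.bias[j]), "sd": ba.sd_difference,
                    "t": None, "p": None, "significant": None,
                    "lower": ba.loa_lower, "upper": ba.loa_upper, "n": ba.n,
                })
    return rows


def run_pipeline(cfg: StudyConfig) -> dict:
    """Run the full fusion study described by a config; returns the tables.

    Per-subject failures are logged and the subject skipped; only
    configuration errors abort the run.
    """
    t_start = time.perf_counter()
    cohort_dir = Path(cfg.cohort_dir)
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    meta = pd.read_csv(cohort_dir / "cohort.csv")
    msd_rows, vol_rows, reg_rows, int_rows = [], [], [], []
    try:
        for _, row in meta.iterrows():
            sid = str(row["subject_id"])
            sdir = cohort_dir / sid
            t0 = time.perf_counter()
            try:
                cmr = load_subject_data(sdir, "cmr")
                echo = {m: load_subject_data(sdir, m) for m in cfg.methods}
                volume = None
                vol_path = sdir / "volume.mha"
                if cfg.intensity and vol_path.exists():
                    volume = read_volume(vol_path)
                res = _process_subject(sid, cmr, echo, float(row["bsa"]), volume, cfg)
            except Exception as exc:  # per-subject failures are skipped
                log.error("subject %s failed and was skipped: %s", sid, exc)
                continue
            msd_rows += res[0]
            vol_rows += res[1]
            reg_rows += res[2]
            int_rows += res[3]
            log.info("subject %s done in %.2f s", sid, time.perf_counter() - t0)

        msd_df = pd.DataFrame(msd_rows)
        vol_df = pd.DataFrame(vol_rows)
        reg_df = pd.DataFrame(reg_rows)
        int_df = pd.DataFrame(int_rows)
        stats_rows = _cohort_stats(vol_df, cfg) if len(vol_df) else []
        stats_df = pd.DataFrame(stats_rows)

        msd_df.to_csv(out_dir / "msd.csv", index=False, float_format=_FLOAT_FMT)
        vol_df.to_csv(out_dir / "volumetrics.csv", index=False, float_format=_FLOAT_FMT)
        reg_df.to_csv(out_dir / "registration.csv", index=False, float_format=_FLOAT_FMT)
        if len(int_df):
            int_df.to_csv(out_dir / "intensity.csv", index=False, float_format=_FLOAT_FMT)
        stats_df.to_csv(out_dir / "stats.csv", index=False, float_format=_FLOAT_FMT)
        (out_dir / "stats.json").write_text(
            json.dumps(stats_rows, indent=2, sort_keys=True, default=float) + "\n"
        )
        log.info("pipeline finished in %.2f s", time.perf_counter() - t_start)
    finally:
        log.removeHandler(handler)
        handler.close()
    return {
        "msd": msd_df,
        "volumetrics": vol_df,
        "registration": reg_df,
        "intensity": int_df,
        "stats": stats_df,
    }
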