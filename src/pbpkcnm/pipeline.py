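"""Constraint-based perturbation analysis across a patient cohort.

Three steps:

1. *Unconstrained estimation* — one CNM run per patient with all 105 drug
   parameters free (10 iterations).
2. *Kp consolidation* — pool the parameter sets that reproduce the
   objectives well (SSR ≤ 0.03) across patients and take the per-index
   median of the 70 partition coefficients; Kp reflects the physical
   chemistry of the compound rather than the individual, so one shared
   value per tissue is imposed on everybody.
3. *Constrained re-estimation* — a second CNM per patient (15 iterations)
   with the Kp coordinates fixed at the consolidated medians and the 35
   remaining parameters free.

Parameters whose final-cluster coefficient of variation is ≤ 0.3 are
regarded as strongly converging (identifiable); comparing their
distributions between age groups (below 70 vs 70 and over) is the study's
read-out.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cnm import Cluster, CNMConfig, ConstraintMask, run_cnm
from .model import compute_observables, simulate
from .parameters import KP_INDICES, N_PARAMS, PARAM_NAMES, BoundBox, DrugParameterSet
from .physiology import PatientPhysiology

__all__ = [
    "StudyInputs",
    "CVReport",
    "PipelineResult",
    "forward_for_patient",
    "run_stage1",
    "select_low_ssr",
    "median_kp",
    "run_stage2",
    "compute_cv",
    "select_strong",
    "age_group_summary",
    "run_pipeline",
    "SSR_SELECT_THRESHOLD",
    "CV_SELECT_THRESHOLD",
    "STRONG_PARAM_IDS",
]

#: Parameter sets with SSR at or below this reproduce the objectives well.
SSR_SELECT_THRESHOLD = 0.03
#: A final-cluster CV at or below this marks a strongly converging parameter.
CV_SELECT_THRESHOLD = 0.3
#: 1-based IDs of the parameters that converge strongly in every patient:
#: renal clearance of CPT-11, biliary clearance of CPT-11, and hepatic
#: CYP3A4 clearance of CPT-11 to APC.
STRONG_PARAM_IDS = (71, 76, 83)


@dataclass(frozen=True)
class StudyInputs:
    """Cohort inputs: physiologies, per-patient objectives, shared bounds."""

    patients: Sequence[PatientPhysiology]
    objectives: np.ndarray  # (n_patients, 13)
    bounds: BoundBox

    def __post_init__(self) -> None:
        obj = np.asarray(self.objectives, dtype=float)
        if obj.shape != (len(self.patients), 13):
            raise ValueError("objectives must be (n_patients, 13)")
        if not np.all(obj > 0):
            raise ValueError("all objective entries must be positive")
        object.__setattr__(self, "objectives", obj)


def forward_for_patient(phys: PatientPhysiology, horizon: float = 30_240.0):
    """Forward map x ↦ 13 observables for one patient (None on failure)."""

    def forward(x: np.ndarray):
        try:
            params = DrugParameterSet(x)
        except ValueError:
            return None
        res = simulate(phys, params, horizon=horizon)
        if not res.ok:
            return None
        return compute_observables(res)

    return forward


def _patient_seed(config: CNMConfig, stage: int, patient_index: int) -> int:
    # keyed derivation: per-patient runs are independent of cohort ordering
    ss = np.random.SeedSequence([config.seed, stage, patient_index])
    return int(ss.generate_state(1)[0] % (2**31))


def run_stage1(
    inputs: StudyInputs,
    config: CNMConfig,
    horizon: float = 30_240.0,
) -> dict[object, list[Cluster]]:
    """Unconstrained CNM per patient; returns iteration histories keyed by
    patient id."""
    out: dict[object, list[Cluster]] = {}
    for i, phys in enumerate(inputs.patients):
        cfg = replace(config, seed=_patient_seed(config, 1, i))
        out[phys.patient_id] = run_cnm(
            forward_for_patient(phys, horizon), inputs.objectives[i],
            inputs.bounds, ConstraintMask.empty(), cfg,
        )
    return out


def select_low_ssr(
    clusters: Mapping[object, Cluster],
    threshold: float = SSR_SELECT_THRESHOLD,
) -> tuple[np.ndarray, np.ndarray]:
    """Pool the well-fitting points (SSR ≤ threshold, inclusive) across
    patients.

    Returns ``(points, patient_ids)`` with one row per selected set.
    Raises if nothing qualifies (advice: more iterations or a looser
    threshold).
    """
    rows, tags = [], []
    for pid, cluster in clusters.items():
        keep = cluster.ok & (cluster.ssr <= threshold)
        rows.append(cluster.points[keep])
        tags.extend([pid] * int(keep.sum()))
    points = np.vstack(rows) if rows else np.empty((0, N_PARAMS))
    if points.shape[0] == 0:
        raise ValueError(
            f"no parameter sets with SSR <= {threshold}; run more iterations "
            "or loosen the threshold"
        )
    return points, np.asarray(tags, dtype=object)


def median_kp(selected_points: np.ndarray) -> ConstraintMask:
    """Per-index median of the 70 Kp coordinates over the pooled selected
    sets, as a constraint mask for the second CNM."""
    pts = np.atleast_2d(np.asarray(selected_points, dtype=float))
    if pts.shape[0] == 0:
        raise ValueError("no selected parameter sets")
    med = np.median(pts[:, KP_INDICES], axis=0)
    return ConstraintMask(np.asarray(KP_INDICES), med)


def run_stage2(
    inputs: StudyInputs,
    mask: ConstraintMask,
    config: CNMConfig,
    horizon: float = 30_240.0,
    initial_points: Mapping[object, np.ndarray] | None = None,
) -> dict[object, list[Cluster]]:
    """Kp-constrained CNM per patient (fresh initial sampling by default;
    pass ``initial_points`` to restart from stage-1 clusters instead)."""
    if not np.array_equal(np.sort(mask.indices), np.asarray(KP_INDICES)):
        raise ValueError("stage-2 mask must fix exactly the 70 Kp indices")
    out: dict[object, list[Cluster]] = {}
    for i, phys in enumerate(inputs.patients):
        cfg = replace(config, seed=_patient_seed(config, 2, i))
        init = None if initial_points is None else initial_points[phys.patient_id]
        out[phys.patient_id] = run_cnm(
            forward_for_patient(phys, horizon), inputs.objectives[i],
            inputs.bounds, mask, cfg, initial_points=init,
        )
    return out


def compute_cv(cluster: Cluster, free: np.ndarray | None = None) -> np.ndarray:
    """Coefficient of variation (sample sd / mean, linear scale) of each
    free parameter over the successful cluster points."""
    if free is None:
        free = np.arange(cluster.points.shape[1])
    pts = cluster.points[cluster.ok][:, free]
    if pts.shape[0] < 2:
        raise ValueError("need at least 2 successful points to compute CV")
    return pts.std(axis=0, ddof=1) / pts.mean(axis=0)


@dataclass(frozen=True)
class CVReport:
    """Per-patient, per-parameter CV table with a selection threshold."""

    cv: pd.DataFrame  # index: patient ids; columns: parameter names
    threshold: float = CV_SELECT_THRESHOLD

    @property
    def selected(self) -> pd.DataFrame:
        return self.cv <= self.threshold

    def selected_in_all_patients(self) -> list[str]:
        return [c for c in self.cv.columns if bool(self.selected[c].all())]


def cv_report(
    clusters: Mapping[object, Cluster],
    free: np.ndarray,
    threshold: float = CV_SELECT_THRESHOLD,
) -> CVReport:
    """CV of every free parameter in every patient's final cluster."""
    rows = {pid: compute_cv(c, free) for pid, c in clusters.items()}
    tab = pd.DataFrame.from_dict(rows, orient="index",
                                 columns=[PARAM_NAMES[i] for i in free])
    return CVReport(cv=tab, threshold=threshold)


def select_strong(report: CVReport,
                  threshold: float | None = None) -> pd.DataFrame:
    """Boolean selection table (CV ≤ threshold, inclusive); parameters
    selected in every patient carry True in the added ``__all__`` row."""
    thr = report.threshold if threshold is None else threshold
    sel = report.cv <= thr
    sel.loc["__all__"] = sel.all(axis=0)
    return sel


def age_group_summary(
    patients: Sequence[PatientPhysiology],
    clusters: Mapping[object, Cluster],
    param_ids: Sequence[int] = STRONG_PARAM_IDS,
    cutoff: float = 70.0,
) -> pd.DataFrame:
    """Pooled distribution summary of selected parameters by age group.

    Groups are ``age < cutoff`` ("below") and ``age >= cutoff`` ("over");
    per group and parameter the pooled cluster points contribute their
    median and quartiles.  An empty group yields NaN rows (with a warning)
    rather than an error.
    """
    import warnings

    groups = {
        "below": [p for p in patients if p.age < cutoff],
        "over": [p for p in patients if p.age >= cutoff],
    }
    records = []
    for gname, members in groups.items():
        if not members:
            warnings.warn(f"age group '{gname}' (cutoff {cutoff}) is empty")
        for pid_param in param_ids:
            col = pid_param - 1
            pooled = [clusters[p.patient_id].points[clusters[p.patient_id].ok, col]
                      for p in members]
            vals = np.concatenate(pooled) if pooled else np.empty(0)
            q25, q50, q75 = (np.percentile(vals, [25, 50, 75])
                             if vals.size else (np.nan,) * 3)
            records.append({
                "group": gname, "param_id": pid_param,
                "param": PARAM_NAMES[col], "n_points": vals.size,
                "q25": q25, "median": q50, "q75": q75,
            })
    return pd.DataFrame.from_records(records)


@dataclass
class PipelineResult:
    """Everything the three-step analysis produces."""

    stage1: dict[object, list[Cluster]]
    mask: ConstraintMask
    stage2: dict[object, list[Cluster]]
    cv_stage1: CVReport
    cv_stage2: CVReport
    selection: pd.DataFrame
    age_summary_stage1: pd.DataFrame
    age_summary_stage2: pd.DataFrame
    config: CNMConfig

    def final_stage1(self) -> dict[object, Cluster]:
        return {pid: h[-1] for pid, h in self.stage1.items()}

    def final_stage2(self) -> dict[object, Cluster]:
        return {pid: h[-1] for pid, h in self.stage2.items()}


def run_pipeline(
    inputs: StudyInputs,
    config: CNMConfig,
    stage2_iterations: int = 15,
    ssr_threshold: float = SSR_SELECT_THRESHOLD,
    cv_threshold: float = CV_SELECT_THRESHOLD,
    horizon: float = 30_240.0,
) -> PipelineResult:
    """Run the full three-step constraint-based perturbation analysis.

    ``config.iterations`` applies to stage 1; stage 2 runs
    ``stage2_iterations`` with the same cluster size and dS.  Deterministic
    under ``config.seed``.
    """
    stage1 = run_stage1(inputs, config, horizon)
    finals1 = {pid: h[-1] for pid, h in stage1.items()}
    selected, _ = select_low_ssr(finals1, ssr_threshold)
    mask = median_kp(selected)
    cfg2 = replace(config, iterations=stage2_iterations)
    stage2 = run_stage2(inputs, mask, cfg2, horizon)
    finals2 = {pid: h[-1] for pid, h in stage2.items()}

    free2 = mask.free_indices(N_PARAMS)
    report1 = cv_report(finals1, free2, cv_threshold)  # same columns for contrast
    report2 = cv_report(finals2, free2, cv_threshold)
    selection = select_strong(report2)
    summary1 = age_group_summary(inputs.patients, finals1)
    summary2 = age_group_summary(inputs.patients, finals2)
    return PipelineResult(
        stage1=stage1, mask=mask, stage2=stage2,
        cv_stage1=report1, cv_stage2=report2, selection=selection,
        age_summary_stage1=summary1, age_summary_stage2=summary2,
        config=config,
    )
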