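"""Patient physiology: organ volumes, blood flows, demographics, dosing.

The circulatory system is modelled as 16 compartments — venous and arterial
blood, lung, and 14 perfused organs — each characterised by a volume (ml/kg)
and a blood flow (ml/min/kg).  Blood leaves the venous pool through the lung
into the arterial pool and perfuses the organs in parallel; the splanchnic
organs (spleen, pancreas, stomach, small and large intestine) drain into the
liver inlet together with the hepatic artery, so the liver sees the sum of
the hepatic-artery and portal flows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

__all__ = [
    "ORGANS",
    "KP_ORGANS",
    "SPLANCHNIC",
    "VENOUS_RETURN",
    "FLOW_KEYS",
    "PhysiologyError",
    "PatientPhysiology",
    "build_physiology",
]

#: The 16 circulatory compartments, in canonical order.
ORGANS = (
    "venous_blood",
    "artery_blood",
    "lung",
    "heart",
    "brain",
    "muscle",
    "adipose",
    "skin",
    "bone",
    "kidney",
    "spleen",
    "pancreas",
    "stomach",
    "small_intestine",
    "large_intestine",
    "liver",
)

#: Tissues with a tissue-plasma partition coefficient (everything but blood).
KP_ORGANS = ORGANS[2:]

#: Organs whose venous outflow enters the liver inlet (portal system).
SPLANCHNIC = ("spleen", "pancreas", "stomach", "small_intestine", "large_intestine")

#: Organs whose venous outflow returns directly to the venous pool.
VENOUS_RETURN = ("heart", "brain", "muscle", "adipose", "skin", "bone", "kidney", "liver")

#: Flow entries carried on a patient record (liver split into total/artery).
FLOW_KEYS = (
    "lung",
    "heart",
    "brain",
    "muscle",
    "adipose",
    "skin",
    "bone",
    "kidney",
    "spleen",
    "pancreas",
    "stomach",
    "small_intestine",
    "large_intestine",
    "liver_total",
    "liver_artery",
)

# Printed physiology tables are rounded to 0.1 ml/min/kg per flow; summed
# over the seven contributing flows the closure error can reach ~1 ml/min/kg.
FLOW_BALANCE_TOL = 1.0


class PhysiologyError(ValueError):
    """Raised when a patient record violates a physiological invariant."""


@dataclass(frozen=True)
class PatientPhysiology:
    """Validated per-patient physiology and dosing.

    Volumes are ml per kg body weight; flows are ml/min per kg; dose is
    μg per kg, administered as a zero-order intravenous infusion of
    ``infusion_duration`` minutes.
    """

    patient_id: int | str
    sex: str
    age: float
    height: float  # cm
    weight: float  # kg
    dose: float  # μg/kg
    infusion_duration: float  # min
    volume: Mapping[str, float] = field(repr=False)  # ml/kg, keys = ORGANS
    flow: Mapping[str, float] = field(repr=False)  # ml/min/kg, keys = FLOW_KEYS

    @property
    def bmi(self) -> float:
        """Body-mass index, weight(kg) / height(m)^2."""
        return self.weight / (self.height / 100.0) ** 2

    @property
    def portal_flow(self) -> float:
        """Portal-vein flow, liver total minus hepatic artery (ml/min/kg)."""
        return self.flow["liver_total"] - self.flow["liver_artery"]

    def balanced_flows(self) -> dict[str, float]:
        """Flows adjusted so every node balances exactly.

        Printed flows are rounded, so the lung flow and the liver total do
        not close exactly against their summands.  The simulator uses a
        consistent set: ``liver_total`` is recomputed as hepatic artery plus
        the splanchnic sum, and ``lung`` as the sum of all venous returns.
        The adjustments stay within the rounding tolerance checked by
        :func:`build_physiology`.
        """
        q = dict(self.flow)
        q["liver_total"] = q["liver_artery"] + sum(q[o] for o in SPLANCHNIC)
        q["lung"] = sum(q[o] for o in VENOUS_RETURN if o != "liver") + q["liver_total"]
        return q


def build_physiology(record: Mapping[str, object]) -> PatientPhysiology:
    """Build and validate a :class:`PatientPhysiology` from a tabular record.

    ``record`` must carry demographics (``sex``, ``age``, ``height_cm``,
    ``weight_kg``), dosing (``dose_ug_per_kg``, ``infusion_min``), one
    ``v_<organ>`` column per circulatory compartment and one ``q_<organ>``
    column per perfused organ (with the liver split into ``q_liver_total``
    and ``q_liver_artery``).

    Raises
    ------
    PhysiologyError
        If an entry is missing or non-positive (the message names the
        organ), or a flow-balance closure is violated beyond the rounding
        tolerance of the printed tables.
    """
    def _get(key: str) -> float:
        if key not in record or record[key] is None:
            raise PhysiologyError(f"missing physiology entry: {key}")
        return float(record[key])  # type: ignore[arg-type]

    volume = {}
    for organ in ORGANS:
        v = _get(f"v_{organ}")
        if not v > 0:
            raise PhysiologyError(f"non-positive volume for {organ}: {v}")
        volume[organ] = v
    flow = {}
    for key in FLOW_KEYS:
        q = _get(f"q_{key}")
        if not q > 0:
            raise PhysiologyError(f"non-positive blood flow for {key}: {q}")
        flow[key] = q

    if flow["liver_artery"] >= flow["liver_total"]:
        raise PhysiologyError(
            "hepatic-artery flow must be below the total liver flow "
            f"({flow['liver_artery']} >= {flow['liver_total']})"
        )
    splanchnic = sum(flow[o] for o in SPLANCHNIC)
    liver_closure = flow["liver_artery"] + splanchnic - flow["liver_total"]
    if abs(liver_closure) > FLOW_BALANCE_TOL:
        raise PhysiologyError(
            "liver flow balance violated: artery + splanchnic - total = "
            f"{liver_closure:.2f} ml/min/kg (liver)"
        )
    venous_return = (
        sum(flow[o] for o in VENOUS_RETURN if o != "liver") + flow["liver_total"]
    )
    lung_closure = venous_return - flow["lung"]
    if abs(lung_closure) > FLOW_BALANCE_TOL:
        raise PhysiologyError(
            "lung flow balance violated: venous returns - lung = "
            f"{lung_closure:.2f} ml/min/kg (lung)"
        )

    height = _get("height_cm")
    weight = _get("weight_kg")
    dose = _get("dose_ug_per_kg")
    infusion = _get("infusion_min")
    for name, val in (("height", height), ("weight", weight), ("dose", dose),
                      ("infusion duration", infusion)):
        if not val > 0:
            raise PhysiologyError(f"non-positive {name}: {val}")

    return PatientPhysiology(
        patient_id=record.get("patient_id", "?"),  # type: ignore[arg-type]
        sex=str(record.get("sex", "?")),
        age=float(record.get("age", float("nan"))),  # type: ignore[arg-type]
        height=height,
        weight=weight,
        dose=dose,
        infusion_duration=infusion,
        volume=volume,
        flow=flow,
    )
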