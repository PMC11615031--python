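"""Cohort descriptive statistics and source-bandwidth scaling.

The evaluation cohort is summarized the way such feasibility studies report
it: continuous variables as median (range), categorical variables as counts
with percentages at one decimal, patient-level variables deduplicated by
patient before summarizing, and missing values counted per variable.

Also provided: the Gaussian-source axial-resolution relation
delta_z = (2 ln 2 / pi) * lambda0^2 / delta_lambda, inverted to give the
optical bandwidth a target resolution requires, and its scaling law
(doubling the centre wavelength needs fourfold bandwidth to hold
resolution).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Optional

import numpy as np

from .optics import TWO_LN2_OVER_PI

TECHNIQUES = ("polypectomy", "EMR", "eFTR")


@dataclass(frozen=True)
class PolypRecord:
    """One resected polyp."""

    patient_id: str
    age: float
    sex: str
    technique: str
    diagnosis: str
    location: str
    diameter: Optional[float] = None  # mm; None when not reported

    def __post_init__(self):
        if self.age <= 0:
            raise ValueError("age must be > 0")
        if self.diameter is not None and self.diameter <= 0:
            raise ValueError("diameter must be > 0 when present")
        if self.technique not in TECHNIQUES:
            raise ValueError(f"unknown technique {self.technique!r}; "
                             f"expected one of {TECHNIQUES}")


def _pct(count: int, denom: int) -> float:
    """Percentage rounded half-up to one decimal (69.2 from 9/13 etc.)."""
    exact = Decimal(100) * Decimal(count) / Decimal(denom)
    return float(exact.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def _categorical(values) -> dict:
    vals = [v for v in values if v is not None]
    n = len(vals)
    cats = {}
    for v in vals:
        cats[v] = cats.get(v, 0) + 1
    return {"n": n,
            "categories": {c: {"count": k, "percent": _pct(k, n)}
                           for c, k in cats.items()}}


def _continuous(values) -> dict:
    vals = [float(v) for v in values if v is not None]
    missing = len(list(values)) - len(vals)
    if not vals:
        return {"n": 0, "missing": missing}
    return {"n": len(vals), "missing": missing,
            "median": float(np.median(vals)),
            "min": float(min(vals)), "max": float(max(vals))}


@dataclass
class CohortSummary:
    """Per-variable descriptive statistics (see ``summarize_cohort``)."""

    n_patients: int
    n_polyps: int
    variables: dict

    def percent(self, variable: str, category: str) -> float:
        return self.variables[variable]["categories"][category]["percent"]

    def to_markdown(self) -> str:
        lines = [f"Patients: n = {self.n_patients}",
                 f"Polyps: n = {self.n_polyps}", ""]
        for name, v in self.variables.items():
            if "categories" in v:
                lines.append(f"**{name}** (n = {v['n']})")
                for cat, cc in v["categories"].items():
                    lines.append(f"- {cat}: {cc['count']} ({cc['percent']})")
            elif v.get("n"):
                lines.append(f"**{name}** (n = {v['n']}): median "
                             f"{v['median']:g} (range {v['min']:g}-{v['max']:g})")
            lines.append("")
        return "\n".join(lines)


def summarize_cohort(records) -> CohortSummary:
    """Descriptive summary of a polyp cohort.

    Patient-level variables (age, sex, polyps per patient) are deduplicated
    by patient_id; polyp-level variables (diameter, technique, diagnosis,
    location) are per record.  Percentages use the variable's own n (so a
    partially missing continuous variable reports its reduced n).
    """
    records = list(records)
    if not records:
        raise ValueError("empty cohort")
    by_patient = {}
    for r in records:
        by_patient.setdefault(r.patient_id, []).append(r)
    patients = {pid: rs[0] for pid, rs in by_patient.items()}
    variables = {
        "age": _continuous([p.age for p in patients.values()]),
        "sex": _categorical([p.sex for p in patients.values()]),
        "polyps_per_patient": _continuous(
            [len(rs) for rs in by_patient.values()]),
        "diameter": _continuous([r.diameter for r in records]),
        "technique": _categorical([r.technique for r in records]),
        "diagnosis": _categorical([r.diagnosis for r in records]),
        "location": _categorical([r.location for r in records]),
    }
    return CohortSummary(n_patients=len(patients), n_polyps=len(records),
                         variables=variables)


# ---------------------------------------------------------------------------
# source-bandwidth scaling

def bandwidth_for_resolution(center_wavelength_nm: float,
                             axial_resolution_um: float) -> float:
    """Optical FWHM bandwidth (nm) a Gaussian source needs for the given
    axial resolution: delta_lambda = (2 ln2/pi) lambda0^2 / delta_z."""
    if center_wavelength_nm <= 0 or axial_resolution_um <= 0:
        raise ValueError("wavelength and resolution must be > 0")
    dz_nm = axial_resolution_um * 1e3
    return TWO_LN2_OVER_PI * center_wavelength_nm ** 2 / dz_nm


def bandwidth_scaling_factor(wavelength_factor: float) -> float:
    """Bandwidth multiplier that holds axial resolution when the centre
    wavelength is scaled by ``wavelength_factor`` (quadratic: doubling the
    wavelength needs fourfold bandwidth)."""
    if wavelength_factor <= 0:
        raise ValueError("wavelength_factor must be > 0")
    return wavelength_factor ** 2
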