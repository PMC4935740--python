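"""Surgical error evaluation: per-hole drilling deviation and global
reduction error.

Two error products are computed, mirroring how model-surgery outcomes are
reported in navigation studies:

* **Drilling deviation** — the Euclidean distance (mm) between a drilled
  and re-registered screw hole and its planned position, tabulated per
  fracture site and hole and summarized by site means and a grand
  mean +/- SD.

* **Global reduction error** — after aligning the post-operative image to
  the pre-operative plan on un-operated bone (ICP on the fixed regions),
  the residual rigid discrepancy between the planned and achieved zygoma:
  displacement is the distance between the two geometric centers, rotation
  the extrinsic X-Y-Z Euler angles of their relative orientation.  Signed
  angles are reported, but only absolute-value summaries are meaningful
  across cases since the sign depends on the (arbitrary) axis conventions.

Summary statistics default to the population standard deviation (divide by
n) taken over absolute values; the sample (n-1) denominator is available via
``ddof=1``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .geometry import EulerAngles, RigidTransform, geometric_center
from .io import TriMesh
from .registration import IcpParams, RegistrationResult, icp

__all__ = [
    "DeviationTable",
    "ErrorReport",
    "drilling_deviation",
    "global_error",
    "summarize_table1",
    "summarize_table2",
]


def drilling_deviation(registered_hole, planned_hole) -> float:
    """Euclidean distance (mm) between a drilled-and-registered screw hole
    and its planned position, both in the image frame."""
    a = np.asarray(registered_hole, dtype=float).reshape(3)
    b = np.asarray(planned_hole, dtype=float).reshape(3)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValidationError("hole positions must be finite")
    return float(np.linalg.norm(a - b))


@dataclass
class DeviationTable:
    """Drilling deviations indexed by (fracture site, hole)."""

    data: pd.DataFrame  # columns: site, hole, deviation_mm

    def __post_init__(self):
        required = {"site", "hole", "deviation_mm"}
        if not required.issubset(self.data.columns):
            raise ValidationError(
                f"deviation table needs columns {sorted(required)}")
        if len(self.data) == 0:
            raise ValidationError("deviation table is empty")
        if (self.data["deviation_mm"] < 0).any():
            raise ValidationError("deviations must be non-negative")

    @classmethod
    def from_values(cls, values) -> "DeviationTable":
        """Build from a (sites x holes) array of deviations (mm)."""
        arr = np.atleast_2d(np.asarray(values, dtype=float))
        recs = [(s + 1, h + 1, arr[h, s])
                for s in range(arr.shape[1]) for h in range(arr.shape[0])]
        return cls(pd.DataFrame(recs, columns=["site", "hole", "deviation_mm"]))

    def site_means(self) -> pd.Series:
        return self.data.groupby("site")["deviation_mm"].mean()

    def grand_mean(self) -> float:
        return float(self.data["deviation_mm"].mean())

    def grand_sd(self, ddof: int = 0) -> float:
        return float(self.data["deviation_mm"].std(ddof=ddof))


@dataclass(frozen=True)
class ErrorReport:
    """Global reduction error for one case: geometric-center displacement
    (mm) and signed per-axis rotation (degrees)."""

    displacement: float
    rotation: EulerAngles
    body_alignment: RegistrationResult | None = None
    zygoma_fit: RegistrationResult | None = None

    def __post_init__(self):
        if self.displacement < 0:
            raise ValidationError("displacement must be non-negative")

    def as_row(self) -> dict[str, float]:
        return {
            "displacement_mm": self.displacement,
            "rot_x_deg": self.rotation.rx,
            "rot_y_deg": self.rotation.ry,
            "rot_z_deg": self.rotation.rz,
        }


def global_error(preop_plan: TriMesh, postop: TriMesh,
                 fixed_region_label: str = "fixed",
                 zygoma_label: str = "zygoma",
                 params: IcpParams | None = None) -> ErrorReport:
    """Global reduction error between a pre-operative plan and the
    post-operative result.

    1. Align the post-operative mesh to the plan using only the un-operated
       (fixed) region, by ICP.
    2. Estimate the residual rigid transform carrying the achieved zygoma
       onto the planned zygoma (ICP between the two zygoma clouds after
       step 1).
    3. Displacement is the distance between the achieved and planned zygoma
       geometric centers (after step 1); rotation is the Euler decomposition
       of the residual transform, in the image frame.
    """
    for mesh, name in ((preop_plan, "pre-op plan"), (postop, "post-op")):
        if mesh.face_labels is None:
            raise ValidationError(f"{name} mesh has no region labels")
        for label in (fixed_region_label, zygoma_label):
            if label not in mesh.labels():
                raise ValidationError(
                    f"{name} mesh lacks region {label!r}; has {mesh.labels()}")

    body = icp(postop.region_vertices(fixed_region_label),
               preop_plan.region_vertices(fixed_region_label), params=params)
    achieved = body.transform.apply(postop.region_vertices(zygoma_label))
    planned = preop_plan.region_vertices(zygoma_label)

    rel = icp(achieved, planned, params=params)
    displacement = float(np.linalg.norm(
        geometric_center(achieved) - geometric_center(planned)))
    return ErrorReport(displacement=displacement,
                       rotation=rel.transform.to_euler(),
                       body_alignment=body, zygoma_fit=rel)


def summarize_table1(table: DeviationTable, ddof: int = 0) -> pd.DataFrame:
    """Per-site mean deviations plus the grand mean and grand SD, one row
    per summary statistic."""
    means = table.site_means()
    rows = [{"statistic": f"site_{int(s)}_mean_mm", "value": float(v)}
            for s, v in means.items()]
    rows.append({"statistic": "grand_mean_mm", "value": table.grand_mean()})
    rows.append({"statistic": "grand_sd_mm", "value": table.grand_sd(ddof=ddof)})
    return pd.DataFrame(rows)


def summarize_table2(reports, ddof: int = 0,
                     absolute: bool = True) -> pd.DataFrame:
    """Column-wise summary of global-error reports: mean and standard
    deviation of the |displacement| and per-axis |rotation| columns.

    *reports* is a list of :class:`ErrorReport` or a DataFrame with columns
    displacement_mm, rot_x_deg, rot_y_deg, rot_z_deg.  With ``absolute``
    (the default) both statistics are taken over absolute values.
    """
    if isinstance(reports, pd.DataFrame):
        df = reports
    else:
        reports = list(reports)
        if not reports:
            raise ValidationError("no error reports to summarize")
        df = pd.DataFrame([r.as_row() for r in reports])
    cols = ["displacement_mm", "rot_x_deg", "rot_y_deg", "rot_z_deg"]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"error table lacks columns {missing}")
    vals = df[cols].abs() if absolute else df[cols]
    return pd.DataFrame({
        "column": cols,
        "abs_mean": [float(vals[c].mean()) for c in cols],
        "abs_sd": [float(vals[c].std(ddof=ddof)) for c in cols],
    })
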