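"""Arteriolar function: basal tone and percent-of-maximal-dilation curves.

Isolated arterioles pressurized without flow develop spontaneous (basal)
tone; a vasodilator dose series is then applied and the fully relaxed
diameter is obtained with sodium nitroprusside (SNP).  Two normalizations
reduce the raw diameters:

* basal tone = 100 · resting / maximal diameter (percent of maximal
  diameter at rest);
* percent maximal dilation at a dose = 100 · (d − d_rest)/(d_max − d_rest),
  i.e. every diameter change is expressed relative to the SNP dilation.

Curve summaries report per-dose group means ± SEM; no sigmoid is fitted —
the dose axis is handled as log10 molar concentration throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import GridError

__all__ = [
    "DoseResponseRecord",
    "CurveSummary",
    "basal_tone",
    "percent_max_dilation",
    "summarize_curves",
    "records_to_frame",
    "records_from_frame",
]


@dataclass(frozen=True)
class DoseResponseRecord:
    """Diameter measurements for one vessel across a dose series."""

    vessel_id: str
    condition: str  # e.g. NT / HT
    treatment: str  # none / l-NAME
    resting_diameter_um: float
    max_diameter_um: float  # SNP diameter at fixed intraluminal pressure
    doses_log10_m: tuple[float, ...]
    diameters_um: tuple[float, ...]

    def __post_init__(self) -> None:
        if not 0 < self.resting_diameter_um <= self.max_diameter_um:
            raise ValueError("require 0 < resting diameter <= maximal diameter")
        doses = np.asarray(self.doses_log10_m)
        if doses.size and np.any(np.diff(doses) <= 0):
            raise ValueError("doses must be strictly increasing")
        if len(self.doses_log10_m) != len(self.diameters_um):
            raise ValueError("one diameter per dose required")

    @property
    def group(self) -> tuple[str, str]:
        return (self.condition, self.treatment)


@dataclass
class CurveSummary:
    """Group-level curve and tone summary.

    ``per_dose`` has columns (condition, treatment, dose_log10_m, mean_pct,
    sem_pct, n); ``tone`` has (condition, treatment, mean_pct, sem_pct, n).
    Groups of a single vessel get SEM 0 and are listed in ``flags``.
    """

    per_dose: pd.DataFrame
    tone: pd.DataFrame
    flags: list[str]


def basal_tone(resting_d: float, max_d: float) -> float:
    """Basal tone as percent of maximal diameter: 100 · resting / max."""
    if not 0 < resting_d <= max_d:
        raise ValueError("require 0 < resting_d <= max_d")
    return min(100.0 * resting_d / max_d, 100.0)


def percent_max_dilation(d: float, d_baseline: float, d_max: float) -> float:
    """Diameter change as percent of the SNP (maximal) dilation."""
    if d_max <= d_baseline:
        raise ValueError("require d_max > d_baseline")
    return 100.0 * (d - d_baseline) / (d_max - d_baseline)


def _mean_sem(values: np.ndarray) -> tuple[float, float]:
    n = values.size
    mean = float(values.mean())
    sem = 0.0 if n < 2 else float(values.std(ddof=1) / math.sqrt(n))
    return mean, sem


def summarize_curves(records: list[DoseResponseRecord]) -> CurveSummary:
    """Reduce per-vessel records to group mean ± SEM curves and tones."""
    if not records:
        raise ValueError("no records to summarize")
    flags: list[str] = []
    groups: dict[tuple[str, str], list[DoseResponseRecord]] = {}
    for rec in records:
        groups.setdefault(rec.group, []).append(rec)

    dose_rows, tone_rows = [], []
    for key in sorted(groups):
        members = groups[key]
        doses = members[0].doses_log10_m
        for rec in members[1:]:
            if rec.doses_log10_m != doses:
                raise GridError(
                    f"vessel {rec.vessel_id} uses a different dose grid "
                    f"than group {key}"
                )
        n = len(members)
        if n == 1:
            flags.append(f"group {key}: single vessel, SEM reported as 0")
        tones = np.array(
            [basal_tone(r.resting_diameter_um, r.max_diameter_um) for r in members]
        )
        mean, sem = _mean_sem(tones)
        tone_rows.append(
            {
                "condition": key[0],
                "treatment": key[1],
                "mean_pct": mean,
                "sem_pct": sem,
                "n": n,
            }
        )
        pct = np.array(
            [
                [
                    percent_max_dilation(
                        d, r.resting_diameter_um, r.max_diameter_um
                    )
                    for d in r.diameters_um
                ]
                for r in members
            ]
        )
        for j, dose in enumerate(doses):
            mean, sem = _mean_sem(pct[:, j])
            dose_rows.append(
                {
                    "condition": key[0],
                    "treatment": key[1],
                    "dose_log10_m": dose,
                    "mean_pct": mean,
                    "sem_pct": sem,
                    "n": n,
                }
            )
    return CurveSummary(
        per_dose=pd.DataFrame(dose_rows), tone=pd.DataFrame(tone_rows), flags=flags
    )


def records_to_frame(records: list[DoseResponseRecord]) -> pd.DataFrame:
    """Long-format table: one row per (vessel, measurement).

    ``row_type`` is resting / dose / snp; ``dose_log10_M`` is empty (NaN)
    for resting and SNP rows.
    """
    rows = []
    for r in records:
        rows.append(
            {
                "vessel_id": r.vessel_id,
                "condition": r.condition,
                "treatment": r.treatment,
                "dose_log10_M": np.nan,
                "diameter_um": r.resting_diameter_um,
                "row_type": "resting",
            }
        )
        for dose, d in zip(r.doses_log10_m, r.diameters_um):
            rows.append(
                {
                    "vessel_id": r.vessel_id,
                    "condition": r.condition,
                    "treatment": r.treatment,
                    "dose_log10_M": dose,
                    "diameter_um": d,
                    "row_type": "dose",
                }
            )
        rows.append(
            {
                "vessel_id": r.vessel_id,
                "condition": r.condition,
                "treatment": r.treatment,
                "dose_log10_M": np.nan,
                "diameter_um": r.max_diameter_um,
                "row_type": "snp",
            }
        )
    return pd.DataFrame(rows)


def records_from_frame(frame: pd.DataFrame) -> list[DoseResponseRecord]:
    """Inverse of :func:`records_to_frame`."""
    records = []
    for vessel_id, sub in frame.groupby("vessel_id", sort=True):
        resting = sub.loc[sub.row_type == "resting", "diameter_um"]
        snp = sub.loc[sub.row_type == "snp", "diameter_um"]
        if len(resting) != 1 or len(snp) != 1:
            raise ValueError(f"vessel {vessel_id}: need one resting and one snp row")
        dose_rows = sub[sub.row_type == "dose"].sort_values("dose_log10_M")
        records.append(
            DoseResponseRecord(
                vessel_id=str(vessel_id),
                condition=str(sub["condition"].iloc[0]),
                treatment=str(sub["treatment"].iloc[0]),
                resting_diameter_um=float(resting.iloc[0]),
                max_diameter_um=float(snp.iloc[0]),
                doses_log10_m=tuple(dose_rows["dose_log10_M"]),
                diameters_um=tuple(dose_rows["diameter_um"]),
            )
        )
    return records
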