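"""Measurement tables, reference-normalized ratios and donor selection.

The donor-selection workflow: measure each subject's standardized bone
set (length/width/height along the body axes, surface area, volume, per
bone), divide every value by the corresponding value of a *reference*
subject (typically the damaged fossil), and pick as reconstruction donor
the subject whose ratios sit closest to 1 — by default the subject with
the smallest arithmetic mean ratio over all 15 cells.

A reference dataset ships with the package
(``data/mtpj_first_ray_measurements.csv``): published linear and
volumetric measurements of the first-ray bones (first metatarsal,
proximal and distal hallucial phalanx) of ten professional athletes and
the *H. naledi* fossil, standardized to metatarsal length 100, together
with the published normalized ratios
(``data/mtpj_first_ray_ratio_reference.csv``) used by the test-suite as
a cross-check.  On that dataset the middle-distance runner has the
smallest mean ratio (1.0127) and is the selected donor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError
from .frame import StandardizedSet, extents
from .mesh import mass_properties

__all__ = [
    "BONES",
    "MEASURES",
    "MeasurementRecord",
    "RatioTable",
    "measure_subject",
    "records_to_frame",
    "load_measurements",
    "ratio_table",
    "donor_score",
    "select_donor",
    "reference_measurements_path",
    "reference_ratio_path",
]

BONES = ("metatarsal", "proximal_phalanx", "distal_phalanx")
MEASURES = ("length", "width", "height", "surface_area", "volume")


@dataclass
class MeasurementRecord:
    """One bone's morphometrics (mm / mm^2 / mm^3, standardized scale)."""

    subject: str
    bone: str
    length: float
    width: float
    height: float
    surface_area: float
    volume: float
    principal_moments: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.bone not in BONES:
            raise InputError(f"bone must be one of {BONES}, got {self.bone!r}")
        for measure in MEASURES:
            if getattr(self, measure) <= 0:
                raise InputError(f"{measure} must be > 0 for {self.subject}/{self.bone}")


def measure_subject(standardized: StandardizedSet, subject: str = "subject"):
    """Extents and mass properties for each bone of a standardized set.

    Returns three :class:`MeasurementRecord`; the metatarsal length is
    100 by construction.
    """
    records = []
    for bone_name, bone in standardized.bones.items():
        length, width, height = extents(bone)
        mp = mass_properties(bone)
        records.append(
            MeasurementRecord(
                subject=subject,
                bone=bone_name,
                length=length,
                width=width,
                height=height,
                surface_area=mp.surface_area,
                volume=mp.volume,
                principal_moments=mp.principal_moments,
            )
        )
    return records


def records_to_frame(records) -> pd.DataFrame:
    rows = [
        {
            "subject": r.subject,
            "bone": r.bone,
            **{m: getattr(r, m) for m in MEASURES},
        }
        for r in records
    ]
    return pd.DataFrame(rows)


def load_measurements(path: str | Path) -> pd.DataFrame:
    """Read a tidy measurement CSV (subject, bone, then the five measures)."""
    p = Path(path)
    if not p.is_file():
        raise InputError(f"measurement table not found: {p}")
    df = pd.read_csv(p)
    missing = {"subject", "bone", *MEASURES} - set(df.columns)
    if missing:
        raise InputError(f"measurement table {p} lacks columns: {sorted(missing)}")
    return df


def reference_measurements_path() -> Path:
    """Packaged athlete + fossil first-ray measurement table."""
    return Path(resources.files("boneframe.data") / "mtpj_first_ray_measurements.csv")


def reference_ratio_path() -> Path:
    """Packaged published ratio table matching the reference measurements."""
    return Path(resources.files("boneframe.data") / "mtpj_first_ray_ratio_reference.csv")


def _round_half_up(value: float, decimals: int) -> float:
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass
class RatioTable:
    """Per-(subject, bone, measure) ratios against a reference subject.

    ``cells`` is a tidy DataFrame with full-precision ``ratio`` values;
    displays are conventionally rounded half-up to 4 decimals
    (:meth:`rounded`).  The reference subject's row is identically 1.
    """

    reference: str
    cells: pd.DataFrame

    def subjects(self):
        return list(dict.fromkeys(self.cells["subject"]))

    def row(self, subject: str) -> np.ndarray:
        sel = self.cells[self.cells["subject"] == subject]
        if sel.empty:
            raise InputError(f"unknown subject {subject!r}")
        return sel["ratio"].to_numpy()

    def rounded(self, decimals: int = 4) -> pd.DataFrame:
        out = self.cells.copy()
        out["ratio"] = [_round_half_up(v, decimals) for v in out["ratio"]]
        return out

    def pivot(self, decimals: int | None = 4) -> pd.DataFrame:
        """Wide subject x (bone, measure) view in canonical order."""
        src = self.rounded(decimals) if decimals is not None else self.cells
        wide = src.pivot(index="subject", columns=["bone", "measure"], values="ratio")
        wide = wide.reindex(columns=pd.MultiIndex.from_product([BONES, MEASURES]))
        return wide.loc[self.subjects()]


def ratio_table(measurements: pd.DataFrame, reference: str) -> RatioTable:
    """Divide every subject's measures by the reference subject's.

    Every subject must provide all three bones and all five measures;
    gaps are reported together in the error message.
    """
    df = measurements.copy()
    subjects = list(dict.fromkeys(df["subject"]))
    if reference not in subjects:
        raise InputError(f"reference subject {reference!r} not in table")
    gaps = []
    for subj in subjects:
        for bone in BONES:
            sel = df[(df["subject"] == subj) & (df["bone"] == bone)]
            if len(sel) != 1:
                gaps.append(f"{subj}/{bone}")
            elif sel[list(MEASURES)].isna().to_numpy().any():
                gaps.append(f"{subj}/{bone} (missing measure)")
    if gaps:
        raise InputError("incomplete measurement table; gaps: " + ", ".join(gaps))

    ref = df[df["subject"] == reference].set_index("bone")
    rows = []
    for subj in subjects:
        sub = df[df["subject"] == subj].set_index("bone")
        for bone in BONES:
            for measure in MEASURES:
                denom = float(ref.loc[bone, measure])
                if denom <= 0:
                    raise InputError(f"reference {measure} for {bone} is not positive")
                rows.append(
                    {
                        "subject": subj,
                        "bone": bone,
                        "measure": measure,
                        "ratio": float(sub.loc[bone, measure]) / denom,
                    }
                )
    return RatioTable(reference=reference, cells=pd.DataFrame(rows))


def donor_score(table: RatioTable, subject: str, method: str = "mean_ratio") -> float:
    """Scalar closeness-to-reference score (lower is closer).

    ``mean_ratio`` — arithmetic mean of the subject's 15 ratios (the
    "smallest mean value" criterion; the default).
    ``mean_abs_dev`` — mean of ``|ratio - 1|``, a deviation-from-unity
    alternative.  The two orderings can differ: a subject whose bones
    are alternately oversized and undersized may average near 1 while
    deviating strongly cell by cell.
    """
    row = table.row(subject)
    if method == "mean_ratio":
        return float(row.mean())
    if method == "mean_abs_dev":
        return float(np.abs(row - 1.0).mean())
    raise InputError(f"unknown scoring method {method!r}")


def select_donor(table: RatioTable, method: str = "mean_ratio") -> str:
    """Non-reference subject with the lowest score; ties keep input order."""
    candidates = [s for s in table.subjects() if s != table.reference]
    if not candidates:
        raise InputError("ratio table has no non-reference subjects")
    scores = [donor_score(table, s, method) for s in candidates]
    best = int(np.argmin(scores))
    if sum(np.isclose(scores, scores[best], rtol=0, atol=1e-12)) > 1:
        warnings.warn("donor score tie; keeping first subject in input order",
                      stacklevel=2)
    return candidates[best]
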