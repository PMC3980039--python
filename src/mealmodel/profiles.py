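"""Mixed-meal tolerance test (MMTT) profiles: data model, CSV I/O and the
elementary glucose arithmetic used throughout the pipeline.

A frequently sampled MMTT draws blood at -15 and 0 min (pre-meal) and at
30, 60, 90, 120 and 180 min after the start of a standardised liquid meal,
measuring plasma glucose (mmol/l), insulin (pmol/l) and C-peptide (nmol/l).
Urine is collected from -15 to +180 min for urinary glucose excretion (UGE).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MmttProfile",
    "MealSpec",
    "read_mmtt_csv",
    "write_mmtt_csv",
    "trapezoid_auc",
    "mpg_0_3h",
    "body_surface_area",
]

#: default FS-MMTT sampling schedule, minutes relative to meal start
SCHEDULE = (-15.0, 0.0, 30.0, 60.0, 90.0, 120.0, 180.0)


@dataclass(frozen=True)
class MealSpec:
    """Standardised test meal (liquid supplement)."""

    carbohydrate_g: float = 100.0
    energy_kJ: float = 2930.0
    duration_min: float = 15.0

    def __post_init__(self) -> None:
        if self.carbohydrate_g <= 0:
            raise ValueError("carbohydrate_g must be positive")


@dataclass
class MmttProfile:
    """One subject-visit's timed samples plus urine glucose and anthropometrics.

    Missing insulin (and, exceptionally, glucose or C-peptide) values are
    stored as NaN, never as zero. Times are minutes relative to meal start,
    strictly increasing within [-15, 180].
    """

    subject_id: str
    visit: str  # "baseline" | "endpoint"
    arm: str
    times: np.ndarray
    glucose: np.ndarray
    insulin: np.ndarray
    cpeptide: np.ndarray
    uge_0_3h: float | None = None  # grams over the -15..180 min collection
    weight: float = float("nan")  # kg
    height: float = float("nan")  # cm
    age: float = float("nan")  # years
    sex: str = "M"
    diabetic: bool = True

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.glucose = np.asarray(self.glucose, dtype=float)
        self.insulin = np.asarray(self.insulin, dtype=float)
        self.cpeptide = np.asarray(self.cpeptide, dtype=float)
        n = self.times.size
        for name in ("glucose", "insulin", "cpeptide"):
            if getattr(self, name).size != n:
                raise ValueError(
                    f"{self.subject_id}/{self.visit}: {name} length != times length"
                )
        if n and (self.times.min() < -15 - 1e-9 or self.times.max() > 180 + 1e-9):
            raise ValueError(
                f"{self.subject_id}/{self.visit}: times outside [-15, 180]"
            )
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(
                f"{self.subject_id}/{self.visit}: times not strictly increasing"
            )
        bad_g = np.where(self.glucose <= 0)[0]
        bad_g = bad_g[~np.isnan(self.glucose[bad_g])]
        if bad_g.size:
            t = self.times[bad_g[0]]
            raise ValueError(
                f"{self.subject_id}/{self.visit}: non-positive glucose at t={t:g}"
            )
        bad_c = np.where(self.cpeptide < 0)[0]
        bad_c = bad_c[~np.isnan(self.cpeptide[bad_c])]
        if bad_c.size:
            t = self.times[bad_c[0]]
            raise ValueError(
                f"{self.subject_id}/{self.visit}: negative C-peptide at t={t:g}"
            )
        bad_i = np.where(self.insulin < 0)[0]
        bad_i = bad_i[~np.isnan(self.insulin[bad_i])]
        if bad_i.size:
            t = self.times[bad_i[0]]
            raise ValueError(
                f"{self.subject_id}/{self.visit}: negative insulin at t={t:g}"
            )
        if self.uge_0_3h is not None and not math.isnan(self.uge_0_3h):
            if self.uge_0_3h < 0:
                raise ValueError(f"{self.subject_id}/{self.visit}: negative UGE")
        if self.visit not in ("baseline", "endpoint"):
            raise ValueError(f"unknown visit label {self.visit!r}")
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M' or 'F', got {self.sex!r}")

    # -- convenience -------------------------------------------------------

    def fasting_value(self, channel: str) -> float:
        """Fasting (pre-meal) level: mean of the -15 and 0 min samples where
        both exist, else the single available one."""
        values = getattr(self, channel)
        pre = values[self.times <= 0]
        pre = pre[~np.isnan(pre)]
        if pre.size == 0:
            raise ValueError(f"no pre-meal {channel} sample")
        return float(pre.mean())

    def value_at(self, channel: str, t: float) -> float:
        values = getattr(self, channel)
        idx = np.where(np.isclose(self.times, t))[0]
        if idx.size == 0:
            raise ValueError(f"no sample at t={t:g}")
        return float(values[idx[0]])

    def n_insulin_postmeal(self) -> int:
        """Number of non-missing insulin samples in [0, 180]."""
        mask = (self.times >= 0) & ~np.isnan(self.insulin)
        return int(mask.sum())

    def bsa(self) -> float:
        return body_surface_area(self.weight, self.height)


def body_surface_area(weight: float, height: float) -> float:
    """DuBois-DuBois body surface area in m^2 (weight kg, height cm)."""
    if not (weight > 0 and height > 0):
        raise ValueError("weight and height must be positive")
    return 0.007184 * weight**0.425 * height**0.725


def trapezoid_auc(
    times: Sequence[float], values: Sequence[float], window: tuple[float, float] = (0.0, 180.0)
) -> float:
    """Trapezoid-rule AUC of ``values`` over ``window`` (default 0-180 min).

    Samples outside the window (the -15 min one in particular) are excluded;
    missing values are dropped pairwise. Requires >= 2 usable points.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    mask = (t >= window[0] - 1e-9) & (t <= window[1] + 1e-9) & ~np.isnan(v)
    t, v = t[mask], v[mask]
    if t.size < 2:
        raise ValueError("trapezoid AUC needs at least two usable points")
    return float(np.trapezoid(v, t))


def mpg_0_3h(profile: MmttProfile) -> float:
    """Mean plasma glucose over the 3 h postprandial window: AUC(0-180)/180."""
    t = profile.times
    g = profile.glucose
    usable = (t >= 0) & ~np.isnan(g)
    if not (np.any(np.isclose(t[usable], 0.0)) and np.any(np.isclose(t[usable], 180.0))):
        raise ValueError("mpg_0_3h requires glucose at both t=0 and t=180")
    span = t[usable].max() - t[usable].min()
    return trapezoid_auc(t, g) / span


# ----------------------------------------------------------------------------
# CSV I/O
#
# Long-format samples table: subject_id, visit, arm, time_min, glucose,
# insulin, cpeptide.  Companion metadata table keyed by (subject_id, visit):
# uge_0_3h, weight, height, age, sex, diabetic.  Both comma-separated, UTF-8,
# header row, decimal point; units fixed (mmol/l, pmol/l, nmol/l, g, kg, cm).
# ----------------------------------------------------------------------------

_SAMPLE_COLS = ["subject_id", "visit", "arm", "time_min", "glucose", "insulin", "cpeptide"]
_META_COLS = ["subject_id", "visit", "uge_0_3h", "weight", "height", "age", "sex", "diabetic"]


def read_mmtt_csv(path, metadata_path=None) -> list[MmttProfile]:
    """Read MMTT profiles from a long-format samples CSV (+ optional
    companion metadata CSV). Returns one profile per (subject_id, visit),
    rows sorted by time; blank numeric cells become NaN."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = [c for c in _SAMPLE_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"samples CSV missing columns: {missing}")
    meta = None
    if metadata_path is not None:
        meta = pd.read_csv(metadata_path, dtype={"subject_id": str})
        meta = meta.set_index(["subject_id", "visit"])

    dup = df.duplicated(subset=["subject_id", "visit", "time_min"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            f"duplicate sample for subject {row['subject_id']} "
            f"visit {row['visit']} at t={row['time_min']:g}"
        )

    profiles: list[MmttProfile] = []
    for (sid, visit), grp in df.groupby(["subject_id", "visit"], sort=True):
        grp = grp.sort_values("time_min")
        kwargs: dict = {}
        if meta is not None and (sid, visit) in meta.index:
            m = meta.loc[(sid, visit)]
            uge = m.get("uge_0_3h", float("nan"))
            kwargs = dict(
                uge_0_3h=None if pd.isna(uge) else float(uge),
                weight=float(m.get("weight", float("nan"))),
                height=float(m.get("height", float("nan"))),
                age=float(m.get("age", float("nan"))),
                sex=str(m.get("sex", "M")),
                diabetic=bool(m.get("diabetic", True)),
            )
        profiles.append(
            MmttProfile(
                subject_id=str(sid),
                visit=str(visit),
                arm=str(grp["arm"].iloc[0]),
                times=grp["time_min"].to_numpy(float),
                glucose=grp["glucose"].to_numpy(float),
                insulin=grp["insulin"].to_numpy(float),
                cpeptide=grp["cpeptide"].to_numpy(float),
                **kwargs,
            )
        )
    return profiles


def write_mmtt_csv(profiles: Iterable[MmttProfile], path, metadata_path=None) -> None:
    """Inverse of :func:`read_mmtt_csv`; round-trips all fields."""
    rows, meta_rows = [], []
    for p in profiles:
        for i in range(p.times.size):
            rows.append(
                dict(
                    subject_id=p.subject_id,
                    visit=p.visit,
                    arm=p.arm,
                    time_min=p.times[i],
                    glucose=p.glucose[i],
                    insulin=p.insulin[i],
                    cpeptide=p.cpeptide[i],
                )
            )
        meta_rows.append(
            dict(
                subject_id=p.subject_id,
                visit=p.visit,
                uge_0_3h=float("nan") if p.uge_0_3h is None else p.uge_0_3h,
                weight=p.weight,
                height=p.height,
                age=p.age,
                sex=p.sex,
                diabetic=p.diabetic,
            )
        )
    pd.DataFrame(rows, columns=_SAMPLE_COLS).to_csv(path, index=False)
    if metadata_path is not None:
        pd.DataFrame(meta_rows, columns=_META_COLS).to_csv(metadata_path, index=False)
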