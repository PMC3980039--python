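"""End-to-end analysis: profiles -> per-subject-visit indices -> trial stats.

Also writes the tidy results CSV (one row per subject-visit) and a JSON run
manifest (config hash, seed, software version, kinetic coefficients) for
auditability.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from typing import Iterable

import pandas as pd

from . import __version__
from .kinetics import kinetic_parameters
from .profiles import MealSpec, MmttProfile, mpg_0_3h
from .secretion import (
    BetaCellIndices,
    FitConfig,
    SecretionFit,
    fit_secretion_model,
    glucose_sensitivity,
    insulin_clearance,
    isr_at_glucose,
    total_insulin_secretion,
)
from .sensitivity import sensitivity_indices
from .trial import ChangeRecord, TrialResult, ancova_lsm_change, kruskal_wallis_change

__all__ = [
    "beta_cell_indices",
    "analyze_profiles",
    "indices_frame",
    "trial_change_records",
    "analyze_trial",
    "write_results",
]

#: parameters analysed on the log scale (log-normal across subjects)
LOG_SCALE_PARAMS = ("glucose_sensitivity", "ogis", "ogis_c")
#: parameter compared with Kruskal-Wallis instead of ANCOVA
NONPARAMETRIC_PARAMS = ("rate_sensitivity",)


def beta_cell_indices(
    profile: MmttProfile,
    meal: MealSpec = MealSpec(),
    config: FitConfig = FitConfig(),
    fit: SecretionFit | None = None,
) -> BetaCellIndices:
    """All per-subject-visit indices for one profile (fitting the secretion
    model unless a fit is supplied)."""
    if fit is None:
        kin = kinetic_parameters(profile.age, profile.sex, profile.bsa(), profile.diabetic)
        fit = fit_secretion_model(profile, kin, config)
    flags = list(fit.flags)
    g_min, g_max = fit.glucose_range
    if not fit.dose_response.contains(9.0):
        flags.append("ISR@9 extrapolated outside observed glucose range")
    total = total_insulin_secretion(fit)
    try:
        sens = sensitivity_indices(profile, meal)
        ogis, ogis_c = sens.ogis, sens.ogis_c
    except ValueError:
        ogis = ogis_c = None
        flags.append("OGIS not computable (missing 0/90/120 samples)")
    return BetaCellIndices(
        subject_id=profile.subject_id,
        visit=profile.visit,
        arm=profile.arm,
        glucose_sensitivity=glucose_sensitivity(fit.dose_response, g_min, g_max),
        isr_at_9=isr_at_glucose(fit.dose_response, 9.0),
        rate_sensitivity=fit.rate_sensitivity,
        total_secretion=total,
        insulin_clearance=insulin_clearance(total, profile),
        ogis=ogis,
        ogis_c=ogis_c,
        mpg_0_3h=mpg_0_3h(profile),
        flags=tuple(flags),
    )


def analyze_profiles(
    profiles: Iterable[MmttProfile],
    meal: MealSpec = MealSpec(),
    config: FitConfig = FitConfig(),
) -> list[BetaCellIndices]:
    return [beta_cell_indices(p, meal, config) for p in profiles]


def indices_frame(indices: Iterable[BetaCellIndices]) -> pd.DataFrame:
    rows = []
    for ix in indices:
        d = dataclasses.asdict(ix)
        d["flags"] = ";".join(d["flags"])
        rows.append(d)
    return pd.DataFrame(rows)


def trial_change_records(
    df: pd.DataFrame, parameter: str, hba1c_high: dict | None = None
) -> list[ChangeRecord]:
    """Complete-case change records for one parameter from an indices table
    (columns subject_id, visit, arm, <parameter>). ``hba1c_high`` maps
    subject_id to the baseline glycaemic-control stratum (default False)."""
    hba1c_high = hba1c_high or {}
    wide = df.pivot_table(
        index=["subject_id", "arm"], columns="visit", values=parameter, aggfunc="first"
    ).reset_index()
    records = []
    for _, row in wide.iterrows():
        b, e = row.get("baseline"), row.get("endpoint")
        if pd.isna(b) or pd.isna(e):
            continue  # complete-case analysis
        records.append(
            ChangeRecord(
                subject_id=row["subject_id"],
                arm=row["arm"],
                baseline_value=float(b),
                endpoint_value=float(e),
                baseline_hba1c_high=bool(hba1c_high.get(row["subject_id"], False)),
            )
        )
    return records


def analyze_trial(
    df: pd.DataFrame,
    comparator_arm: str,
    parameters: tuple[str, ...] = (
        "isr_at_9",
        "glucose_sensitivity",
        "rate_sensitivity",
        "total_secretion",
        "insulin_clearance",
        "ogis",
        "ogis_c",
    ),
    hba1c_high: dict | None = None,
) -> dict:
    """Per-parameter between-arm analysis of an indices table.

    Returns {parameter: TrialResult} for ANCOVA parameters and
    {parameter: (H, p)} for the Kruskal-Wallis ones.
    """
    out: dict = {}
    for param in parameters:
        records = trial_change_records(df, param, hba1c_high)
        if not records:
            continue
        if param in NONPARAMETRIC_PARAMS:
            out[param] = kruskal_wallis_change(records)
        else:
            out[param] = ancova_lsm_change(
                records, comparator_arm,
                log_scale=param in LOG_SCALE_PARAMS, parameter=param,
            )
    return out


def write_results(
    indices: Iterable[BetaCellIndices], out_csv, manifest_path=None,
    config: FitConfig = FitConfig(), seed: int | None = None,
) -> pd.DataFrame:
    """Write the tidy per-subject-visit results CSV and a JSON run manifest."""
    df = indices_frame(indices)
    df.to_csv(out_csv, index=False)
    if manifest_path is not None:
        cfg = dataclasses.asdict(config)
        manifest = dict(
            software="mealmodel",
            version=__version__,
            seed=seed,
            config=cfg,
            config_hash=hashlib.sha256(
                json.dumps(cfg, sort_keys=True, default=str).encode()
            ).hexdigest()[:16],
            n_rows=int(len(df)),
        )
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=2)
    return df
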