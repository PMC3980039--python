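"""Between-arm statistics on baseline-to-endpoint changes of model parameters.

Each parameter is analysed by ANCOVA with the endpoint value as response,
the baseline value and a binary baseline glycaemic-control stratum
(HbA1c >= 9.0 %) as covariates, and treatment arm as the factor. Least
squares means (LSM) are adjusted endpoint predictions at grand-mean
covariates; the change LSM subtracts the pooled baseline mean, and arm
contrasts are comparator-subtracted with residual-df t intervals.

Log-normally distributed parameters (beta cell glucose sensitivity, the
OGIS indices) are additionally analysed on the log scale: point estimates
are reported from the raw-scale model, significance from the log-scale one.
Rate sensitivity, which is highly non-normal, is compared across arms with
a Kruskal-Wallis test on the changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

__all__ = ["ChangeRecord", "ArmEstimate", "ArmContrast", "TrialResult",
           "ancova_lsm_change", "kruskal_wallis_change"]


@dataclass(frozen=True)
class ChangeRecord:
    subject_id: str
    arm: str
    baseline_value: float
    endpoint_value: float
    baseline_hba1c_high: bool  # HbA1c >= 9.0 %

    def __post_init__(self) -> None:
        if not (np.isfinite(self.baseline_value) and np.isfinite(self.endpoint_value)):
            raise ValueError(f"{self.subject_id}: non-finite value")


@dataclass(frozen=True)
class ArmEstimate:
    arm: str
    n: int
    lsm_change: float
    sem: float


@dataclass(frozen=True)
class ArmContrast:
    """Comparator-subtracted LSM change for one arm."""

    arm: str
    comparator: str
    diff: float
    sem: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass(frozen=True)
class TrialResult:
    parameter: str
    arms: tuple[ArmEstimate, ...]
    contrasts: tuple[ArmContrast, ...]
    log_scale: bool
    test: str

    def __post_init__(self) -> None:
        for c in self.contrasts:
            if not (c.ci_low - 1e-12 <= c.diff <= c.ci_high + 1e-12):
                raise ValueError("CI must contain the point estimate")


def _design(df: pd.DataFrame, arms: list[str], log_scale: bool):
    """Endpoint ~ baseline + hba1c stratum + arm (treatment-coded).

    A covariate that is constant across the dataset carries no information
    and would make the design singular; such columns are dropped (e.g. all
    subjects in the same glycaemic-control stratum)."""
    base = np.log(df["baseline"].to_numpy()) if log_scale else df["baseline"].to_numpy()
    y = np.log(df["endpoint"].to_numpy()) if log_scale else df["endpoint"].to_numpy()
    X = [np.ones(len(df))]
    names = ["const"]
    for name, col in (("baseline", base), ("hba1c_high", df["hba1c_high"].to_numpy(float))):
        if np.ptp(col) > 0:
            X.append(col)
            names.append(name)
    for arm in arms[1:]:
        X.append((df["arm"] == arm).to_numpy(float))
        names.append(f"arm[{arm}]")
    X = np.column_stack(X)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # identify the offending column for the error message
        full = np.linalg.matrix_rank(X)
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == full:
                raise ValueError(f"rank-deficient ANCOVA design: column {names[j]!r}")
        raise ValueError("rank-deficient ANCOVA design")
    return y, X, names


def ancova_lsm_change(
    records: list[ChangeRecord], comparator_arm: str, log_scale: bool = False,
    parameter: str = "",
) -> TrialResult:
    """ANCOVA of endpoint on baseline + HbA1c stratum + arm.

    LSM per arm is the model prediction at grand-mean covariates; the change
    LSM subtracts the pooled baseline mean. Contrasts are vs
    ``comparator_arm`` with two-sided t tests on residual df. With
    ``log_scale`` the test is run on log-transformed values while point
    estimates stay on the original scale.
    """
    if not records:
        raise ValueError("no records")
    df = pd.DataFrame(
        dict(
            arm=[r.arm for r in records],
            baseline=[r.baseline_value for r in records],
            endpoint=[r.endpoint_value for r in records],
            hba1c_high=[r.baseline_hba1c_high for r in records],
        )
    )
    arms = sorted(df["arm"].unique())
    if comparator_arm not in arms:
        raise ValueError(f"comparator arm {comparator_arm!r} absent from data")
    arms = [comparator_arm] + [a for a in arms if a != comparator_arm]
    counts = df["arm"].value_counts()
    if len(arms) < 2:
        raise ValueError("ANCOVA needs >= 2 arms")
    if counts.min() < 3:
        raise ValueError(f"arm {counts.idxmin()!r} has fewer than 3 records")
    if log_scale and ((df["baseline"] <= 0).any() or (df["endpoint"] <= 0).any()):
        raise ValueError("log-scale analysis requires positive values")

    def fit(logit: bool):
        y, X, names = _design(df, arms, logit)
        model = sm.OLS(y, X).fit()
        return model, names

    raw_model, names = fit(False)
    p_model = raw_model
    if log_scale:
        p_model, _ = fit(True)

    # LSM at grand-mean covariates
    gm = {"const": 1.0, "baseline": df["baseline"].mean(),
          "hba1c_high": df["hba1c_high"].astype(float).mean()}
    baseline_mean = df["baseline"].mean()
    arm_estimates = []
    for arm in arms:
        row = np.array([
            gm.get(name, 1.0 if name == f"arm[{arm}]" else 0.0) for name in names
        ])
        lsm = float(row @ raw_model.params)
        sem = float(np.sqrt(row @ raw_model.cov_params() @ row))
        arm_estimates.append(
            ArmEstimate(arm=arm, n=int(counts[arm]), lsm_change=lsm - baseline_mean, sem=sem)
        )

    tcrit = scipy.stats.t.ppf(0.975, raw_model.df_resid)
    contrasts = []
    for j, arm in enumerate(arms[1:]):
        k = names.index(f"arm[{arm}]")
        diff = float(raw_model.params[k])
        sem = float(raw_model.bse[k])
        pval = float(p_model.pvalues[k])
        contrasts.append(
            ArmContrast(
                arm=arm, comparator=comparator_arm, diff=diff, sem=sem,
                ci_low=diff - tcrit * sem, ci_high=diff + tcrit * sem, p_value=pval,
            )
        )
    return TrialResult(
        parameter=parameter,
        arms=tuple(arm_estimates),
        contrasts=tuple(contrasts),
        log_scale=log_scale,
        test="ANCOVA" + (" (log-scale test)" if log_scale else ""),
    )


def kruskal_wallis_change(records: list[ChangeRecord]) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and chi-square p-value on the
    endpoint-minus-baseline changes across arms."""
    df = pd.DataFrame(
        dict(arm=[r.arm for r in records],
             change=[r.endpoint_value - r.baseline_value for r in records])
    )
    groups = [g["change"].to_numpy() for _, g in df.groupby("arm")]
    if len(groups) < 2 or min(len(g) for g in groups) < 2:
        raise ValueError("Kruskal-Wallis needs >= 2 arms with >= 2 records each")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = scipy.stats.kruskal(*groups)
    return float(h), float(p)
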