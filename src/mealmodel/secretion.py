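"""Beta cell secretion model and derived indices.

Insulin secretion (pmol min^-1 m^-2) is modelled as the sum of two
components:

* a glucose dose-response f(G) modulated by a time-varying potentiation
  factor P(t) — gastrointestinal hormones, neural effects and prolonged
  hyperglycaemia all potentiate secretion — constrained to average unity
  over the 3 h test so that f retains the scale of the secretory response;
* a derivative component k_d * max(dG/dt, 0) capturing anticipatory (early)
  insulin release while glucose is rising; its single coefficient is the
  rate sensitivity.

    ISR(t) = P(t) * f(G(t)) + rate_sensitivity * max(dG/dt, 0)

The model is fitted to measured glucose and C-peptide by regularised least
squares: C-peptide residuals (the model ISR convolved through two-compartment
C-peptide kinetics) plus roughness penalties on the dose-response and the
potentiation factor. Glucose is represented by a smoothing spline whose
derivative feeds the rate component. Smoothing weights are selected so the
relative residual SDs approach the expected measurement error (~1 % for
glucose, ~4 % for C-peptide).

Derived indices: beta cell glucose sensitivity (mean slope of f over the
observed glucose range), ISR at 9 mmol/l glucose, rate sensitivity, total
insulin secretion (integral of ISR over 0-180 min) and insulin clearance
(total secretion / insulin AUC, subjects with >= 5 insulin samples only).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline, make_smoothing_spline
from scipy.optimize import lsq_linear

from .kinetics import CpKinetics, steady_state_isr, transfer_matrix
from .profiles import MmttProfile, trapezoid_auc

__all__ = [
    "DoseResponse",
    "FitConfig",
    "SecretionFit",
    "BetaCellIndices",
    "SmoothingSelection",
    "UnidentifiableError",
    "fit_secretion_model",
    "select_smoothing",
    "secretion_rate",
    "glucose_sensitivity",
    "isr_at_glucose",
    "total_insulin_secretion",
    "insulin_clearance",
    "pooled_residual_sd",
]

ISR_GRID = np.arange(0.0, 181.0, 5.0)  # the 5-min reporting grid (37 nodes)


class UnidentifiableError(ValueError):
    """Raised when the dose-response cannot be identified from the data."""


@dataclass(frozen=True)
class DoseResponse:
    """Piecewise-linear ISR-vs-glucose dose-response f(G)."""

    glucose_knots: np.ndarray  # mmol/l, increasing
    isr_values: np.ndarray  # pmol min^-1 m^-2 at each knot

    def __post_init__(self) -> None:
        k = np.asarray(self.glucose_knots, float)
        v = np.asarray(self.isr_values, float)
        object.__setattr__(self, "glucose_knots", k)
        object.__setattr__(self, "isr_values", v)
        if k.size < 2 or v.size != k.size:
            raise ValueError("dose-response needs >= 2 matching knots/values")
        if np.any(np.diff(k) <= 0):
            raise ValueError("glucose knots must be strictly increasing")

    def __call__(self, g) -> np.ndarray:
        """Evaluate f at glucose ``g``; linear extrapolation beyond the knots."""
        k, v = self.glucose_knots, self.isr_values
        g = np.asarray(g, dtype=float)
        out = np.interp(g, k, v)
        lo, hi = g < k[0], g > k[-1]
        if np.any(lo):
            s = (v[1] - v[0]) / (k[1] - k[0])
            out = np.where(lo, v[0] + s * (g - k[0]), out)
        if np.any(hi):
            s = (v[-1] - v[-2]) / (k[-1] - k[-2])
            out = np.where(hi, v[-1] + s * (g - k[-1]), out)
        return out if out.ndim else float(out)

    def contains(self, g: float) -> bool:
        return bool(self.glucose_knots[0] - 1e-12 <= g <= self.glucose_knots[-1] + 1e-12)


@dataclass(frozen=True)
class FitConfig:
    """Fitting options. Smoothing bounds bracket the admissible regularisation
    weights searched by the selection scan; residual targets are percent-of-signal."""

    n_interior_knots: int = 4
    potentiation_spacing: float = 30.0  # min between potentiation nodes
    grid_step: float = 1.0  # min, internal simulation grid
    glucose_residual_target: float = 1.0  # % of signal
    cpeptide_residual_target: float = 4.0  # % of signal
    residual_band: float = 0.30  # +/- relative tolerance around each target
    lam_glucose_bounds: tuple[float, float] = (1e-4, 3e2)
    lam_secretion_bounds: tuple[float, float] = (1e-7, 3e-1)
    potentiation_penalty_weight: float = 1.0
    max_iter: int = 200
    tol: float = 1e-6
    min_pairs: int = 5
    bisect_iter: int = 18
    refine: bool = True  # joint Gauss-Newton polish after the alternation


@dataclass
class SecretionFit:
    """A fitted secretion model for one subject-visit."""

    dose_response: DoseResponse
    potentiation: np.ndarray  # unit-mean P(t) on the 5-min grid
    rate_sensitivity: float  # pmol m^-2 (mmol/l)^-1
    isr_grid: np.ndarray  # pmol min^-1 m^-2 on the 5-min grid
    glucose_spline: GlucoseCurve  # continuous G(t); .derivative() gives dG/dt
    residual_sd_glucose: float  # % of signal
    residual_sd_cpeptide: float  # % of signal
    smoothing_factors: dict
    converged: bool
    flags: tuple[str, ...] = ()
    glucose_range: tuple[float, float] = (0.0, 0.0)  # fitted G(t) min/max, mmol/l
    glucose_residuals: np.ndarray = field(default_factory=lambda: np.empty(0))
    cpeptide_residuals: np.ndarray = field(default_factory=lambda: np.empty(0))
    df_glucose: float = 0.0  # effective dof of the glucose spline
    df_cpeptide: float = 0.0  # effective dof of the secretion-model fit


@dataclass
class BetaCellIndices:
    """Per-subject-visit summary of beta cell function and insulin sensitivity."""

    subject_id: str
    visit: str
    arm: str
    glucose_sensitivity: float  # pmol min^-1 m^-2 (mmol/l)^-1
    isr_at_9: float  # pmol min^-1 m^-2
    rate_sensitivity: float  # pmol m^-2 (mmol/l)^-1
    total_secretion: float  # nmol/m^2 over 3 h
    insulin_clearance: float | None  # l min^-1 m^-2; None if < 5 insulin samples
    ogis: float | None  # ml min^-1 m^-2
    ogis_c: float | None  # ml min^-1 m^-2
    mpg_0_3h: float  # mmol/l
    flags: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# glucose smoothing spline
# ---------------------------------------------------------------------------

def _dof_corrected_sd(residuals: np.ndarray, df: float) -> float:
    """Unbiased relative residual SD: RMS inflated for the effective degrees
    of freedom absorbed by the fit, sqrt(sum r^2 / (n - df))."""
    n = residuals.size
    df_eff = min(df, n - 1.0)
    return float(np.sqrt(np.sum(residuals**2) / (n - df_eff)))


class GlucoseCurve:
    """Continuous glucose signal G(t): the fasting level before the meal
    (the pre-meal state is a steady state by design of the test) and a
    smoothing spline through the post-meal samples, anchored at the fasting
    value at t = 0."""

    def __init__(self, fasting: float, spline: BSpline):
        self.fasting = fasting
        self.spline = spline

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        out = np.where(t <= 0, self.fasting, np.asarray(self.spline(np.clip(t, 0.0, None))))
        return out if out.ndim else float(out)

    def derivative(self) -> "GlucoseCurveDerivative":
        return GlucoseCurveDerivative(self.spline.derivative())


class GlucoseCurveDerivative:
    def __init__(self, dspline):
        self._dspline = dspline

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        out = np.where(t <= 0, 0.0, np.asarray(self._dspline(np.clip(t, 0.0, None))))
        return out if out.ndim else float(out)


@dataclass
class GlucoseSplineFit:
    curve: GlucoseCurve
    lam: float
    rel_residuals: np.ndarray  # (fit - obs)/obs at the sample times
    df: float  # effective degrees of freedom (smoother-matrix trace)
    sd_pct: float  # dof-corrected relative residual SD, %
    flags: tuple[str, ...]


def fit_glucose_spline(
    times: np.ndarray, glucose: np.ndarray, config: FitConfig = FitConfig()
) -> GlucoseSplineFit:
    """Fit the continuous glucose signal, selecting the spline penalty so the
    dof-corrected relative residual SD matches the expected glucose
    measurement error (~1 %).

    The dof correction (inflating the residual RMS by the smoother's
    effective degrees of freedom, estimated as the smoother-matrix trace)
    makes the criterion an unbiased noise estimate, so selection does not
    have to distort the curve just to push raw residuals up. If even the
    largest admissible weight leaves the SD below target (noise-free data)
    the boundary weight is returned with a flag; likewise at the lower
    boundary when the target cannot be reached from above.
    """
    t = np.asarray(times, float)
    g = np.asarray(glucose, float)
    keep = ~np.isnan(g)
    t, g = t[keep], g[keep]
    n = t.size
    pre = t <= 0
    if not pre.any():
        raise ValueError("no pre-meal glucose sample")
    target = config.glucose_residual_target / 100.0
    lo, hi = config.lam_glucose_bounds

    post = np.where(~pre)[0]

    def build(gv: np.ndarray, lam: float) -> tuple[GlucoseCurve, np.ndarray]:
        fasting = float(gv[pre].mean())
        # mirror the post-meal samples around t = 0: the even fit has zero
        # slope at the meal start, making G(t) C^1 against the flat pre-meal
        # segment (glucose cannot jump into a finite rise instantaneously)
        tp, yp = t[~pre], gv[~pre]
        ts = np.concatenate([-tp[::-1], [0.0], tp])
        ys = np.concatenate([yp[::-1], [fasting], yp])
        spl = make_smoothing_spline(ts, ys, lam=2 * lam)
        curve = GlucoseCurve(fasting, spl)
        return curve, np.asarray(curve(t), float)

    def evaluate(lam: float):
        # residuals and dof are accounted on the post-meal samples: the
        # pre-meal pair is a duplicate informing the fasting level, and its
        # within-pair scatter is assay noise on a constant, not curve misfit
        curve, vals = build(g, lam)
        rel = (vals[post] - g[post]) / g[post]
        # smoother-matrix trace by direct perturbation (n is tiny)
        df = 0.0
        eps = 1e-6 * float(np.mean(g))
        for j in post:
            g2 = g.copy()
            g2[j] += eps
            _, vals2 = build(g2, lam)
            df += (vals2[j] - vals[j]) / eps
        return curve, rel, df, _dof_corrected_sd(rel, df)

    def pack(lam, curve, rel, df, sd, flags) -> GlucoseSplineFit:
        return GlucoseSplineFit(curve, lam, rel, df, 100 * sd, tuple(flags))

    # the corrected SD is not monotone in the weight near the interpolation
    # end (residual dof collapse), so scan the admissible range for the
    # closest match and refine locally between the bracketing neighbours
    grid = list(np.geomspace(lo, hi, 9))
    evals = [evaluate(lam) for lam in grid]
    best_i = min(range(len(grid)), key=lambda i: abs(evals[i][3] - target))
    lam, (curve, rel, df, sd) = grid[best_i], evals[best_i]
    for lo_i, hi_i in ((best_i - 1, best_i), (best_i, best_i + 1)):
        if 0 <= lo_i and hi_i < len(grid):
            sd_lo, sd_hi = evals[lo_i][3], evals[hi_i][3]
            if (sd_lo - target) * (sd_hi - target) < 0:
                llo, lhi = np.log(grid[lo_i]), np.log(grid[hi_i])
                for _ in range(8):
                    lmid = float(np.exp(0.5 * (llo + lhi)))
                    emid = evaluate(lmid)
                    if abs(emid[3] - target) < abs(sd - target):
                        lam, (curve, rel, df, sd) = lmid, emid
                    if (emid[3] - target) * (sd_lo - target) > 0:
                        llo = np.log(lmid)
                    else:
                        lhi = np.log(lmid)
                break
    flags = []
    if sd < target * (1 - config.residual_band) and lam >= grid[-1]:
        flags.append("glucose smoothing at upper bound")
    elif sd > target * (1 + config.residual_band) and lam <= grid[0]:
        flags.append("glucose smoothing at lower bound")
    return pack(lam, curve, rel, df, sd, flags)


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------

def _hat_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Piecewise-linear hat-function basis, x clamped to the knot span."""
    xc = np.clip(x, knots[0], knots[-1])
    B = np.zeros((x.size, knots.size))
    for j, k in enumerate(knots):
        left = knots[j - 1] if j > 0 else k
        right = knots[j + 1] if j < knots.size - 1 else k
        up = (xc - left) / (k - left) if k > left else np.ones_like(xc)
        down = (right - xc) / (right - k) if right > k else np.ones_like(xc)
        B[:, j] = np.clip(np.minimum(up, down), 0.0, 1.0)
    return B


def _second_diff_matrix(knots: np.ndarray) -> np.ndarray:
    """Second-divided-difference rows (approximate curvature) for uneven knots,
    scaled by the mean spacing squared so rows are dimensionless in x."""
    n = knots.size
    if n < 3:
        return np.zeros((0, n))
    hbar = float(np.mean(np.diff(knots)))
    D = np.zeros((n - 2, n))
    for i in range(1, n - 1):
        h1 = knots[i] - knots[i - 1]
        h2 = knots[i + 1] - knots[i]
        c = 2.0 / (h1 + h2)
        D[i - 1, i - 1] = c / h1
        D[i - 1, i] = -c * (1 / h1 + 1 / h2)
        D[i - 1, i + 1] = c / h2
    return D * hbar**2


class _FitWorkspace:
    """Per-profile precomputation shared across smoothing-weight evaluations."""

    def __init__(self, profile: MmttProfile, kinetics: CpKinetics, config: FitConfig):
        self.profile = profile
        self.kinetics = kinetics
        self.config = config
        t = profile.times
        usable = ~np.isnan(profile.glucose) & ~np.isnan(profile.cpeptide)
        if int(usable.sum()) < config.min_pairs:
            raise ValueError(
                f"{profile.subject_id}/{profile.visit}: fewer than "
                f"{config.min_pairs} usable (glucose, C-peptide) pairs"
            )
        g_obs = profile.glucose[~np.isnan(profile.glucose)]
        if np.ptp(g_obs) < 1e-9:
            raise UnidentifiableError(
                f"{profile.subject_id}/{profile.visit}: dose-response "
                "unidentifiable (constant glucose)"
            )
        self.g_obs = g_obs
        self.sample_times = t[usable]
        self.c_obs = profile.cpeptide[usable]

        # glucose spline (its own smoothing selection)
        gfit = fit_glucose_spline(t, profile.glucose, config)
        self.spline = gfit.curve
        self.lam_glucose = gfit.lam
        self.glucose_sd = gfit.sd_pct
        self.glucose_residuals = gfit.rel_residuals
        self.df_glucose = gfit.df
        self.flags = list(gfit.flags)

        # fine simulation grid
        h = config.grid_step
        self.tt = np.arange(-15.0, 180.0 + h / 2, h)
        self.G = np.asarray(self.spline(self.tt), float)
        self.dGplus = np.clip(np.asarray(self.spline.derivative()(self.tt), float), 0.0, None)

        # dose-response knots spread evenly over the fitted glucose range
        # (even spacing keeps every segment's slope well conditioned, which
        # matters when ISR@9 must be extrapolated below the observed range)
        g_lo, g_hi = float(self.G.min()), float(self.G.max())
        if g_hi - g_lo < 1e-9:
            raise UnidentifiableError("dose-response unidentifiable (constant glucose)")
        knots = np.linspace(g_lo, g_hi, config.n_interior_knots + 2)
        self.knots = knots
        self.Bg = _hat_basis(self.G, knots)  # fine-grid glucose basis
        self.Df = _second_diff_matrix(knots)

        # potentiation nodes over [0, 180]; P clamped to P(0) before the meal
        self.tp = np.arange(0.0, 180.0 + 1e-9, config.potentiation_spacing)
        self.Bp = _hat_basis(self.tt, self.tp)
        self.Dp = _second_diff_matrix(self.tp)
        w = np.full(self.tp.size, config.potentiation_spacing)
        w[0] = w[-1] = config.potentiation_spacing / 2
        self.p_mean_weights = w / 180.0  # trapezoid time-average weights

        # C-peptide transfer operator, rows interpolated at the sample times
        bsa = profile.bsa()
        M, hom = transfer_matrix(kinetics, self.tt, bsa)
        idx = np.searchsorted(self.tt, self.sample_times) - 1
        idx = np.clip(idx, 0, self.tt.size - 2)
        wgt = (self.sample_times - self.tt[idx]) / h
        self.rows = (1 - wgt)[:, None] * M[idx] + wgt[:, None] * M[idx + 1]
        self.hom = (1 - wgt) * hom[idx] + wgt * hom[idx + 1]
        self.c0 = profile.fasting_value("cpeptide")
        self.fscale = max(steady_state_isr(self.c0, kinetics, bsa), 1.0)

    # -- alternating regularised least squares ----------------------------

    def fit(self, lam_secretion: float, warm=None) -> dict:
        cfg = self.config
        nf, np_ = self.knots.size, self.tp.size
        y0 = (self.c_obs - self.hom * self.c0) / self.c_obs
        if warm is None:
            f = np.full(nf, self.fscale)
            p = np.ones(np_)
            r = 0.0
        else:
            f, p, r = warm["f"].copy(), warm["p"].copy(), warm["r"]

        sqlam_f = np.sqrt(lam_secretion) / self.fscale
        sqlam_p = np.sqrt(lam_secretion * cfg.potentiation_penalty_weight)
        converged = False
        for _ in range(cfg.max_iter):
            prev = np.concatenate([f, p, [r]])

            # (1) dose-response values and rate sensitivity, P fixed
            P_fine = self.Bp @ p
            cols = np.column_stack([P_fine[:, None] * self.Bg, self.dGplus])
            A = (self.rows @ cols) / self.c_obs[:, None]
            pen = np.zeros((self.Df.shape[0], nf + 1))
            pen[:, :nf] = sqlam_f * self.Df
            sol = lsq_linear(
                np.vstack([A, pen]),
                np.concatenate([y0, np.zeros(pen.shape[0])]),
                bounds=(np.zeros(nf + 1), np.full(nf + 1, np.inf)),
                method="bvls",
            )
            f, r = sol.x[:nf], float(sol.x[nf])

            # (2) potentiation nodes, f and r fixed
            f_fine = self.Bg @ f
            colsP = f_fine[:, None] * self.Bp
            offset = self.rows @ (r * self.dGplus)
            A = (self.rows @ colsP) / self.c_obs[:, None]
            yP = y0 - offset / self.c_obs
            pen = sqlam_p * self.Dp
            sol = lsq_linear(
                np.vstack([A, pen]),
                np.concatenate([yP, np.zeros(pen.shape[0])]),
                bounds=(np.full(np_, 0.01), np.full(np_, np.inf)),
                method="bvls",
            )
            p = sol.x

            # renormalise P to unit time-average; compensate in f so the
            # product P*f — and hence the ISR — is unchanged
            m = float(self.p_mean_weights @ p)
            p = p / m
            f = f * m

            cur = np.concatenate([f, p, [r]])
            denom = max(float(np.linalg.norm(prev)), 1e-12)
            if np.linalg.norm(cur - prev) / denom < cfg.tol:
                converged = True
                break

        if cfg.refine:
            # the alternation crawls along the weakly identified trade-off
            # between the rate component and a potentiation tilt; a joint
            # bounded Gauss-Newton polish settles it
            f, p, r, ok = self._refine(f, p, r, sqlam_f, sqlam_p)
            converged = converged or ok

        P_fine = self.Bp @ p
        isr_fine = P_fine * (self.Bg @ f) + r * self.dGplus
        pred = self.hom * self.c0 + self.rows @ isr_fine
        rel = (pred - self.c_obs) / self.c_obs
        return self._package(f, p, r, isr_fine, rel, lam_secretion, converged)

    def _refine(self, f, p, r, sqlam_f, sqlam_p):
        from scipy.optimize import least_squares

        nf, np_ = self.knots.size, self.tp.size
        Pf = sqlam_f * self.Df
        Pp = sqlam_p * self.Dp
        n_data = self.c_obs.size

        def split(theta):
            return theta[:nf], theta[nf : nf + np_], theta[-1]

        def residuals(theta):
            f_, p_, r_ = split(theta)
            isr = (self.Bp @ p_) * (self.Bg @ f_) + r_ * self.dGplus
            pred = self.hom * self.c0 + self.rows @ isr
            return np.concatenate([
                (pred - self.c_obs) / self.c_obs,
                Pf @ f_,
                Pp @ p_,
                [100.0 * (self.p_mean_weights @ p_ - 1.0)],  # unit-mean P
            ])

        def jacobian(theta):
            f_, p_, r_ = split(theta)
            P_fine = self.Bp @ p_
            f_fine = self.Bg @ f_
            J = np.zeros((n_data + Pf.shape[0] + Pp.shape[0] + 1, nf + np_ + 1))
            J[:n_data, :nf] = (self.rows @ (P_fine[:, None] * self.Bg)) / self.c_obs[:, None]
            J[:n_data, nf : nf + np_] = (
                self.rows @ (f_fine[:, None] * self.Bp)
            ) / self.c_obs[:, None]
            J[:n_data, -1] = (self.rows @ self.dGplus) / self.c_obs
            J[n_data : n_data + Pf.shape[0], :nf] = Pf
            J[n_data + Pf.shape[0] : -1, nf : nf + np_] = Pp
            J[-1, nf : nf + np_] = 100.0 * self.p_mean_weights
            return J

        lb = np.concatenate([np.zeros(nf), np.full(np_, 0.01), [0.0]])
        theta0 = np.maximum(np.concatenate([f, p, [r]]), lb + 1e-12)
        sol = least_squares(
            residuals, theta0, jac=jacobian, bounds=(lb, np.inf),
            xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=300,
        )
        f_, p_, r_ = split(sol.x)
        m = float(self.p_mean_weights @ p_)
        return f_ * m, p_ / m, float(r_), sol.status > 0

    def _package(self, f, p, r, isr_fine, rel, lam_secretion, converged) -> dict:
        cfg = self.config
        P_fine = self.Bp @ p

        # effective dof: hat-matrix traces of the two penalised linear
        # subproblems at the solution, minus one for the shared scale
        # (P unit-mean) counted in both
        def hat_trace(A: np.ndarray, pen: np.ndarray) -> float:
            ata = A.T @ A + pen.T @ pen + 1e-10 * np.eye(A.shape[1])
            return float(np.trace(A @ np.linalg.solve(ata, A.T)))

        cols_f = np.column_stack([P_fine[:, None] * self.Bg, self.dGplus])
        A_f = (self.rows @ cols_f) / self.c_obs[:, None]
        pen_f = np.zeros((self.Df.shape[0], cols_f.shape[1]))
        pen_f[:, : self.knots.size] = (np.sqrt(lam_secretion) / self.fscale) * self.Df
        cols_p = (self.Bg @ f)[:, None] * self.Bp
        A_p = (self.rows @ cols_p) / self.c_obs[:, None]
        pen_p = np.sqrt(lam_secretion * cfg.potentiation_penalty_weight) * self.Dp
        df = max(hat_trace(A_f, pen_f) + hat_trace(A_p, pen_p) - 1.0, 1.0)

        return dict(
            f=f, p=p, r=r, isr_fine=isr_fine, residuals=rel, df=df,
            cpeptide_sd=100 * _dof_corrected_sd(rel, df), converged=converged,
        )


def select_smoothing(
    profile: MmttProfile, kinetics: CpKinetics, config: FitConfig = FitConfig()
) -> "SmoothingSelection":
    """Select the regularisation weights by bisection so the fitted relative
    residual SDs approach the expected measurement errors (~1 % glucose,
    ~4 % C-peptide).

    The glucose weight is selected inside the spline fit; here the secretion
    penalty weight (shared by the dose-response and potentiation roughness
    terms) is bisected on the C-peptide residual SD. If the target cannot be
    reached inside the admissible bounds the boundary weight is returned
    with a warning flag.
    """
    ws = _FitWorkspace(profile, kinetics, config)
    return _select_on_workspace(ws)


@dataclass
class SmoothingSelection:
    lam_glucose: float
    lam_secretion: float
    achieved_glucose_sd: float  # %
    achieved_cpeptide_sd: float  # %
    flags: tuple[str, ...]
    _workspace: _FitWorkspace | None = field(default=None, repr=False)
    _result: dict | None = field(default=None, repr=False)


def _select_on_workspace(ws: _FitWorkspace) -> SmoothingSelection:
    # The dof-corrected residual SD is not monotone in the weight (as the
    # penalty vanishes the residual dof collapse), so the target is located
    # by a coarse scan over the admissible log-range, refined locally.
    cfg = ws.config
    target = cfg.cpeptide_residual_target
    lo, hi = cfg.lam_secretion_bounds
    flags = list(ws.flags)

    grid = np.geomspace(lo, hi, 9)
    results, warm = [], None
    for lam in grid[::-1]:  # largest first: smooth fits make good warm starts
        warm = ws.fit(float(lam), warm=warm)
        results.append((float(lam), warm))
    results.reverse()

    def score(item):
        lam, res = item
        # prefer the closest to target; among near-ties the smoother fit
        return (abs(res["cpeptide_sd"] - target), -np.log(lam))

    best_i = min(range(len(results)), key=lambda i: score(results[i]))
    lam, res = results[best_i]

    # local bisection between the neighbours bracketing the target
    for lo_i, hi_i in ((best_i - 1, best_i), (best_i, best_i + 1)):
        if 0 <= lo_i and hi_i < len(results):
            sd_lo = results[lo_i][1]["cpeptide_sd"]
            sd_hi = results[hi_i][1]["cpeptide_sd"]
            if (sd_lo - target) * (sd_hi - target) < 0:
                llo, lhi = np.log(results[lo_i][0]), np.log(results[hi_i][0])
                for _ in range(6):
                    lmid = float(np.exp(0.5 * (llo + lhi)))
                    mid = ws.fit(lmid, warm=res)
                    if abs(mid["cpeptide_sd"] - target) < abs(res["cpeptide_sd"] - target):
                        lam, res = lmid, mid
                    if (mid["cpeptide_sd"] - target) * (sd_lo - target) > 0:
                        llo = np.log(lmid)
                    else:
                        lhi = np.log(lmid)
                break

    if res["cpeptide_sd"] < target * (1 - cfg.residual_band) and lam >= grid[-1]:
        flags.append("secretion smoothing at upper bound")
    elif res["cpeptide_sd"] > target * (1 + cfg.residual_band) and lam <= grid[0]:
        flags.append("secretion smoothing at lower bound")

    return SmoothingSelection(
        ws.lam_glucose, lam, ws.glucose_sd, res["cpeptide_sd"], tuple(flags), ws, res
    )


def fit_secretion_model(
    profile: MmttProfile,
    kinetics: CpKinetics,
    config: FitConfig = FitConfig(),
    smoothing: SmoothingSelection | None = None,
) -> SecretionFit:
    """Fit the secretion model to one subject-visit.

    When ``smoothing`` is not supplied the regularisation weights are
    selected automatically (:func:`select_smoothing`). Optimiser stalls are
    reported through ``converged=False`` rather than raised.
    """
    if smoothing is None or smoothing._workspace is None:
        smoothing = select_smoothing(profile, kinetics, config)
    ws = smoothing._workspace
    res = smoothing._result
    if res is None:
        res = ws.fit(smoothing.lam_secretion)

    # report on the 5-min grid
    idx = np.searchsorted(ws.tt, ISR_GRID)
    isr_grid = np.clip(res["isr_fine"][idx], 0.0, None)
    pot_grid = (ws.Bp @ res["p"])[idx]
    dr = DoseResponse(ws.knots, res["f"])
    return SecretionFit(
        dose_response=dr,
        potentiation=pot_grid,
        rate_sensitivity=res["r"],
        isr_grid=isr_grid,
        glucose_spline=ws.spline,
        residual_sd_glucose=smoothing.achieved_glucose_sd,
        residual_sd_cpeptide=res["cpeptide_sd"],
        smoothing_factors={
            "glucose": smoothing.lam_glucose,
            "secretion": smoothing.lam_secretion,
        },
        converged=res["converged"],
        flags=smoothing.flags,
        glucose_range=(float(ws.g_obs.min()), float(ws.g_obs.max())),
        glucose_residuals=ws.glucose_residuals,
        cpeptide_residuals=res["residuals"],
        df_glucose=ws.df_glucose,
        df_cpeptide=res["df"],
    )


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------

def pooled_residual_sd(fits: "list[SecretionFit]", channel: str = "cpeptide") -> float:
    """Pooled dof-corrected relative residual SD (%) across fitted profiles:
    sqrt(sum of squared relative residuals / total residual dof)."""
    ss, dof = 0.0, 0.0
    for fit in fits:
        r = getattr(fit, f"{channel}_residuals")
        df = getattr(fit, f"df_{channel}")
        ss += float(np.sum(r**2))
        dof += r.size - min(df, r.size - 1.0)
    return 100.0 * float(np.sqrt(ss / dof))


def secretion_rate(fit: SecretionFit, t: float) -> float:
    """Model ISR at time ``t`` (min in [0, 180]): P(t)*f(G(t)) + rate
    component on rising glucose, clipped at zero."""
    if not (0 <= t <= 180):
        raise ValueError("t must lie in [0, 180] min")
    P = float(np.interp(t, ISR_GRID, fit.potentiation))
    G = float(fit.glucose_spline(t))
    dG = float(fit.glucose_spline.derivative()(t))
    isr = P * fit.dose_response(G) + fit.rate_sensitivity * max(dG, 0.0)
    return max(isr, 0.0)


def glucose_sensitivity(dr: DoseResponse, g_min: float, g_max: float) -> float:
    """Beta cell glucose sensitivity: mean slope of f over [g_min, g_max],
    i.e. the chord slope (f(g_max) - f(g_min)) / (g_max - g_min)."""
    if not g_max > g_min:
        raise ValueError("degenerate glucose range")
    return float((dr(g_max) - dr(g_min)) / (g_max - g_min))


def isr_at_glucose(dr: DoseResponse, g: float = 9.0) -> float:
    """ISR at a fixed glucose level (default 9 mmol/l); values outside the
    knot span are linearly extrapolated from the outermost segment (use
    ``dr.contains(g)`` to flag extrapolation)."""
    return float(dr(g))


def total_insulin_secretion(fit: SecretionFit) -> float:
    """Integral of ISR over the 3 h test, in nmol/m^2."""
    return float(np.trapezoid(fit.isr_grid, ISR_GRID)) / 1000.0


def insulin_clearance(total_secretion: float, profile: MmttProfile) -> float | None:
    """Total insulin secretion / plasma insulin AUC, in l min^-1 m^-2.

    Computed only for profiles with at least five non-missing insulin
    measurements (returns None otherwise, per the analysis filter).
    """
    n_ins = int((~np.isnan(profile.insulin)).sum())
    if n_ins < 5:
        return None
    auc = trapezoid_auc(profile.times, profile.insulin)  # pmol.min/l over 0-180
    if auc <= 0:
        raise ValueError("non-positive insulin AUC")
    return total_secretion * 1000.0 / auc
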