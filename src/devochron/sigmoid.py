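"""Log-sigmoid activation model and initiation-time estimation.

Zygotic activation of a gene is modelled on the log10 scale as

    log10(mRNA(t)) = a - b / (1 + exp(c * (t - t0)))

so the late-time asymptote is ``a`` (log10 of the maximal level), the
early-time asymptote is ``a - b`` (basal/maternal level), ``c`` is the
rise rate (per hour) and ``t0`` the time of half-rise, taken as the
operational gene initiation time. The model is fit by nonlinear least
squares on log10-transformed levels with a multi-start initialization:
a coarse grid over (t0, c) — where (a, b) are solved in closed form
because the model is linear in them — seeds local refinements, and the
best refined solution is kept. A 95% confidence interval for t0 comes
from the NLS parameter covariance with a t-distribution on (n - 4)
degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.special import expit
from scipy.stats import t as t_dist

from .errors import InsufficientDataError, NonIdentifiableError
from .types import ExpressionProfile

__all__ = [
    "log_sigmoid",
    "SigmoidFit",
    "fit_sigmoid",
    "fit_log_series",
    "initiation_time",
    "fitted_max_level",
    "goodness_of_fit",
    "is_zygotic",
    "fit_profiles",
]

#: Minimum fitted rise (log10 units) for a gene to count as zygotic
#: (~3.2-fold rise); genes below the gate are excluded from timing analyses.
ZYGOTIC_MIN_RISE = 0.5

_N_POINTS_MIN = 5


def log_sigmoid(t, a: float, b: float, c: float, t0: float):
    """Model value log10(mRNA) at time(s) ``t``."""
    t = np.asarray(t, dtype=float)
    # 1 / (1 + exp(c*(t-t0))) == expit(-c*(t-t0)); expit is overflow-safe.
    return a - b * expit(-c * (t - t0))


@dataclass
class SigmoidFit:
    """Fitted parameters with goodness of fit and t0 confidence bounds.

    ``identifiable`` is False for flat profiles (no measurable rise);
    ``converged`` is False when the optimizer failed from every start
    (the fit never raises for that).
    """

    a: float
    b: float
    c: float
    t0: float
    r2: float
    t0_ci: tuple[float, float]
    converged: bool
    identifiable: bool = True
    se_t0: float = float("nan")
    rss: float = float("nan")
    n_points: int = 0
    floor: float = float("nan")
    t_min: float = float("nan")
    t_max: float = float("nan")

    @property
    def dof(self) -> int:
        return self.n_points - 4

    @property
    def window_rise(self) -> float:
        """Modeled rise (log10 units) realized inside the sampled window.

        Equals b when the half-rise sits well inside the window but
        collapses toward 0 for degenerate fits that park t0 outside the
        data and inflate b along the flat tail of the sigmoid.
        """
        if not (self.identifiable and np.isfinite(self.c) and np.isfinite(self.t0)):
            return 0.0
        rise = self.b * (
            expit(-self.c * (self.t_min - self.t0))
            - expit(-self.c * (self.t_max - self.t0))
        )
        return float(rise) if np.isfinite(rise) else 0.0


def _closed_form_ab(y: np.ndarray, s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares (a, b) for y = a - b*s, vectorized over grid rows of s."""
    n = y.size
    Ss = s.sum(axis=-1)
    Sss = (s * s).sum(axis=-1)
    Sy = y.sum()
    Ssy = s @ y
    denom = Sss - Ss * Ss / n
    with np.errstate(divide="ignore", invalid="ignore"):
        b = (Ss * Sy / n - Ssy) / denom
        a = (Sy + Ss * b) / n
    return a, b


def _residual_factory(t: np.ndarray, y: np.ndarray):
    def resid(p):
        a, b, c, t0 = p
        return a - b * expit(-c * (t - t0)) - y

    def jac(p):
        a, b, c, t0 = p
        s = expit(-c * (t - t0))
        sp = s * (1.0 - s)
        J = np.empty((t.size, 4))
        J[:, 0] = 1.0
        J[:, 1] = -s
        J[:, 2] = b * sp * (t - t0)
        J[:, 3] = -b * c * sp
        return J

    return resid, jac


def fit_log_series(
    times: np.ndarray,
    y: np.ndarray,
    *,
    n_t0_starts: int = 16,
    n_c_starts: int = 12,
    n_refine: int = 3,
) -> SigmoidFit:
    """Fit the sigmoid to an already log10-transformed series.

    Grid-initialized multi-start NLS; see the module docstring. Bounds:
    c in (0, 10], b in (0, 10], t0 in [min(t)-5, max(t)+5], a free.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(y, dtype=float)
    n = t.size
    if n < _N_POINTS_MIN:
        raise InsufficientDataError(f"need >= {_N_POINTS_MIN} time points, got {n}")

    sst = float(((y - y.mean()) ** 2).sum())
    if np.ptp(y) < 1e-9:
        # Perfectly flat: b -> 0, t0 meaningless.
        return SigmoidFit(
            a=float(y.mean()), b=0.0, c=float("nan"), t0=float("nan"),
            r2=float("nan"), t0_ci=(float("nan"), float("nan")),
            converged=True, identifiable=False, rss=0.0, n_points=n,
            t_min=float(t.min()), t_max=float(t.max()),
        )

    t0_grid = np.linspace(t.min(), t.max(), n_t0_starts)
    c_grid = np.geomspace(0.08, 8.0, n_c_starts)
    cc, tt0 = np.meshgrid(c_grid, t0_grid)
    cc, tt0 = cc.ravel(), tt0.ravel()
    s = expit(-cc[:, None] * (t[None, :] - tt0[:, None]))
    a0, b0 = _closed_form_ab(y, s)
    rss0 = ((a0[:, None] - b0[:, None] * s - y[None, :]) ** 2).sum(axis=-1)
    rss0[~np.isfinite(rss0)] = np.inf
    order = np.argsort(rss0)

    lb = np.array([-np.inf, 1e-8, 1e-6, t.min() - 5.0])
    ub = np.array([np.inf, 10.0, 10.0, t.max() + 5.0])
    resid, jac = _residual_factory(t, y)

    best = None
    starts = 0
    seen_t0: set[float] = set()
    for idx in order:
        if starts >= n_refine:
            break
        if tt0[idx] in seen_t0:
            continue
        seen_t0.add(tt0[idx])
        starts += 1
        x0 = np.clip([a0[idx], b0[idx], cc[idx], tt0[idx]], lb, ub)
        try:
            sol = least_squares(
                resid, x0, jac=jac, bounds=(lb, ub), method="trf",
                xtol=1e-13, ftol=1e-13, gtol=1e-13, max_nfev=400,
            )
        except Exception:
            continue
        rss = float(2.0 * sol.cost)
        if best is None or rss < best[0]:
            best = (rss, sol)

    if best is None:
        return SigmoidFit(
            a=float("nan"), b=float("nan"), c=float("nan"), t0=float("nan"),
            r2=float("nan"), t0_ci=(float("nan"), float("nan")),
            converged=False, identifiable=False, n_points=n,
            t_min=float(t.min()), t_max=float(t.max()),
        )

    rss, sol = best
    a, b, c, t0 = (float(v) for v in sol.x)
    r2 = 1.0 - rss / sst if sst > 0 else float("nan")

    se_t0 = float("nan")
    ci = (float("nan"), float("nan"))
    dof = n - 4
    if dof > 0:
        J = jac(sol.x)
        try:
            cov = np.linalg.pinv(J.T @ J) * (rss / dof)
            var = cov[3, 3]
            if var >= 0:
                se_t0 = float(np.sqrt(var))
                half = float(t_dist.ppf(0.975, dof) * se_t0)
                ci = (t0 - half, t0 + half)
        except np.linalg.LinAlgError:
            pass

    return SigmoidFit(
        a=a, b=b, c=c, t0=t0, r2=r2, t0_ci=ci, converged=True,
        identifiable=bool(b > 1e-6), se_t0=se_t0, rss=rss, n_points=n,
        t_min=float(t.min()), t_max=float(t.max()),
    )


def fit_sigmoid(profile: ExpressionProfile, floor: float | None = None, **kwargs) -> SigmoidFit:
    """Fit the activation model to an expression profile.

    ``floor`` is the pseudo-level added before log10 (default: half the
    smallest positive level of the profile, so zeros are representable).
    """
    if len(profile) < _N_POINTS_MIN:
        raise InsufficientDataError(
            f"{profile.gene_id}/{profile.repeat_id}: need >= {_N_POINTS_MIN} points"
        )
    if not np.any(profile.levels > 0):
        raise NonIdentifiableError(
            f"{profile.gene_id}/{profile.repeat_id}: all-zero profile"
        )
    if floor is None:
        floor = profile.default_floor()
    y = np.log10(profile.levels + floor)
    fit = fit_log_series(profile.times, y, **kwargs)
    fit.floor = float(floor)
    return fit


def initiation_time(fit: SigmoidFit) -> tuple[float, tuple[float, float]]:
    """t0 and its 95% CI; (nan, (nan, nan)) propagates non-converged or
    non-identifiable fits."""
    if not fit.converged or not fit.identifiable:
        return float("nan"), (float("nan"), float("nan"))
    return fit.t0, fit.t0_ci


def fitted_max_level(fit: SigmoidFit) -> float:
    """Estimated maximal mRNA level, 10**a."""
    return float(10.0 ** fit.a)


def goodness_of_fit(profile: ExpressionProfile, fit: SigmoidFit, floor: float | None = None) -> float:
    """R^2 of the fit on the log10 scale (1 - SS_res/SS_tot about the mean)."""
    if floor is None:
        floor = fit.floor if np.isfinite(fit.floor) else profile.default_floor()
    y = np.log10(profile.levels + floor)
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0:
        warnings.warn(f"{profile.gene_id}: zero variance, R^2 undefined")
        return float("nan")
    yhat = log_sigmoid(profile.times, fit.a, fit.b, fit.c, fit.t0)
    return float(1.0 - ((y - yhat) ** 2).sum() / sst)


def is_zygotic(fit: SigmoidFit, min_rise: float = ZYGOTIC_MIN_RISE) -> bool:
    """Gate for measurable zygotic activation.

    Requires the rise the fitted model realizes inside the sampled
    window to reach ``min_rise`` log10 units (~3.2-fold); this equals
    the asymptotic b for genuine activation but rejects degenerate fits
    whose half-rise lies outside the measured window.
    """
    return bool(fit.converged and fit.identifiable and fit.window_rise >= min_rise)


def fit_profiles(
    profiles: list[ExpressionProfile],
    floor: float | None = None,
    min_rise: float = ZYGOTIC_MIN_RISE,
):
    """Fit every profile; returns a tidy table (one row per gene x repeat).

    Columns: gene_id, repeat_id, a, b, c, t0, t0_lo, t0_hi, se_t0, r2,
    n_points, converged, identifiable, zygotic.
    """
    import pandas as pd

    rows = []
    for p in profiles:
        fit = fit_sigmoid(p, floor=floor)
        rows.append(
            dict(
                gene_id=p.gene_id, repeat_id=p.repeat_id,
                a=fit.a, b=fit.b, c=fit.c, t0=fit.t0,
                t0_lo=fit.t0_ci[0], t0_hi=fit.t0_ci[1], se_t0=fit.se_t0,
                r2=fit.r2, n_points=fit.n_points,
                converged=fit.converged, identifiable=fit.identifiable,
                zygotic=is_zygotic(fit, min_rise),
            )
        )
    return pd.DataFrame(rows)
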