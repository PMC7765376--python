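"""Single-agent dose-response fitting: median-effect and 4-parameter logistic.

The median-effect model is the mass-action sigmoid

    fa / fu = (D / Dm)**m,        fu = 1 - fa,

with Dm the dose producing a half-maximal effect (fa = 0.5) and m the
sigmoidicity. Linearized, log(fa/fu) is a straight line in log D with slope m
and intercept -m*log(Dm); the linear fit is exact on model data and is the
default. A 4PL (Hill) fit on the viability scale is kept for QC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = [
    "MedianEffectFit",
    "HillFit",
    "FitError",
    "fit_median_effect",
    "dose_for_effect",
    "fit_hill",
    "ic50_in_combination",
    "DOSE_CEILING",
    "FA_CLAMP_EPS",
    "PLATEAU_DELTA",
]

#: Doses above this ceiling (molar) are excluded from fits; activity needing
#: more than 10 uM is not considered pharmacologically meaningful.
DOSE_CEILING = 1e-5

#: fa is clamped to [eps, 1-eps] before log-linearization; levels sitting at
#: the clamp boundary are censored rather than fitted.
FA_CLAMP_EPS = 1e-4

#: Saturated-plateau censoring: top dose levels are dropped while the fa
#: increment from the level below stays under this threshold. Drugs with a
#: partial-efficacy floor (emax > 0) plateau below fa = 1; keeping plateau
#: points flattens the log(fa/fu) line and badly inflates extrapolated Dx.
PLATEAU_DELTA = 0.04

#: Plateau censoring never reduces the fit below this many points.
PLATEAU_MIN_POINTS = 3


class FitError(ValueError):
    """A dose-response fit could not be performed (e.g. inactive compound)."""


@dataclass(frozen=True)
class MedianEffectFit:
    """Median-effect parameters (Dm, m) for one single agent."""

    Dm: float
    m: float
    n_points_used: int
    r_squared: float
    censored_levels: tuple[int, ...] = ()
    method: str = "linearized"

    def __post_init__(self) -> None:
        if not (self.Dm > 0):
            raise FitError(f"Dm must be > 0, got {self.Dm}")
        if self.n_points_used < 2:
            raise FitError("a median-effect fit needs >= 2 usable points")

    def fa(self, dose) -> np.ndarray:
        """Model fraction affected at the given dose(s)."""
        dose = np.asarray(dose, dtype=float)
        ratio = np.power(dose / self.Dm, self.m)
        return ratio / (1.0 + ratio)


@dataclass(frozen=True)
class HillFit:
    """4-parameter logistic on the viability scale (QC companion fit)."""

    ec50: float
    hill_slope: float
    e0: float
    emax: float
    rss: float
    converged: bool = True
    flags: tuple[str, ...] = ()

    def viability(self, dose) -> np.ndarray:
        dose = np.asarray(dose, dtype=float)
        with np.errstate(divide="ignore"):
            ratio = np.power(np.where(dose > 0, dose / self.ec50, 0.0), self.hill_slope)
        return self.emax + (self.e0 - self.emax) / (1.0 + ratio)


def _usable_points(doses, fa, eps, dose_ceiling, plateau_delta):
    doses = np.asarray(doses, dtype=float)
    fa = np.asarray(fa, dtype=float)
    if doses.shape != fa.shape:
        raise ValueError("doses and fa must have the same shape")
    fa_clamped = np.clip(fa, eps, 1.0 - eps)
    usable = (doses > 0) & (fa_clamped > eps) & (fa_clamped < 1.0 - eps)
    if dose_ceiling is not None:
        usable &= doses <= dose_ceiling
    if plateau_delta is not None and plateau_delta > 0:
        # walk down from the top dose, dropping levels on a saturated plateau
        order = np.flatnonzero(usable)[np.argsort(doses[np.flatnonzero(usable)])]
        keep = order.size
        while keep > PLATEAU_MIN_POINTS and (
            fa_clamped[order[keep - 1]] - fa_clamped[order[keep - 2]] < plateau_delta
        ):
            keep -= 1
            usable[order[keep]] = False
    censored = tuple(int(i) for i in np.flatnonzero(~usable))
    return doses, fa_clamped, usable, censored


def fit_median_effect(
    doses,
    fa,
    *,
    eps: float = FA_CLAMP_EPS,
    dose_ceiling: float | None = DOSE_CEILING,
    plateau_delta: float | None = PLATEAU_DELTA,
    method: str = "linearized",
) -> MedianEffectFit:
    """Fit (Dm, m) of the median-effect model to fraction-affected data.

    Censoring happens in three steps before the least-squares line of
    log(fa/fu) on log(D): fa values are clamped to ``[eps, 1-eps]`` and levels
    at the clamp boundary (fully inactive or fully effective wells, where
    log(fa/fu) is undefined) are excluded; doses above ``dose_ceiling`` are
    excluded; and top dose levels sitting on a saturated plateau (consecutive
    fa increments below ``plateau_delta``) are excluded while more than
    three points remain, because a partial-efficacy plateau is outside the
    median-effect model and corrupts the linearization. Raises
    :class:`FitError` with "inactive/unfittable" when fewer than two usable
    points remain.
    """
    doses, fa_c, usable, censored = _usable_points(
        doses, fa, eps, dose_ceiling, plateau_delta
    )
    if usable.sum() < 2:
        raise FitError(
            "inactive/unfittable: fewer than 2 dose levels with fa strictly inside (0, 1)"
        )
    x = np.log(doses[usable])
    y = np.log(fa_c[usable] / (1.0 - fa_c[usable]))
    # Weighted least squares with delta-method weights: var(logit fa) scales
    # as var(fa) / (fa (1 - fa))^2, so extreme-fa levels, whose logit is
    # noise-dominated, are downweighted by (fa (1 - fa))^2.
    w = (fa_c[usable] * (1.0 - fa_c[usable])) ** 2
    w = w / w.sum()
    xb = float(np.sum(w * x))
    yb = float(np.sum(w * y))
    sxx = float(np.sum(w * (x - xb) ** 2))
    sxy = float(np.sum(w * (x - xb) * (y - yb)))
    syy = float(np.sum(w * (y - yb) ** 2))
    if sxx <= 0:
        raise FitError("inactive/unfittable: degenerate dose spacing")
    m = sxy / sxx
    if not np.isfinite(m) or m <= 0:
        raise FitError("inactive/unfittable: non-positive median-effect slope")
    intercept = yb - m * xb
    dm = float(np.exp(-intercept / m))
    r2 = float(sxy**2 / (sxx * syy)) if syy > 0 else 1.0
    r2 = min(r2, 1.0)
    n_used = int(usable.sum())

    if method == "linearized":
        return MedianEffectFit(dm, m, n_used, r2, censored, "linearized")
    if method != "nonlinear":
        raise ValueError(f"unknown method {method!r}")

    d_fit, fa_fit = doses[usable], fa_c[usable]

    def resid(params):
        log_dm, mm = params
        ratio = np.exp(mm * (np.log(d_fit) - log_dm))
        return ratio / (1.0 + ratio) - fa_fit

    sol = optimize.least_squares(resid, x0=[np.log(dm), m], method="lm")
    log_dm, m_nl = sol.x
    if not np.isfinite(m_nl) or m_nl <= 0:
        raise FitError("inactive/unfittable: nonlinear fit diverged")
    ss_res = float(np.sum(sol.fun**2))
    ss_tot = float(np.sum((fa_fit - fa_fit.mean()) ** 2))
    r2_nl = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return MedianEffectFit(
        float(np.exp(log_dm)), float(m_nl), n_used, min(max(r2_nl, 0.0), 1.0),
        censored, "nonlinear",
    )


def dose_for_effect(fit: MedianEffectFit, fa_target: float) -> float:
    """Dose Dx producing effect level ``fa_target``: Dx = Dm*(fa/(1-fa))^(1/m)."""
    if not 0.0 < fa_target < 1.0:
        raise ValueError(f"fa_target must lie strictly in (0, 1), got {fa_target}")
    return float(fit.Dm * (fa_target / (1.0 - fa_target)) ** (1.0 / fit.m))


def fit_hill(doses, v) -> HillFit:
    """Nonlinear least-squares 4PL fit of viability against dose.

    Initialization is fixed (e0 = 1, emax = min v, ec50 = geometric-mid dose,
    slope = 1) so the fit is deterministic. Non-convergence (or a flat curve)
    returns a flagged fit whose ec50 falls back to the median-effect estimate
    when one is available.
    """
    doses = np.asarray(doses, dtype=float)
    v = np.asarray(v, dtype=float)
    if doses.shape != v.shape:
        raise ValueError("doses and v must have the same shape")
    if doses.size < 4:
        raise ValueError("a 4PL fit needs >= 4 points including vehicle")
    if not np.any(doses == 0):
        raise ValueError("a 4PL fit needs a vehicle (dose 0) point")

    nonzero = np.sort(doses[doses > 0])
    ec50_0 = float(np.exp(np.mean(np.log([nonzero[0], nonzero[-1]]))))
    p0 = [ec50_0, 1.0, 1.0, float(np.min(v))]

    def model(d, ec50, slope, e0, emax):
        with np.errstate(divide="ignore"):
            ratio = np.power(np.where(d > 0, d / ec50, 0.0), slope)
        return emax + (e0 - emax) / (1.0 + ratio)

    flags: list[str] = []
    try:
        popt, _ = optimize.curve_fit(
            model, doses, v, p0=p0,
            bounds=([1e-15, 0.05, 0.0, 0.0], [1.0, 20.0, 2.0, 2.0]),
            maxfev=20000,
        )
        ec50, slope, e0, emax = (float(p) for p in popt)
        rss = float(np.sum((model(doses, *popt) - v) ** 2))
        converged = True
        if e0 - emax < 0.05:
            flags.append("flat-curve")
            converged = False
    except (RuntimeError, ValueError):
        converged = False
        flags.append("non-convergence")
        ec50, slope, e0, emax = ec50_0, 1.0, float(v.max()), float(v.min())
        rss = float("nan")

    if not converged:
        try:
            me = fit_median_effect(doses, np.clip(1.0 - v, 0.0, 1.0))
            ec50 = me.Dm
            flags.append("ec50-from-median-effect")
        except FitError:
            flags.append("no-fallback-ec50")
    if e0 < emax:
        e0, emax = emax, e0
        flags.append("asymptotes-swapped")
    return HillFit(ec50, slope, e0, emax, rss, converged, tuple(flags))


def ic50_in_combination(
    norm_matrix,
    fixed_dose_index_B: int,
    *,
    dose_ceiling: float | None = DOSE_CEILING,
):
    """IC50 of drug A at a fixed dose of the partner drug B.

    The row-slice of the normalized matrix at column ``fixed_dose_index_B`` is
    treated as a single-agent titration of drug A and refit with the
    median-effect model; the returned dict reports the slice IC50 beside the
    single-agent (vehicle-column) IC50 as a fold-shift. An unfittable slice is
    flagged rather than raised.
    """
    j = int(fixed_dose_index_B)
    dosesA = norm_matrix.dosesA
    fa_slice = np.clip(1.0 - norm_matrix.v[:, j], 0.0, 1.0)
    fa_alone = np.clip(1.0 - norm_matrix.v[:, 0], 0.0, 1.0)
    out = {
        "fixed_dose_B": float(norm_matrix.dosesB[j]),
        "ic50_alone": np.nan,
        "ic50_combo": np.nan,
        "fold_shift": np.nan,
        "flags": [],
    }
    try:
        fit0 = fit_median_effect(dosesA, fa_alone, dose_ceiling=dose_ceiling)
        out["ic50_alone"] = dose_for_effect(fit0, 0.5)
    except FitError as err:
        out["flags"].append(f"single-agent: {err}")
    try:
        fit_j = fit_median_effect(dosesA, fa_slice, dose_ceiling=dose_ceiling)
        out["ic50_combo"] = dose_for_effect(fit_j, 0.5)
    except FitError as err:
        out["flags"].append(f"combination slice: {err}")
    if np.isfinite(out["ic50_alone"]) and np.isfinite(out["ic50_combo"]):
        out["fold_shift"] = out["ic50_alone"] / out["ic50_combo"]
    return out
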