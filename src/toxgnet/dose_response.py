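"""Three-parameter log-logistic viability curves and ICp estimation.

ATP-assay luminescence is modelled as

    f(x) = d / (1 + exp(b * (ln x - ln e)))

with slope b, upper asymptote d (the vehicle-level signal) and inflection
concentration e; the lower asymptote is fixed at zero.  For b > 0 the curve
decreases with concentration, and the concentration inhibiting the readout
by p percent has the closed form

    IC_p = e * (q / (1 - q)) ** (1 / b),     q = p / 100.

IC50 therefore equals e for any slope.  The maximum exposure dose for the
transcriptome experiments is taken between IC0.1 and IC50 and diluted in
five two-fold steps plus a solvent-only vehicle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .io import DOSE_LEVELS, DataError

__all__ = [
    "AtpAssay",
    "DoseResponseFit",
    "ExposureSeries",
    "log_logistic",
    "fit_log_logistic",
    "invert_icp",
    "build_exposure_series",
]


@dataclass
class AtpAssay:
    """Blank-inclusive luminescence readings for one chemical.

    ``luminescence`` has one row per concentration; replicate columns.
    """

    chemical: str
    concentrations: np.ndarray
    luminescence: np.ndarray
    blank: np.ndarray = field(default_factory=lambda: np.zeros(1))

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.luminescence = np.atleast_2d(np.asarray(self.luminescence, dtype=float))
        self.blank = np.atleast_1d(np.asarray(self.blank, dtype=float))
        if (self.concentrations <= 0).any():
            raise DataError(f"{self.chemical}: concentrations must be positive")
        if len(np.unique(self.concentrations)) < 4:
            raise DataError(f"{self.chemical}: need >= 4 distinct concentrations")
        if self.luminescence.shape[0] != self.concentrations.size:
            raise DataError(f"{self.chemical}: luminescence rows != concentrations")

    def corrected_response(self) -> np.ndarray:
        """Luminescence with the mean blank subtracted (rows x replicates)."""
        return self.luminescence - float(np.mean(self.blank))


@dataclass
class DoseResponseFit:
    chemical: str
    b: float
    d: float
    e: float
    residual_sse: float
    ci95: dict[str, tuple[float, float]]
    converged: bool


@dataclass
class ExposureSeries:
    max_dose: float
    doses: dict[str, float]  # dose_level -> concentration (vehicle -> 0)


def log_logistic(x: np.ndarray, b: float, d: float, e: float) -> np.ndarray:
    """Forward model f(x) = d / (1 + exp(b (ln x - ln e)))."""
    x = np.asarray(x, dtype=float)
    return d / (1.0 + np.exp(b * (np.log(x) - np.log(e))))


def _residuals(params: np.ndarray, logx: np.ndarray, y: np.ndarray) -> np.ndarray:
    b, d, log_e = params
    return d / (1.0 + np.exp(b * (logx - log_e))) - y


def fit_log_logistic(assay: AtpAssay) -> DoseResponseFit:
    """Least-squares fit of the three-parameter log-logistic model.

    Optimization runs in log-concentration space from several self-starting
    values (d from the maximal response, e from the concentration nearest
    half-max, slope starts b in {0.5, 1, 2, 4}); the best start wins.
    95% intervals are Wald intervals from the asymptotic covariance of the
    least-squares estimate.
    """
    y2d = assay.corrected_response()
    logx = np.repeat(np.log(assay.concentrations), y2d.shape[1])
    y = y2d.ravel()

    span = float(np.ptp(y))
    scale = max(float(np.max(np.abs(y))), 1.0)
    no_fit = DoseResponseFit(
        assay.chemical, np.nan, np.nan, np.nan, np.nan, {}, converged=False
    )
    if span < 1e-9 * scale:
        return no_fit  # flat response: no dose effect to fit

    d0 = float(np.max(y))
    half = d0 / 2.0
    means = y2d.mean(axis=1)
    e0_log = float(np.log(assay.concentrations)[np.argmin(np.abs(means - half))])

    best = None
    for b0 in (0.5, 1.0, 2.0, 4.0):
        try:
            sol = optimize.least_squares(
                _residuals, x0=[b0, d0, e0_log], args=(logx, y), method="lm"
            )
        except Exception:  # singular start; try the next one
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not np.isfinite(best.cost):
        return no_fit

    b, d, log_e = best.x
    sse = float(2.0 * best.cost)
    n, p = y.size, 3
    dof = n - p
    converged = bool(best.success and d > 0 and np.isfinite(b))

    ci95: dict[str, tuple[float, float]] = {}
    if converged and dof > 0:
        jac = best.jac
        try:
            cov = np.linalg.inv(jac.T @ jac) * (sse / dof)
            se = np.sqrt(np.diag(cov))
            tcrit = stats.t.ppf(0.975, dof)
            for name, est, s in zip(("b", "d", "log_e"), best.x, se):
                ci95[name] = (float(est - tcrit * s), float(est + tcrit * s))
            lo, hi = ci95.pop("log_e")
            ci95["e"] = (float(np.exp(lo)), float(np.exp(hi)))
        except np.linalg.LinAlgError:
            pass

    return DoseResponseFit(
        chemical=assay.chemical,
        b=float(b),
        d=float(d),
        e=float(np.exp(log_e)),
        residual_sse=sse,
        ci95=ci95,
        converged=converged,
    )


def invert_icp(fit: DoseResponseFit, p: float) -> float:
    """Concentration at which the fitted curve drops to d * (1 - p/100)."""
    if not fit.converged:
        raise DataError(f"{fit.chemical}: cannot invert a non-converged fit")
    if not 0.0 < p < 100.0:
        raise DataError(f"p must be in (0, 100), got {p}")
    if fit.b <= 0:
        raise DataError(
            f"{fit.chemical}: slope b={fit.b:.3g} <= 0 — curve does not "
            "decrease with concentration, ICp undefined"
        )
    q = p / 100.0
    return float(fit.e * (q / (1.0 - q)) ** (1.0 / fit.b))


def build_exposure_series(fit: DoseResponseFit, p_max: float = 50.0) -> ExposureSeries:
    """Set the maximum exposure dose at IC(p_max) and dilute two-fold.

    p_max must lie in [0.1, 50]: doses are chosen between the concentration
    where cell death begins (IC0.1) and IC50.
    """
    if not 0.1 <= p_max <= 50.0:
        raise DataError(f"p_max must be in [0.1, 50], got {p_max}")
    max_dose = invert_icp(fit, p_max)
    doses = {"vehicle": 0.0}
    for rank, level in enumerate(DOSE_LEVELS[1:]):  # 1/16 ... 1/1
        doses[level] = max_dose / 2 ** (4 - rank)
    return ExposureSeries(max_dose=max_dose, doses=doses)
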