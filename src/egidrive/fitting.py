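"""Nonlinear least-squares estimation of drive-model parameters.

The single-generation assay seeds many replicate vials at starting EGI
frequencies x0 spanning (0, 1), lets one generation elapse and records the
offspring frequency x1.  Each replicate contributes one observation of the
per-generation change dx = x1 - x0, and the drive model's delta-x curve is
fit to the (x0, dx) scatter by Gauss-Newton least squares.  The fitted
curve's interior zero crossing is the replacement-threshold estimate; a
one-sigma band on the threshold comes from re-solving for the root with
every parameter displaced by +/- one standard deviation.

Model variants
--------------
``F_only``      free F, with c = 1 (random mating).
``F_and_c``     free F and mating propensity c.
``product_Fw1`` free product F*w1 as a single parameter.  F and w1 are not
                separately identifiable from assay data because only their
                product enters the preference-form dynamics; components
                measured in independent fecundity and mate-choice
                experiments are combined by
                :func:`predict_threshold_from_components` instead.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .model import (
    DriveParams,
    NoThresholdError,
    find_threshold,
)

__all__ = [
    "AssayRecord",
    "FitResult",
    "VARIANTS",
    "fit_model",
    "threshold_band",
    "r_squared",
    "predict_threshold_from_components",
]

logger = logging.getLogger(__name__)

VARIANTS: dict[str, tuple[str, ...]] = {
    "F_only": ("F",),
    "F_and_c": ("F", "c"),
    "product_Fw1": ("Fw1",),
}


@dataclass
class AssayRecord:
    """One replicate of the single-generation drive assay.

    Founder adults (``start_egi`` EGI + ``start_wt`` wild-type) mate and
    lay; ``offspring_egi`` / ``offspring_wt`` are the adult offspring
    counted one generation later.  Derived frequencies are fractions.
    """

    start_egi: int
    start_wt: int
    offspring_egi: int
    offspring_wt: int
    temperature: Optional[float] = None
    replicate: Optional[str] = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("start_egi", "start_wt", "offspring_egi", "offspring_wt"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be nonnegative, got {v}")
        if self.start_egi + self.start_wt == 0:
            raise ValueError("a replicate must have at least one founder")

    @property
    def x0(self) -> float:
        """Starting EGI frequency among founders."""
        return self.start_egi / (self.start_egi + self.start_wt)

    @property
    def total_offspring(self) -> int:
        return self.offspring_egi + self.offspring_wt

    @property
    def x1(self) -> float:
        """Offspring EGI frequency; NaN when the vial produced no offspring."""
        tot = self.total_offspring
        return self.offspring_egi / tot if tot > 0 else float("nan")

    @property
    def dx(self) -> float:
        """Observed per-generation frequency change x1 - x0."""
        return self.x1 - self.x0


@dataclass
class FitResult:
    """Gauss-Newton fit of the delta-x model to assay data."""

    variant: str
    estimates: dict
    sigmas: dict
    ssr: float
    r2: float
    threshold: Optional[float]
    threshold_low: Optional[float]
    threshold_high: Optional[float]
    iterations: int
    converged: bool
    n_records: int
    damped: bool = False

    def params(self, displace: float = 0.0) -> DriveParams:
        """Drive parameters at (estimate + displace * sigma) for every
        free parameter.  ``product_Fw1`` maps the product onto F (w1 = 1),
        which leaves the dynamics unchanged."""
        vals = {
            k: self.estimates[k] + displace * self.sigmas.get(k, 0.0)
            for k in self.estimates
        }
        if self.variant == "product_Fw1":
            return DriveParams(F=vals["Fw1"])
        return DriveParams(F=vals["F"], c=vals.get("c", 1.0))

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "estimates": dict(self.estimates),
            "sigmas": dict(self.sigmas),
            "ssr": self.ssr,
            "r_squared": self.r2,
            "threshold": self.threshold,
            "threshold_low": self.threshold_low,
            "threshold_high": self.threshold_high,
            "iterations": self.iterations,
            "converged": self.converged,
            "n_records": self.n_records,
            "damped": self.damped,
        }


def r_squared(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Coefficient of determination ``1 - SSR/SST``.

    SST is taken about the mean of the observations; the score can be
    negative when the fit is worse than the constant mean.
    """
    y = np.asarray(observed, dtype=float)
    f = np.asarray(predicted, dtype=float)
    if y.shape != f.shape:
        raise ValueError("observed and predicted must have equal length")
    if y.size < 2:
        raise ValueError("need at least two observations")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0 or np.all(y == y[0]):
        raise ValueError("R^2 undefined: observations are all identical")
    ssr = float(np.sum((y - f) ** 2))
    return 1.0 - ssr / sst


def _predict(theta: np.ndarray, x: np.ndarray, variant: str) -> np.ndarray:
    """Model dx at frequencies x for parameter vector theta."""
    if variant == "F_and_c":
        F, c = theta
        cx = c * x
        num = F * cx * cx
        den = num + (1.0 - cx) ** 2
    else:  # F_only and product_Fw1 share the same curve shape
        g = theta[0]
        num = g * x * x
        den = num + (1.0 - x) ** 2
    return num / den - x


def _jacobian(theta: np.ndarray, x: np.ndarray, variant: str) -> np.ndarray:
    """Central-difference Jacobian d(prediction)/d(theta)."""
    p = theta.size
    J = np.empty((x.size, p))
    for j in range(p):
        h = 1e-6 * max(abs(theta[j]), 1.0)
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        J[:, j] = (_predict(tp, x, variant) - _predict(tm, x, variant)) / (2.0 * h)
    return J


def _valid_theta(theta: np.ndarray) -> bool:
    return bool(np.all(np.isfinite(theta)) and np.all(theta > 0.0))


def fit_model(
    records: Iterable[AssayRecord],
    variant: str = "F_and_c",
    init: Optional[DriveParams] = None,
    max_iter: int = 100,
    step_tol: float = 1e-8,
) -> FitResult:
    """Fit the delta-x model to assay records by Gauss-Newton.

    Each record is one residual ``dx_i - delta_x(x0_i; theta)`` so every
    measured frequency weighs equally regardless of replicate structure.
    Records with zero total offspring have undefined dx and are excluded
    with a warning.  Parameter standard deviations come from the standard
    NLS covariance ``(J'J)^-1 * SSR / (n - p)``; the threshold and its
    one-sigma band are derived from the fitted parameters via root finding.

    Ill-conditioned normal equations or objective-increasing steps fall
    back to Levenberg-style damping (the result is flagged ``damped``);
    accepted steps never increase the sum of squared residuals.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {sorted(VARIANTS)}")
    recs = list(records)
    usable = [r for r in recs if r.total_offspring > 0]
    dropped = len(recs) - len(usable)
    if dropped:
        warnings.warn(
            f"excluded {dropped} record(s) with zero total offspring (dx undefined)",
            RuntimeWarning,
            stacklevel=2,
        )
        logger.warning("excluded %d zero-offspring record(s)", dropped)
    names = VARIANTS[variant]
    p = len(names)
    if len(usable) <= p:
        raise ValueError(f"need more than {p} usable records, got {len(usable)}")
    x = np.array([r.x0 for r in usable])
    y = np.array([r.dx for r in usable])
    if np.unique(x).size < 2:
        raise ValueError("need at least two distinct starting frequencies")

    if init is None:
        init = DriveParams()
    if variant == "F_and_c":
        theta = np.array([init.F, init.c])
    elif variant == "F_only":
        theta = np.array([init.F])
    else:
        theta = np.array([init.F * init.w1])

    ssr = float(np.sum((y - _predict(theta, x, variant)) ** 2))
    lam = 0.0
    damped = False
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        r = y - _predict(theta, x, variant)
        J = _jacobian(theta, x, variant)
        A = J.T @ J
        g = J.T @ r
        accepted = False
        for _ in range(60):
            M = A + lam * np.diag(np.maximum(np.diag(A), 1e-12))
            try:
                step = np.linalg.solve(M, g)
            except np.linalg.LinAlgError:
                lam = max(10.0 * lam, 1e-4)
                damped = True
                continue
            trial = theta + step
            if _valid_theta(trial):
                trial_ssr = float(np.sum((y - _predict(trial, x, variant)) ** 2))
                if np.isfinite(trial_ssr) and trial_ssr <= ssr:
                    accepted = True
                    break
            lam = max(10.0 * lam, 1e-4)
            damped = True
        if not accepted:
            break
        theta, ssr = trial, trial_ssr
        lam *= 0.3
        if lam < 1e-12:
            lam = 0.0
        if np.max(np.abs(step)) < step_tol:
            converged = True
            break

    n = x.size
    J = _jacobian(theta, x, variant)
    A = J.T @ J
    s2 = ssr / (n - p)
    try:
        cov = s2 * np.linalg.inv(A)
        sig = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        sig = np.full(p, np.nan)
        damped = True

    estimates = dict(zip(names, (float(t) for t in theta)))
    sigmas = dict(zip(names, (float(s) for s in sig)))
    r2 = r_squared(y, _predict(theta, x, variant))

    result = FitResult(
        variant=variant,
        estimates=estimates,
        sigmas=sigmas,
        ssr=ssr,
        r2=r2,
        threshold=None,
        threshold_low=None,
        threshold_high=None,
        iterations=it,
        converged=converged,
        n_records=n,
        damped=damped,
    )
    try:
        result.threshold = find_threshold(result.params())
    except NoThresholdError:
        logger.warning("fitted model has no interior threshold")
    if result.threshold is not None and np.all(np.isfinite(sig)):
        low, high = threshold_band(result)
        result.threshold_low, result.threshold_high = low, high
    return result


def threshold_band(fit: FitResult) -> tuple:
    """One-sigma threshold band from displacing every free parameter.

    Re-solves for the interior root with all parameters at estimate + sigma
    and again at estimate - sigma (parameter covariance is deliberately
    ignored), then orders the two roots.  A displaced parameter set with no
    interior root yields ``None`` for that end of the band.
    """
    bounds = []
    for displace in (+1.0, -1.0):
        try:
            params = fit.params(displace)
            bounds.append(find_threshold(params))
        except (NoThresholdError, ValueError):
            bounds.append(None)
    present = [b for b in bounds if b is not None]
    if len(present) == 2:
        return (min(present), max(present))
    if len(present) == 1:
        # +sigma displacement lowers the threshold, so a missing +sigma root
        # leaves the low end open and vice versa
        if bounds[0] is None:
            return (None, present[0])
        return (present[0], None)
    return (None, None)


def predict_threshold_from_components(F: float, w1: float = 1.0) -> float:
    """Replacement threshold from independently measured components.

    ``F`` is the fecundity ratio (mean EGI offspring per vial over mean
    wild-type offspring); ``w1`` is the EGI x EGI mate-preference weight
    relative to wild-type x wild-type, estimated from mate-choice counts.
    The threshold is the interior zero of the preference-form delta-x and
    equals ``1 / (1 + F * w1)``.
    """
    if F <= 0:
        raise ValueError("fecundity ratio F must be positive")
    if w1 < 0:
        raise ValueError("preference weight w1 must be nonnegative")
    if F * w1 == 0:
        raise NoThresholdError("F * w1 = 0: the drive never spreads")
    return find_threshold(DriveParams(F=F, w1=w1))
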