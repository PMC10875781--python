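"""Deterministic frequency dynamics for extreme-underdominance gene drives.

An engineered-genetic-incompatibility (EGI) strain and its wild-type
counterpart form an extreme underdominance pair: both pure genotypes are
fully fit, but every EGI x wild-type hybrid dies.  With ``x`` the EGI
frequency among adults, random-mating pair frequencies are Hardy-Weinberg,
hybrids contribute nothing, and the next-generation EGI frequency is

    x' = F (cx)^2 / (F (cx)^2 + (1 - cx)^2)          (propensity form)
    x' = F w1 x^2 / (F w1 x^2 + (1 - x)^2)           (preference form)

where ``F`` is EGI fecundity relative to wild-type, ``c`` rescales the
effective EGI frequency in pairing (a mating-propensity modifier), and
``w1, w2, w3`` weight the EGI x EGI, EGI-female x wt-male and wt-female x
EGI-male pairings relative to wt x wt.  Only the product ``F * w1`` shapes
the preference-form dynamics, because hybrid pairings leave no offspring.

The map has stable fixed points at 0 and 1 and one interior unstable
equilibrium x* — the replacement threshold.  Releases above x* drive the
engineered genotype to fixation; below it the genotype is eliminated.  For
``c = 1`` the threshold has the closed form ``x* = 1 / (1 + F * w1)``.

Frequencies are fractions in [0, 1] throughout; conversion to percent is a
reporting concern left to callers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence, Union

import numpy as np

__all__ = [
    "DriveParams",
    "MatingDistribution",
    "Trajectory",
    "DegenerateModelError",
    "NoThresholdError",
    "mating_probabilities",
    "next_frequency",
    "delta_x",
    "find_threshold",
    "closed_form_threshold",
    "iterate_trajectory",
]

Mode = Literal["propensity", "preference"]

ArrayLike = Union[float, Sequence[float], np.ndarray]


class DegenerateModelError(ValueError):
    """Model evaluated at a parameter/frequency combination with no meaning
    (zero normalizer or zero denominator)."""


class NoThresholdError(RuntimeError):
    """The per-generation change has no interior negative-to-positive zero:
    the drive either always spreads or never spreads."""


@dataclass(frozen=True)
class DriveParams:
    """Parameters of the underdominance drive model.

    Parameters
    ----------
    F : float
        Fecundity of EGI x EGI pairs relative to wild-type x wild-type
        (wild-type fixed at 1).  Must be positive.
    c : float
        Mating-propensity modifier of EGI individuals: the effective EGI
        frequency in pairing is ``c * x``.  Must be positive.
    w1, w2, w3 : float
        Mate-preference weights of the EGI x EGI, EGI-female x wt-male and
        wt-female x EGI-male pairings relative to wt x wt.  Nonnegative.

    ``c`` and the ``w`` weights are alternative parameterizations of
    non-random mating, not composable: ``c != 1`` together with any
    ``w != 1`` is rejected.  The defaults reduce the model to random
    mating with equal fitness.
    """

    F: float = 1.0
    c: float = 1.0
    w1: float = 1.0
    w2: float = 1.0
    w3: float = 1.0

    def __post_init__(self) -> None:
        if not self.F > 0:
            raise ValueError(f"relative fecundity F must be positive, got {self.F}")
        if not self.c > 0:
            raise ValueError(f"mating propensity c must be positive, got {self.c}")
        for name in ("w1", "w2", "w3"):
            w = getattr(self, name)
            if w < 0:
                raise ValueError(f"preference weight {name} must be nonnegative, got {w}")
        if self.c != 1.0 and (self.w1, self.w2, self.w3) != (1.0, 1.0, 1.0):
            raise ValueError(
                "mating propensity c and preference weights w1-w3 are alternative "
                "parameterizations of non-random mating; leave one group at its "
                "neutral value (c=1 or w1=w2=w3=1)"
            )

    @property
    def mode(self) -> Mode:
        """Which parameterization is active ('preference' when c == 1)."""
        return "propensity" if self.c != 1.0 else "preference"

    @property
    def uses_preference_weights(self) -> bool:
        return (self.w1, self.w2, self.w3) != (1.0, 1.0, 1.0)


@dataclass(frozen=True)
class MatingDistribution:
    """Probabilities of the four (female x male) pairings at one frequency.

    ``z`` is the preference-mode normalizer
    ``w1 x^2 + (w2 + w3) x (1 - x) + (1 - x)^2``; it is ``None`` in
    propensity mode, where the pairing terms are not renormalized.
    """

    p_egi_egi: float
    p_egi_wt: float
    p_wt_egi: float
    p_wt_wt: float
    z: Optional[float] = None

    @property
    def total(self) -> float:
        return self.p_egi_egi + self.p_egi_wt + self.p_wt_egi + self.p_wt_wt

    def as_tuple(self) -> tuple:
        return (self.p_egi_egi, self.p_egi_wt, self.p_wt_egi, self.p_wt_wt)


@dataclass(frozen=True)
class Trajectory:
    """Generation-indexed EGI frequencies from iterating the drive map.

    ``outcome`` is one of ``fixation``, ``loss``, ``equilibrium``,
    ``max_generations`` or (stochastic cage simulations only)
    ``extinction`` when a population produces no offspring at all.
    """

    frequencies: tuple
    outcome: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "frequencies", tuple(float(x) for x in self.frequencies))

    @property
    def generations(self) -> int:
        return len(self.frequencies) - 1

    @property
    def final(self) -> float:
        return self.frequencies[-1]


def _check_frequency(x: np.ndarray) -> None:
    if np.any((x < 0.0) | (x > 1.0)):
        raise ValueError("frequency x must lie in [0, 1]")


def mating_probabilities(
    x: float, params: DriveParams, mode: Optional[Mode] = None
) -> MatingDistribution:
    """Pairing probabilities for the four (female x male) combinations.

    In preference mode the four terms are weighted Hardy-Weinberg
    frequencies renormalized by ``z`` and sum to 1 by construction.  In
    propensity mode the terms ``(cx)^2, cx(1-cx), cx(1-cx), (1-cx)^2``
    sum to 1 only while ``c*x <= 1``; beyond that the probability
    interpretation breaks and a warning is emitted (the per-generation
    change remains well defined, which matters during fitting).
    """
    xf = float(x)
    _check_frequency(np.asarray(xf))
    if mode is None:
        mode = "propensity" if params.c != 1.0 else "preference"
    if mode == "propensity":
        if params.uses_preference_weights:
            raise ValueError("propensity mode requires neutral preference weights")
        cx = params.c * xf
        if cx > 1.0:
            warnings.warn(
                f"c*x = {cx:.4g} > 1: propensity-mode pairing terms no longer "
                "form a probability distribution",
                RuntimeWarning,
                stacklevel=2,
            )
        hybrid = cx * (1.0 - cx)
        return MatingDistribution(cx * cx, hybrid, hybrid, (1.0 - cx) ** 2, z=None)
    if mode == "preference":
        if params.c != 1.0:
            raise ValueError("preference mode requires c = 1")
        w1, w2, w3 = params.w1, params.w2, params.w3
        z = w1 * xf * xf + (w2 + w3) * xf * (1.0 - xf) + (1.0 - xf) ** 2
        if z == 0.0:
            raise DegenerateModelError(
                "all pairing weights vanish at this frequency (z = 0)"
            )
        return MatingDistribution(
            w1 * xf * xf / z,
            w2 * xf * (1.0 - xf) / z,
            w3 * xf * (1.0 - xf) / z,
            (1.0 - xf) ** 2 / z,
            z=z,
        )
    raise ValueError(f"unknown mode {mode!r}")


def next_frequency(x: ArrayLike, params: DriveParams) -> Union[float, np.ndarray]:
    """EGI frequency in the next generation.

    Hybrid pairings contribute no offspring, so only the EGI x EGI and
    wt x wt terms appear.  Accepts scalars or arrays of frequencies.
    """
    arr = np.asarray(x, dtype=float)
    _check_frequency(arr)
    if params.uses_preference_weights:
        num = params.F * params.w1 * arr * arr
        den = num + (1.0 - arr) ** 2
    else:
        cx = params.c * arr
        num = params.F * cx * cx
        den = num + (1.0 - cx) ** 2
    if np.any(den == 0.0):
        raise DegenerateModelError(
            "both surviving pairing classes have zero weight (denominator = 0)"
        )
    out = num / den
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


def delta_x(x: ArrayLike, params: DriveParams) -> Union[float, np.ndarray]:
    """Per-generation change in EGI frequency, ``next_frequency(x) - x``."""
    arr = np.asarray(x, dtype=float)
    out = next_frequency(arr, params) - arr
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


def closed_form_threshold(F: float, w1: float = 1.0) -> float:
    """Closed-form threshold ``1 / (1 + F*w1)`` for c = 1."""
    if F * w1 <= 0:
        raise NoThresholdError("F*w1 must be positive for an interior threshold")
    return 1.0 / (1.0 + F * w1)


def _bisect(f, lo: float, hi: float, tol: float) -> float:
    # f(lo) < 0 < f(hi); plain bisection, robust over fast
    for _ in range(200):
        if hi - lo < tol:
            break
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        if fm == 0.0:
            return mid
        if fm < 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def find_threshold(
    params: DriveParams, grid_step: float = 1e-3, tol: float = 1e-9
) -> float:
    """Interior unstable equilibrium of the drive map.

    Scans ``delta_x`` on a regular grid over (0, 1) for negative-to-positive
    sign changes and refines each bracket by bisection.  Raises
    :class:`NoThresholdError` when no such crossing exists.  If several
    crossings exist (possible only in propensity mode with c != 1) the
    smallest is returned with a warning.
    """
    if grid_step <= 0 or tol <= 0:
        raise ValueError("grid_step and tol must be positive")
    xs = np.arange(grid_step, 1.0, grid_step)
    d = np.asarray(delta_x(xs, params))
    sign = np.sign(d)

    roots: list[float] = []
    nz = np.flatnonzero(sign != 0)
    # exact zeros at grid nodes that separate a negative from a positive arm
    for i in np.flatnonzero(sign == 0):
        prev = nz[nz < i]
        nxt = nz[nz > i]
        if prev.size and nxt.size and sign[prev[-1]] < 0 < sign[nxt[0]]:
            roots.append(float(xs[i]))
    # adjacent-node sign changes
    f = lambda x: delta_x(x, params)
    for i, j in zip(nz[:-1], nz[1:]):
        if j == i + 1 and sign[i] < 0 < sign[j]:
            roots.append(_bisect(f, float(xs[i]), float(xs[j]), tol))

    if not roots:
        raise NoThresholdError(
            "delta_x has no negative-to-positive crossing on (0, 1): the drive "
            "either always spreads or never spreads under these parameters"
        )
    roots.sort()
    if len(roots) > 1:
        warnings.warn(
            f"{len(roots)} interior crossings found; returning the smallest",
            RuntimeWarning,
            stacklevel=2,
        )
    return roots[0]


def iterate_trajectory(
    x0: float,
    params: DriveParams,
    max_generations: int = 200,
    fix_tol: float = 1e-6,
) -> Trajectory:
    """Iterate the deterministic drive map from ``x0``.

    Stops when the frequency is within ``fix_tol`` of fixation (outcome
    ``fixation``) or loss (``loss``), lands exactly on a fixed point
    (``equilibrium``), or after ``max_generations`` steps.
    """
    x = float(x0)
    _check_frequency(np.asarray(x))
    freqs = [x]
    outcome = "max_generations"
    for _ in range(max_generations):
        if x > 1.0 - fix_tol:
            outcome = "fixation"
            break
        if x < fix_tol:
            outcome = "loss"
            break
        x_next = next_frequency(x, params)
        if x_next == x:
            outcome = "equilibrium"
            break
        freqs.append(x_next)
        x = x_next
    else:
        outcome = "max_generations"
    if outcome == "max_generations" and freqs:
        # landed on a boundary check after the final appended step
        if freqs[-1] > 1.0 - fix_tol:
            outcome = "fixation"
        elif freqs[-1] < fix_tol:
            outcome = "loss"
    return Trajectory(frequencies=tuple(freqs), outcome=outcome)
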