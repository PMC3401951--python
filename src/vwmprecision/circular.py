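"""Circular statistics for orientation-reproduction error.

Orientation stimuli live on a pi-periodic space: a bar rotated by pi rad is
the same bar. All dispersion computations in this module therefore map
angles to the doubled-angle (2*pi-periodic) representation before taking
resultants, the standard device for axial data. Circular SD and its
reciprocal (precision, rad^-1) are reported on the doubled scale.

The key quantities:

* Fisher circular SD: ``sqrt(-2 * ln(Rbar))`` where ``Rbar`` is the mean
  resultant length of unit vectors at the (doubled) error angles.
* Precision: ``1 / SD``, minus the value expected for uniform random
  responding (estimated by Monte Carlo), so that guessing scores ~0.
* Sensorimotor correction: memory precision recovered from observed error
  by subtracting motor/perceptual-matching error variance,
  ``1 / sqrt(SD_vwm**2 - SD_sm**2)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ORIENTATION_PERIOD",
    "AngleSet",
    "PrecisionEstimate",
    "InsufficientDataError",
    "InvalidAngleError",
    "angular_error",
    "mean_resultant_length",
    "circular_sd",
    "chance_precision",
    "precision",
    "sensorimotor_corrected_precision",
    "precision_difference",
]

#: Period of the orientation stimulus space (bars are axial).
ORIENTATION_PERIOD = math.pi

#: Smallest circular SD used when forming reciprocals, so that a
#: zero-dispersion sample yields a large finite precision, not infinity.
DEFAULT_SD_FLOOR = 1e-6


class InvalidAngleError(ValueError):
    """Raised for non-finite or out-of-range angular input."""


class InsufficientDataError(ValueError):
    """Raised when fewer than two error values are available."""


@dataclass(frozen=True)
class AngleSet:
    """A validated collection of angles on a circular space.

    Parameters
    ----------
    values:
        Angles in radians, each in ``[0, period)``.
    period:
        Angular period: ``pi`` for orientation data, ``2*pi`` for the
        internal doubled representation.
    """

    values: np.ndarray
    period: float = ORIENTATION_PERIOD

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", arr)
        if not self.period > 0:
            raise InvalidAngleError(f"period must be positive, got {self.period}")
        if arr.size and not np.all(np.isfinite(arr)):
            raise InvalidAngleError("angles must be finite")
        if arr.size and (arr.min() < 0 or arr.max() >= self.period):
            raise InvalidAngleError(
                f"angles must lie in [0, {self.period}); "
                f"got range [{arr.min()}, {arr.max()}]"
            )

    def __len__(self) -> int:
        return int(self.values.size)

    def doubled(self) -> "AngleSet":
        """Map to the 2*pi-periodic representation (angles scaled by 2*pi/period)."""
        scale = 2.0 * math.pi / self.period
        return AngleSet((self.values * scale) % (2.0 * math.pi), 2.0 * math.pi)


@dataclass(frozen=True)
class PrecisionEstimate:
    """Circular SD and (chance-corrected) precision for one set of errors.

    ``circular_sd`` is on the doubled-angle scale; precisions are its
    reciprocals in rad^-1. ``corrected_precision`` has the chance value
    subtracted so that uniform random responding scores ~0.
    """

    circular_sd: float
    raw_precision: float
    chance_precision: float
    corrected_precision: float
    n_trials: int
    chance_method: str = "monte_carlo"
    undefined: bool = False


def _as_errors(errors, period: float | None):
    """Coerce an AngleSet or array-like of signed errors to (array, period)."""
    if isinstance(errors, AngleSet):
        return np.asarray(errors.values, dtype=float), errors.period
    arr = np.asarray(errors, dtype=float).ravel()
    if not np.all(np.isfinite(arr)):
        raise InvalidAngleError("error angles must be finite")
    return arr, (ORIENTATION_PERIOD if period is None else period)


def angular_error(response, target, period: float = ORIENTATION_PERIOD):
    """Minimal signed circular difference ``response - target`` modulo period.

    Returns a value (elementwise for array input) in ``(-period/2, period/2]``.
    """
    if not period > 0:
        raise InvalidAngleError(f"period must be positive, got {period}")
    resp = np.asarray(response, dtype=float)
    targ = np.asarray(target, dtype=float)
    if not (np.all(np.isfinite(resp)) and np.all(np.isfinite(targ))):
        raise InvalidAngleError("response and target must be finite")
    # (target - response + p/2) mod p lies in [0, p); negating the shifted
    # value lands the result in the half-open interval (-p/2, p/2].
    err = -(((targ - resp) + period / 2.0) % period - period / 2.0)
    if np.ndim(response) == 0 and np.ndim(target) == 0:
        return float(err)
    return err


def mean_resultant_length(angles_2pi) -> float:
    """Mean resultant length Rbar of unit vectors at 2*pi-periodic angles."""
    arr = np.asarray(angles_2pi, dtype=float).ravel()
    return float(np.abs(np.exp(1j * arr).mean()))


def circular_sd(errors, period: float | None = None, r_floor: float | None = None) -> float:
    """Fisher circular SD, ``sqrt(-2 ln Rbar)``, on the doubled-angle scale.

    Errors on a pi-periodic space are doubled before computing the
    resultant. ``Rbar`` is floored at ``1/n`` by default (the resolution
    limit of n unit vectors), which caps the SD at ``sqrt(2 ln n)`` and
    prevents divergence for near-uniform samples.

    Raises
    ------
    InsufficientDataError
        If fewer than two error values are supplied.
    """
    arr, per = _as_errors(errors, period)
    n = arr.size
    if n < 2:
        raise InsufficientDataError(f"need >= 2 error values, got {n}")
    doubled = arr * (2.0 * math.pi / per)
    rbar = mean_resultant_length(doubled)
    if rbar >= 1.0:
        return 0.0
    floor = (1.0 / n) if r_floor is None else r_floor
    rbar = max(rbar, floor)
    return math.sqrt(-2.0 * math.log(rbar))


def chance_precision(
    n_trials: int,
    n_replicates: int = 10_000,
    seed: int = 0,
    r_floor: float | None = None,
    sd_floor: float = DEFAULT_SD_FLOOR,
) -> float:
    """Expected precision (1/SD) of ``n_trials`` uniform random errors.

    Monte Carlo estimate, deterministic given ``seed``. This is the value
    subtracted from raw precision so that random responding scores ~0.
    """
    if n_trials < 2:
        raise InsufficientDataError(f"need n_trials >= 2, got {n_trials}")
    if n_replicates < 1000:
        raise ValueError(f"need n_replicates >= 1000, got {n_replicates}")
    rng = np.random.default_rng(seed)
    ang = rng.uniform(0.0, 2.0 * math.pi, size=(n_replicates, n_trials))
    rbar = np.abs(np.exp(1j * ang).mean(axis=1))
    floor = (1.0 / n_trials) if r_floor is None else r_floor
    rbar = np.clip(rbar, floor, 1.0 - 1e-15)
    sd = np.sqrt(-2.0 * np.log(rbar))
    return float(np.mean(1.0 / np.maximum(sd, sd_floor)))


def precision(
    errors,
    chance: float,
    period: float | None = None,
    r_floor: float | None = None,
    sd_floor: float = DEFAULT_SD_FLOOR,
    chance_method: str = "monte_carlo",
) -> PrecisionEstimate:
    """Chance-corrected precision of a set of response errors.

    ``raw_precision = 1 / circular_sd`` and
    ``corrected_precision = raw_precision - chance``.
    """
    arr, per = _as_errors(errors, period)
    sd = circular_sd(arr, period=per, r_floor=r_floor)
    raw = 1.0 / max(sd, sd_floor)
    return PrecisionEstimate(
        circular_sd=sd,
        raw_precision=raw,
        chance_precision=float(chance),
        corrected_precision=raw - float(chance),
        n_trials=int(arr.size),
        chance_method=chance_method,
    )


def _variance_difference_precision(sd_large: float, sd_small: float) -> float:
    if not (np.isfinite(sd_large) and np.isfinite(sd_small)):
        raise InvalidAngleError("circular SDs must be finite")
    if sd_large < 0 or sd_small < 0:
        raise InvalidAngleError("circular SDs must be non-negative")
    diff = sd_large * sd_large - sd_small * sd_small
    if diff <= 0.0:
        return math.nan
    return 1.0 / math.sqrt(diff)


def sensorimotor_corrected_precision(sd_vwm: float, sd_sm: float) -> float:
    """Memory precision after removing sensorimotor error variance.

    ``1 / sqrt(sd_vwm**2 - sd_sm**2)`` assuming independent motor and
    memory error. Returns NaN (the undefined flag) when the variance
    difference is non-positive; callers log and exclude such cases rather
    than silently dropping them.
    """
    return _variance_difference_precision(sd_vwm, sd_sm)


def precision_difference(sd_large_load: float, sd_small_load: float) -> float:
    """Precision attributable to the extra load, by variance subtraction.

    Same contract as :func:`sensorimotor_corrected_precision` with the
    higher-load and lower-load circular SDs; NaN when the difference in
    variance is non-positive.
    """
    return _variance_difference_precision(sd_large_load, sd_small_load)
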