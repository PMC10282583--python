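"""Hazard-curve containers shared across the modelling and contrast layers.

A :class:`HazardCurve` is a log mortality rate evaluated on an age grid and
tagged with a *flavor*: ``conditional`` (isoline random effects set to zero),
``marginal`` (survivor-weighted average over isolines, reflecting frailty
composition change) or ``per_isoline``.  The flavor travels with the curve so
that downstream differencing never silently mixes the two population
interpretations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

FLAVORS = ("marginal", "conditional", "per_isoline")


@dataclass(frozen=True)
class HazardCurve:
    """Log mortality rate mu(x) on an age grid (days)."""

    ages: np.ndarray
    log_mu: np.ndarray
    flavor: str
    stratum: str
    isoline: str | None = None

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=float)
        log_mu = np.asarray(self.log_mu, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "log_mu", log_mu)
        if ages.ndim != 1 or ages.shape != log_mu.shape:
            raise ValueError("ages and log_mu must be 1-d arrays of equal length")
        if ages.size and not np.all(np.diff(ages) > 0):
            raise ValueError("age grid must be strictly increasing")
        if not np.all(np.isfinite(log_mu)):
            raise ValueError("log_mu contains non-finite values")
        if self.flavor not in FLAVORS:
            raise ValueError(f"unknown flavor {self.flavor!r}; expected one of {FLAVORS}")

    @property
    def mu(self) -> np.ndarray:
        return np.exp(self.log_mu)


def curve_difference(a: HazardCurve, b: HazardCurve) -> np.ndarray:
    """Pointwise log-hazard difference a - b on a shared grid.

    Curves of different flavors are never comparable (a marginal rate reflects
    survivor composition, a conditional one does not), so mixing them raises.
    """
    if a.flavor != b.flavor:
        raise ValueError(
            f"cannot difference curves of different flavors: {a.flavor!r} vs {b.flavor!r}"
        )
    if a.ages.shape != b.ages.shape or not np.allclose(a.ages, b.ages):
        raise ValueError("curves must share an identical age grid")
    return a.log_mu - b.log_mu


@dataclass(frozen=True)
class DifferenceBand:
    """Pointwise bootstrap percentile band for a log-hazard difference.

    ``significant_windows`` lists the maximal closed age intervals on which the
    percentile interval excludes zero, each tagged with the sign of the point
    estimate there.  The bands are pointwise (piecewise), not familywise.
    """

    ages: np.ndarray
    delta: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    alpha: float
    flavor: str
    label_a: str
    label_b: str
    n_boot: int
    significant_windows: tuple[tuple[float, float, int], ...] = field(default=())

    def __post_init__(self) -> None:
        for name in ("ages", "delta", "lower", "upper"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (self.ages.shape == self.delta.shape == self.lower.shape == self.upper.shape):
            raise ValueError("ages, delta, lower, upper must have identical shapes")
        if np.any(self.lower > self.delta + 1e-9) or np.any(self.upper < self.delta - 1e-9):
            raise ValueError("point estimate must lie inside the band")


def significant_windows(
    ages: np.ndarray, delta: np.ndarray, lower: np.ndarray, upper: np.ndarray
) -> tuple[tuple[float, float, int], ...]:
    """Maximal runs of consecutive grid ages where the CI excludes zero.

    Returns tuples ``(age_start, age_end, sign)`` with sign +1 where the whole
    run has lower > 0 and -1 where upper < 0.
    """
    sig = np.zeros(len(ages), dtype=int)
    sig[lower > 0] = 1
    sig[upper < 0] = -1
    windows: list[tuple[float, float, int]] = []
    i = 0
    n = len(ages)
    while i < n:
        if sig[i] == 0:
            i += 1
            continue
        j = i
        while j + 1 < n and sig[j + 1] == sig[i]:
            j += 1
        windows.append((float(ages[i]), float(ages[j]), int(sig[i])))
        i = j + 1
    return tuple(windows)
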