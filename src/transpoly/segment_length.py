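"""Length of the ancestral segment around a balanced trans-species polymorphism.

For a sample of four chromosomes (one per allelic class per species) the
ancestral segment is the region in which no class-switching recombination
occurs until the lineages of each allelic class coalesce.  On each side of the
selected site its length ``X`` (in Morgans) is the distance to the nearest
class-switching crossover accumulated by the four stage-II lineages over the
duration ``T + t``, where ``T`` is the split time and ``t = max(t1, t2)`` is
the extra coalescence time of the two allelic classes in the ancestral
species, with ``t1 ~ Exp(mean 2*Na*p)`` and ``t2 ~ Exp(mean 2*Na*q)``.

Each lineage switches allelic class at rate (opposite-class frequency) per
Morgan, so the four lineages jointly accrue hazard ``2(p + q) = 2`` per Morgan
per generation -- independent of ``p``.  Hence ``X | t ~ Exp(rate 2(T + t))``
and marginally the survival function has the closed three-term mixture form

    S(x) = exp(-2Tx) * [ a/(a+2x) + b/(b+2x) - (a+b)/(a+b+2x) ]

with ``a = 1/(2*Na*p)`` and ``b = 1/(2*Na*q)``.  The two-sided length is the
sum of two independent one-sided draws (self-convolution).

All four stage-II lineages are treated as exposed until ``t = max(t1, t2)``;
this slightly overstates the hazard in the window between the two class
coalescences (by about a third of one lineage's share) and is accurate when
``Na << T``.  The Monte-Carlo oracle in the test-suite implements the same
convention; the conditional simulator implements the full process.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, optimize, signal

from .params import ModelParams, ParameterError

__all__ = [
    "stage2_time_density",
    "stage2_time_mean",
    "LengthDistribution",
    "one_sided_distribution",
    "two_sided_distribution",
]


def _rates(Na: float, p: float) -> tuple[float, float]:
    return 1.0 / (2.0 * Na * p), 1.0 / (2.0 * Na * (1.0 - p))


def stage2_time_density(t, Na: float, p: float):
    """Density of ``t = max(t1, t2)``, the extra stage-II coalescence time.

    ``t1`` and ``t2`` are the (exponential) coalescence times of the two A1
    and the two A2 lineages in the ancestral species.
    """
    a, b = _rates(Na, p)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ParameterError("t must be non-negative")
    out = a * np.exp(-a * t) * (1.0 - np.exp(-b * t)) + b * np.exp(-b * t) * (
        1.0 - np.exp(-a * t)
    )
    return out if out.shape else float(out)


def stage2_time_mean(Na: float, p: float) -> float:
    """``E[max(t1, t2)] = 1/a + 1/b - 1/(a+b)``."""
    a, b = _rates(Na, p)
    return 1.0 / a + 1.0 / b - 1.0 / (a + b)


@dataclass
class LengthDistribution:
    """One- or two-sided ancestral-segment length law.

    Lengths are handled internally in Morgans; ``r`` (per-bp recombination
    rate) converts to base pairs for reporting.  Lengths in bp are continuous,
    not floored.
    """

    Na: float
    T: float
    p: float
    r: float
    side: str = "one"  # "one" | "two"
    grid_bp: float = 0.05  # two-sided convolution resolution, bp-equivalent
    _grid: tuple[np.ndarray, np.ndarray] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not (
            np.isfinite(self.Na)
            and np.isfinite(self.T)
            and self.Na > 0
            and self.T > 0
            and 0 < self.p < 1
            and self.r > 0
        ):
            raise ParameterError("need finite Na > 0, T > 0, 0 < p < 1, r > 0")
        if self.side not in ("one", "two"):
            raise ParameterError("side must be 'one' or 'two'")

    # -- closed form (one-sided) ------------------------------------------
    @property
    def _ab(self) -> tuple[float, float]:
        return _rates(self.Na, self.p)

    @property
    def x_max(self) -> float:
        """Upper truncation point: survival is below ~1e-20 beyond this."""
        scale = 45.0 / (2.0 * self.T)
        return scale if self.side == "one" else 2.0 * scale

    def _survival_one(self, x):
        a, b = self._ab
        x = np.asarray(x, dtype=float)
        return np.exp(-2.0 * self.T * x) * (
            a / (a + 2.0 * x) + b / (b + 2.0 * x) - (a + b) / (a + b + 2.0 * x)
        )

    def _density_one(self, x):
        a, b = self._ab
        x = np.asarray(x, dtype=float)
        e = np.exp(-2.0 * self.T * x)
        mix = a / (a + 2.0 * x) + b / (b + 2.0 * x) - (a + b) / (a + b + 2.0 * x)
        dmix = (
            2.0 * a / (a + 2.0 * x) ** 2
            + 2.0 * b / (b + 2.0 * x) ** 2
            - 2.0 * (a + b) / (a + b + 2.0 * x) ** 2
        )
        return e * (2.0 * self.T * mix + dmix)

    # -- two-sided grid ----------------------------------------------------
    def _convolution(self) -> tuple[np.ndarray, np.ndarray]:
        """Self-convolved density on a uniform Morgan grid (cached)."""
        if self._grid is None:
            dx = self.grid_bp * self.r
            n = int(np.ceil(self.x_max / 2.0 / dx))
            if n < 100:
                raise ParameterError("convolution grid too coarse; lower grid_bp")
            xs = (np.arange(n) + 0.5) * dx
            f1 = self._density_one(xs)
            f2 = signal.fftconvolve(f1, f1) * dx
            x2 = (np.arange(f2.size) + 1.0) * dx
            # discretization can leave mass error ~dx; renormalize
            f2 /= np.trapezoid(f2, x2) + self._survival_one(xs[-1]) * 2.0
            self._grid = (x2, np.maximum(f2, 0.0))
        return self._grid

    # -- public queries ----------------------------------------------------
    def survival(self, x, unit: str = "morgans"):
        """``P(length > x)``; monotone nonincreasing from 1 to 0."""
        x = np.asarray(x, dtype=float) * (self.r if unit == "bp" else 1.0)
        if self.side == "one":
            return self._survival_one(x)
        xg, fg = self._convolution()
        cdf = np.concatenate([[0.0], integrate.cumulative_trapezoid(fg, xg)])
        s = 1.0 - np.interp(x, xg, cdf, left=0.0, right=cdf[-1])
        return s if s.shape else float(s)

    def cdf(self, x, unit: str = "morgans"):
        return 1.0 - self.survival(x, unit=unit)

    def density(self, x, unit: str = "morgans"):
        """Probability density (per Morgan, or per bp if ``unit='bp'``)."""
        scale = self.r if unit == "bp" else 1.0
        x = np.asarray(x, dtype=float) * scale
        if self.side == "one":
            return self._density_one(x) * scale
        xg, fg = self._convolution()
        out = np.interp(x, xg, fg, left=0.0, right=0.0) * scale
        return out if out.shape else float(out)

    @property
    def mean_morgans(self) -> float:
        """One-sided: numeric integral of the survival function.
        Two-sided: exactly twice the one-sided mean (independent sides)."""
        m, _ = integrate.quad(
            self._survival_one, 0.0, 45.0 / (2.0 * self.T), limit=200, epsabs=1e-14
        )
        return m if self.side == "one" else 2.0 * m

    @property
    def mean_bp(self) -> float:
        return self.mean_morgans / self.r

    def grid_mean_bp(self) -> float:
        """Mean of the numeric self-convolution itself (two-sided only);
        used to validate the grid against the exact ``2 * one-sided mean``."""
        if self.side != "two":
            raise ParameterError("grid mean is defined for the two-sided law")
        xg, fg = self._convolution()
        return np.trapezoid(fg * xg, xg) / self.r

    def quantile(self, level: float, unit: str = "bp") -> float:
        """Smallest ``x`` with ``CDF(x) >= level`` (relative tol 1e-8)."""
        if not 0 <= level < 1:
            raise ParameterError("quantile level must lie in [0, 1)")
        if level == 0:
            return 0.0
        if self.side == "one":
            f = lambda x: self._survival_one(x) - (1.0 - level)
            x = optimize.brentq(f, 0.0, self.x_max, xtol=1e-300, rtol=1e-12)
        else:
            xg, fg = self._convolution()
            cdf = np.concatenate([[0.0], integrate.cumulative_trapezoid(fg, xg)])
            cdf /= cdf[-1]
            x = float(np.interp(level, cdf, np.concatenate([[0.0], xg[1:]])))
        return x / self.r if unit == "bp" else x


def one_sided_distribution(params: ModelParams) -> LengthDistribution:
    """Marginal law of the one-sided ancestral-segment length ``X``."""
    return LengthDistribution(
        Na=params.Na, T=params.T, p=params.p, r=params.r, side="one"
    )


def two_sided_distribution(params: ModelParams, grid_bp: float = 0.05) -> LengthDistribution:
    """Law of the total (two-sided) segment length: the numeric
    self-convolution of the one-sided law."""
    return LengthDistribution(
        Na=params.Na, T=params.T, p=params.p, r=params.r, side="two", grid_bp=grid_bp
    )
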