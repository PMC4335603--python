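"""Parameter containers shared by every computation in the package.

Conventions
-----------
* Time is measured in **generations**, backward from the present.  Conversion
  from years uses a user-supplied generation time (``GENERATION_TIME_YEARS``
  defaults to 20, appropriate for apes).
* Population sizes are **diploid**: two lineages in a population of size ``N``
  coalesce at rate ``1/(2N)`` per generation.
* ``p`` is the equilibrium frequency of the **derived** allele A1 at the
  selected site (the allele whose lineages are forced to coalesce when the
  polymorphism arose); ``q = 1 - p`` is the frequency of the ancestral allele.
* Genetic distances are in Morgans; ``d = r * (bp distance)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

GENERATION_TIME_YEARS = 20.0


class ParameterError(ValueError):
    """Raised when a model parameter violates its domain."""


@dataclass(frozen=True)
class DemographyParams:
    """Two descendant species of diploid size ``Ne`` that split ``T``
    generations ago from an ancestral species of diploid size ``Na``.

    ``bottlenecks`` optionally lists per-species epochs ``(start_gen, end_gen,
    size)`` (backward in time, within ``[0, T)``) used by the neutral
    recurrent-mutation null model.
    """

    Ne: float
    Na: float
    T: float
    bottlenecks: tuple[tuple[float, float, float], ...] = ()

    def __post_init__(self) -> None:
        if not (self.Ne > 0 and self.Na > 0 and self.T > 0):
            raise ParameterError("Ne, Na and T must all be positive")
        epochs = sorted(self.bottlenecks)
        for i, (s, e, n) in enumerate(epochs):
            if not (0 <= s < e <= self.T and n > 0):
                raise ParameterError(f"bottleneck epoch {(s, e, n)} invalid")
            if i and s < epochs[i - 1][1]:
                raise ParameterError("bottleneck epochs overlap")


@dataclass(frozen=True)
class SelectionParams:
    """Balanced polymorphism: equilibrium frequency ``p`` of the derived
    allele A1, age ``Ts`` in generations measured backward from the end of
    stage II, and the harmonic-mean homozygote selection coefficient ``s``
    (used only by the fluctuating-frequency overdominance mode)."""

    p: float
    Ts: float = 0.0
    s: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.p < 1:
            raise ParameterError("p must lie strictly between 0 and 1")
        if self.Ts < 0 or self.s < 0:
            raise ParameterError("Ts and s must be non-negative")

    @property
    def q(self) -> float:
        return 1.0 - self.p


@dataclass(frozen=True)
class LocusParams:
    """Window of ``L`` base pairs with uniform per-bp per-generation
    recombination rate ``r`` and mutation rate ``mu``; the selected site sits
    at 0-based index ``selected_pos``."""

    r: float
    mu: float
    L: int = 1
    selected_pos: int = 0

    def __post_init__(self) -> None:
        if self.r < 0 or self.mu < 0:
            raise ParameterError("r and mu must be non-negative")
        if self.L < 1 or not 0 <= self.selected_pos < self.L:
            raise ParameterError("need L >= 1 and 0 <= selected_pos < L")

    def distance(self, pos: int) -> float:
        """Genetic distance (Morgans) of site ``pos`` from the selected site."""
        return self.r * abs(pos - self.selected_pos)


@dataclass(frozen=True)
class SamplingParams:
    """``n`` chromosomes sampled per species; ``class_counts`` optionally fixes
    the number sampled from each allelic class, ``(n_A1, n_A2)`` per species
    (conditioned sampling)."""

    n: int
    class_counts: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ParameterError("n must be at least 1")
        if self.class_counts is not None:
            a, b = self.class_counts
            if a < 0 or b < 0 or a + b != self.n:
                raise ParameterError("class counts must be >= 0 and sum to n")


@dataclass(frozen=True)
class ModelParams:
    """Bundle of demography, selection and locus parameters."""

    demography: DemographyParams
    selection: SelectionParams
    locus: LocusParams

    # convenience accessors used throughout
    @property
    def Ne(self) -> float:
        return self.demography.Ne

    @property
    def Na(self) -> float:
        return self.demography.Na

    @property
    def T(self) -> float:
        return self.demography.T

    @property
    def p(self) -> float:
        return self.selection.p

    @property
    def q(self) -> float:
        return self.selection.q

    @property
    def Ts(self) -> float:
        return self.selection.Ts

    @property
    def r(self) -> float:
        return self.locus.r

    @property
    def mu(self) -> float:
        return self.locus.mu


_CONFIG_KEYS = {"Ne", "Na", "T", "p", "Ts", "s", "r", "mu", "L", "selected_pos", "n", "seed"}


def load_config(path: str | Path) -> dict[str, float]:
    """Read a flat ``key = value`` config file.

    Documented keys: Ne, Na, T, p, Ts, s, r, mu, L, selected_pos, n, seed.
    Unknown keys are rejected; ``#`` starts a comment.
    """
    values: dict[str, float] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ParameterError(f"{path}:{lineno}: expected 'key = value'")
        key, _, val = line.partition("=")
        key = key.strip()
        if key not in _CONFIG_KEYS:
            raise ParameterError(f"{path}:{lineno}: unknown key {key!r}")
        values[key] = float(val.strip())
    return values


def model_params(
    Ne: float = 10_000,
    Na: float = 50_000,
    T: float = 250_000,
    p: float = 0.5,
    Ts: float = 0.0,
    s: float = 0.0,
    r: float = 1.2e-8,
    mu: float = 1.2e-8,
    L: int = 1,
    selected_pos: int = 0,
    **_ignored: float,
) -> ModelParams:
    """Build a :class:`ModelParams` from flat keyword values (config keys)."""
    return ModelParams(
        demography=DemographyParams(Ne=Ne, Na=Na, T=T),
        selection=SelectionParams(p=p, Ts=Ts, s=s),
        locus=LocusParams(r=r, mu=mu, L=int(L), selected_pos=int(selected_pos)),
    )
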