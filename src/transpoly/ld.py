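"""Pairwise linkage-disequilibrium summaries for shared SNPs.

The trans-species signature is *coupling*: around a balanced trans-species
polymorphism the same alleles ride on the same haplotypes in both species,
whereas recurrent-mutation shared SNPs show weak, phase-inconsistent LD.

All statistics are computed on **phased haplotype counts**; the chi-square LD
test is the 1-df ``n * r^2`` statistic without continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .params import ParameterError

__all__ = [
    "HaplotypeTable",
    "LDResult",
    "pairwise_ld",
    "ld_significance",
    "coupling_phase",
    "retention_probability",
    "simulate_retention",
]


@dataclass(frozen=True)
class HaplotypeTable:
    """2x2 phased two-locus haplotype counts for one species.

    ``n11`` counts haplotypes carrying allele 1 at both loci, ``n12`` allele 1
    at the first locus and allele 2 at the second, etc.  Allele labels must be
    assigned consistently across species (order alleles lexicographically by
    nucleotide at each site) so that coupling-phase comparisons are stable.
    """

    n11: int
    n12: int
    n21: int
    n22: int

    def __post_init__(self) -> None:
        if min(self.n11, self.n12, self.n21, self.n22) < 0:
            raise ParameterError("haplotype counts must be non-negative")
        if self.total < 2:
            raise ParameterError("need at least two haplotypes")

    @classmethod
    def from_haplotypes(cls, x: np.ndarray, y: np.ndarray) -> "HaplotypeTable":
        """Build from two aligned 0/1 haplotype columns (0 = allele 1)."""
        x = np.asarray(x).astype(int)
        y = np.asarray(y).astype(int)
        if x.shape != y.shape:
            raise ParameterError("haplotype columns must have equal length")
        return cls(
            n11=int(np.sum((x == 0) & (y == 0))),
            n12=int(np.sum((x == 0) & (y == 1))),
            n21=int(np.sum((x == 1) & (y == 0))),
            n22=int(np.sum((x == 1) & (y == 1))),
        )

    @property
    def total(self) -> int:
        return self.n11 + self.n12 + self.n21 + self.n22

    @property
    def freqs(self) -> tuple[float, float]:
        """Allele-1 frequency at each locus."""
        n = self.total
        return (self.n11 + self.n12) / n, (self.n11 + self.n21) / n

    @property
    def both_polymorphic(self) -> bool:
        fA, fB = self.freqs
        return 0 < fA < 1 and 0 < fB < 1


@dataclass(frozen=True)
class LDResult:
    """``D``, ``D'`` and ``r^2`` for one species; ``defined`` is False when
    either locus is monomorphic (the values are then NaN, not an error)."""

    D: float
    Dprime: float
    r2: float
    n: int
    defined: bool


def pairwise_ld(table: HaplotypeTable) -> LDResult:
    """Standard two-locus LD from phased counts.

    ``D = f(11) - f(1.)f(.1)``; ``r^2 = D^2 / (fA fa fB fb)``; ``D'``
    normalizes ``D`` by its frequency bound.  Two-haplotype tables (e.g. only
    ``11`` and ``22`` present) give ``r^2 = 1``.
    """
    if not table.both_polymorphic:
        return LDResult(np.nan, np.nan, np.nan, table.total, defined=False)
    n = table.total
    fA, fB = table.freqs
    D = table.n11 / n - fA * fB
    denom = fA * (1 - fA) * fB * (1 - fB)
    r2 = D * D / denom
    if D >= 0:
        bound = min(fA * (1 - fB), (1 - fA) * fB)
    else:
        bound = min(fA * fB, (1 - fA) * (1 - fB))
    dprime = 0.0 if D == 0 else D / bound
    return LDResult(D=D, Dprime=dprime, r2=r2, n=n, defined=True)


def ld_significance(
    table: HaplotypeTable, alpha: float = 0.05
) -> tuple[float, float, bool]:
    """1-df chi-square LD test on phased haplotypes: ``chi2 = n * r^2``.

    Returns ``(chi2, p_value, significant)``; undefined LD (monomorphic
    locus) gives ``(nan, nan, False)``.
    """
    res = pairwise_ld(table)
    if not res.defined:
        return np.nan, np.nan, False
    chi2 = res.n * res.r2
    pval = float(stats.chi2.sf(chi2, df=1))
    return chi2, pval, pval < alpha


def coupling_phase(tableA: HaplotypeTable, tableB: HaplotypeTable) -> str:
    """Compare coupling phase between two species.

    ``'same'`` if ``sign(D)`` matches under the shared allele labelling,
    ``'opposite'`` if it differs, ``'indeterminate'`` if either ``D`` is zero
    or undefined.
    """
    a, b = pairwise_ld(tableA), pairwise_ld(tableB)
    if not (a.defined and b.defined) or a.D == 0 or b.D == 0:
        return "indeterminate"
    return "same" if (a.D > 0) == (b.D > 0) else "opposite"


def retention_probability(n: int, p: float, Ne: float, d: float) -> float:
    """Approximate probability ``R_n`` that a sampled lineage of the focal
    allelic class does not switch class during stage I.

    Stage I is the within-species coalescence of the ``n`` sampled
    class-members (class frequency ``p``, diploid size ``Ne``) into a single
    lineage; the focal lineage switches by recombination at rate
    ``d*(1-p)`` per generation while it persists.  We approximate
    ``R_n = E[exp(-d q T_path)]`` by ``exp(-d q E[T_mrca])`` with
    ``E[T_mrca] = 4 Ne p (1 - 1/n)``; by Jensen's inequality this
    *underestimates* retention (hence the LD it predicts), so it is a
    conservative lower bound -- the simulation estimator
    :func:`simulate_retention` is the reference.
    """
    if n < 1:
        raise ParameterError("n must be at least 1")
    if d < 0:
        raise ParameterError("d must be non-negative")
    q = 1.0 - p
    t_mrca = 4.0 * Ne * p * (1.0 - 1.0 / n)
    return float(np.exp(-d * q * t_mrca))


def simulate_retention(
    n: int,
    p: float,
    Ne: float,
    d: float,
    replicates: int = 2000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Monte-Carlo estimate of ``R_n`` (mean, standard error).

    Simulates the ``n``-lineage Kingman coalescent within the class (pairwise
    rate ``1/(2 Ne p)``) and exposes a focal lineage to class-switching at
    rate ``d*(1-p)``; retention means the focal lineage's path to the class
    MRCA carries no switch.
    """
    rng = np.random.default_rng(seed)
    q = 1.0 - p
    rate_pair = 1.0 / (2.0 * Ne * p)
    kept = 0
    for _ in range(replicates):
        k = n
        t_path = 0.0  # time the focal lineage existed before the class MRCA
        while k > 1:
            wait = rng.exponential(1.0 / (rate_pair * k * (k - 1) / 2.0))
            t_path += wait
            k -= 1
        # no switch anywhere on the focal path of total length t_path
        if rng.random() < np.exp(-d * q * t_path):
            kept += 1
    mean = kept / replicates
    se = np.sqrt(mean * (1 - mean) / replicates)
    return mean, se
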