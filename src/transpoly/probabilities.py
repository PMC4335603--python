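"""Elementary probabilities for trans-species polymorphisms.

These are the back-of-the-envelope quantities that determine whether a pair of
species is suitable for a trans-species polymorphism scan: how likely neutral
incomplete lineage sorting (ILS) is to mimic the signal, how likely a random
sample is to capture both selected alleles, and how much archaic admixture
inflates the ILS probability.
"""

from __future__ import annotations

import math

from .params import ParameterError

__all__ = [
    "capture_probability",
    "neutral_ils_probability",
    "introgression_fold_change",
]


def capture_probability(p: float, n: int) -> float:
    """Probability that ``n`` chromosomes sampled at random from each of the
    two species capture both alleles of the balanced polymorphism (frequency
    ``p``) in both species: ``(1 - p**n - q**n)**2``.

    Symmetric in ``p`` vs ``1 - p``, maximal at ``p = 0.5``, nondecreasing in
    ``n``.
    """
    if not 0 < p < 1:
        raise ParameterError("p must lie strictly between 0 and 1")
    if n < 1:
        raise ParameterError("n must be at least 1")
    q = 1.0 - p
    one = max(0.0, 1.0 - p**n - q**n)
    return one * one


def neutral_ils_probability(T: float, Ne: float) -> float:
    """Approximate probability that a *neutral* polymorphism is shared by both
    species through incomplete lineage sorting.

    Requires two lineages per species to survive back to the split, giving
    ``exp(-T/(2*Ne)) * exp(-T/(2*Ne))`` for diploid size ``Ne`` and split time
    ``T`` generations; strictly decreasing in ``T`` and increasing in ``Ne``.
    """
    if T < 0:
        raise ParameterError("T must be non-negative")
    if Ne <= 0:
        raise ParameterError("Ne must be positive")
    return math.exp(-T / (2.0 * Ne)) ** 2


def introgression_fold_change(T_archaic: float, Ne: float) -> float:
    """Factor by which archaic admixture inflates the neutral ILS probability.

    Introgressed haplotypes only need to survive back to the archaic split,
    ``T_archaic`` generations ago, instead of to the species split: one of the
    two survival terms is shortened by ``T_archaic``, inflating the product by
    ``exp(T_archaic/(2*Ne))``.  For modern humans receiving Neanderthal /
    Denisovan gene flow (T_archaic ~ 440 Kya at 20 y/gen, Ne = 10,000) the
    factor is about three.
    """
    if T_archaic < 0:
        raise ParameterError("T_archaic must be non-negative")
    if Ne <= 0:
        raise ParameterError("Ne must be positive")
    return math.exp(T_archaic / (2.0 * Ne))
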