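"""Coalescent times of two lineages near the selected site, and the expected
number of shared neutral SNPs in the ancestral segment.

Two regimes are covered:

* **Infinitely old polymorphism** -- the two allelic classes behave as a
  two-deme finite-island model (deme sizes ``p*Na`` and ``q*Na``; an A1
  lineage moves to the A2 background by class-switching recombination at rate
  ``d*q`` per generation, an A2 lineage at ``d*p``; no reverse mutation).
  First-step analysis gives closed-form expected coalescent times.

* **Finite age** -- a discrete per-generation Markov chain over the state of
  the two neutral-site lineages.  During the selection phase (the most recent
  ``Ts`` generations of stage III) the state is ``(n1, n2)``: how many of the
  lineages sit on the derived-A1 / ancestral-A2 background, with coalesced
  states merged into the absorbing ``(*)``.  At the moment the polymorphism
  arose, every lineage on the derived background descends from the single
  founder chromosome, so ``(2,0)`` is forced into ``(*)`` (the ``Q_SN``
  bridge); the remaining process is a neutral pairwise coalescent in the
  ancestral species (``P_N``).

The expected number of shared neutral SNPs at distance ``d`` is proportional
to the expected pairwise coalescent time ``E[T_B](d)`` of the neutral site's
two stage-III lineages: each of the two branches accumulates mutations at
rate ``mu`` per generation, and a mutation on either branch is carried into
both species by the two allelic-class MRCAs provided the site stays inside
the ancestral segment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import ModelParams, ParameterError
from .segment_length import one_sided_distribution, stage2_time_mean

__all__ = [
    "IslandModelTimes",
    "infinite_age_times",
    "ChainMatrices",
    "build_chain_matrices",
    "expected_TB_numeric",
    "expected_TB_approx",
    "expected_shared_snps",
    "age_from_present_to_Ts",
]

#: fixed state ordering of the selection-phase chain
SELECTION_STATES = ("(1,1)", "(0,2)", "(2,0)", "(*)")
NEUTRAL_STATES = ("(**)", "(*)")


@dataclass(frozen=True)
class IslandModelTimes:
    """Expected coalescent times (generations) at genetic distance ``d`` for
    an infinitely old polymorphism: two A1 lineages (``T1``), two A2 lineages
    (``T2``), one of each (``TB``, infinite at ``d = 0``)."""

    T1: float
    T2: float
    TB: float
    d: float

    @property
    def TB_is_infinite(self) -> bool:
        return math.isinf(self.TB)


def infinite_age_times(d: float, Na: float, p: float) -> IslandModelTimes:
    """Solve the island-model first-step recursions.

    With ``c1 = 1/(2*Na*p)``, ``c2 = 1/(2*Na*q)``, switch rates ``m1 = d*q``
    (per A1 lineage) and ``m2 = d*p``::

        T1 = 1/(c1 + 2*m1) + (2*m1/(c1 + 2*m1)) * TB
        T2 = 1/(c2 + 2*m2) + (2*m2/(c2 + 2*m2)) * TB
        TB = 1/d + (m1*T2 + m2*T1)/d          (m1 + m2 = d)

    ``d = 0`` returns the isolated-deme limit with ``TB`` infinite (signalled
    through :attr:`IslandModelTimes.TB_is_infinite`, not an exception); all
    three tend to ``2*Na`` as ``d`` grows (panmictic limit).
    """
    if d < 0:
        raise ParameterError("d must be non-negative")
    if not (Na > 0 and 0 < p < 1):
        raise ParameterError("need Na > 0 and 0 < p < 1")
    q = 1.0 - p
    if d == 0:
        return IslandModelTimes(T1=2 * Na * p, T2=2 * Na * q, TB=math.inf, d=0.0)
    c1, c2 = 1.0 / (2 * Na * p), 1.0 / (2 * Na * q)
    m1, m2 = d * q, d * p
    A = np.array(
        [
            [1.0, 0.0, -2 * m1 / (c1 + 2 * m1)],
            [0.0, 1.0, -2 * m2 / (c2 + 2 * m2)],
            [-m2 / d, -m1 / d, 1.0],
        ]
    )
    rhs = np.array([1.0 / (c1 + 2 * m1), 1.0 / (c2 + 2 * m2), 1.0 / d])
    T1, T2, TB = np.linalg.solve(A, rhs)
    return IslandModelTimes(T1=float(T1), T2=float(T2), TB=float(TB), d=d)


@dataclass(frozen=True)
class ChainMatrices:
    """Per-generation transition matrices of the finite-age chain.

    ``PS`` is 4x4 over :data:`SELECTION_STATES`, ``PN`` 2x2 over
    :data:`NEUTRAL_STATES`, and ``QSN`` the 4x2 bridge applied at the phase
    boundary (the derived-background pair ``(2,0)`` is forced into ``(*)``).
    """

    PS: np.ndarray
    PN: np.ndarray
    QSN: np.ndarray
    d: float
    Na: float
    p: float


def build_chain_matrices(d: float, Na: float, p: float) -> ChainMatrices:
    """Exact one-generation transition probabilities.

    Within a generation each lineage first recombines onto the opposite
    background (probability ``d*q`` from A1, ``d*p`` from A2) and the two
    lineages then coalesce with probability ``1/(2*Na*f)`` if they share a
    background of frequency ``f``.
    """
    if d < 0:
        raise ParameterError("d must be non-negative")
    q = 1.0 - p
    s1, s2 = d * q, d * p  # switch probabilities for an A1 / A2 lineage
    c1, c2 = 1.0 / (2 * Na * p), 1.0 / (2 * Na * q)
    if max(s1, s2) > 1 or max(c1, c2) >= 1:
        raise ParameterError(
            "per-generation probability exceeds 1: reduce d or increase Na"
        )
    PS = np.zeros((4, 4))
    # from (1,1): only one lineage switching can lead to a shared background
    a = s1 * (1 - s2)  # A1 switched -> both on A2
    b = s2 * (1 - s1)  # A2 switched -> both on A1
    PS[0, 1] = a * (1 - c2)
    PS[0, 2] = b * (1 - c1)
    PS[0, 3] = a * c2 + b * c1
    PS[0, 0] = 1.0 - PS[0, 1:].sum()
    # from (0,2): both on the ancestral background (each switches w.p. s2)
    PS[1, 0] = 2 * s2 * (1 - s2)
    PS[1, 2] = s2 * s2
    PS[1, 3] = (1 - s2) ** 2 * c2
    PS[1, 1] = 1.0 - PS[1, 0] - PS[1, 2] - PS[1, 3]
    # from (2,0): both on the derived background
    PS[2, 0] = 2 * s1 * (1 - s1)
    PS[2, 1] = s1 * s1
    PS[2, 3] = (1 - s1) ** 2 * c1
    PS[2, 2] = 1.0 - PS[2, 0] - PS[2, 1] - PS[2, 3]
    PS[3, 3] = 1.0
    cn = 1.0 / (2 * Na)
    PN = np.array([[1 - cn, cn], [0.0, 1.0]])
    QSN = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0], [0.0, 1.0]])
    return ChainMatrices(PS=PS, PN=PN, QSN=QSN, d=d, Na=Na, p=p)


def _selection_phase(
    mats: ChainMatrices, Ts: int, method: str
) -> tuple[float, np.ndarray]:
    """Expected non-absorbed generations during the selection phase and the
    state distribution after ``Ts`` steps (transient states only)."""
    Pt = mats.PS[:3, :3]
    v0 = np.array([1.0, 0.0, 0.0])
    if method == "survival-sum":
        v = v0.copy()
        steps = 0.0
        for _ in range(Ts):
            steps += v.sum()
            v = v @ Pt
        return steps, v
    if method != "fundamental":
        raise ParameterError("method must be 'survival-sum' or 'fundamental'")
    I = np.eye(3)
    PT = np.linalg.matrix_power(Pt, Ts)
    if mats.d == 0:
        # (1,1) is invariant: no event can occur during selection
        return float(Ts), v0 @ PT
    # sum_{g=0}^{Ts-1} v0 Pt^g = v0 (I - Pt)^{-1} (I - Pt^Ts)
    partial = np.linalg.solve((I - Pt).T, v0) @ (I - PT)
    return float(partial.sum()), v0 @ PT


def expected_TB_numeric(
    d: float, Na: float, p: float, Ts: float, method: str = "fundamental"
) -> float:
    """Expected absorption time (generations) into ``(*)`` from ``(1,1)``.

    Accumulates the survival probability over the ``Ts`` selection-phase
    generations, applies the ``Q_SN`` bridge, then closes the neutral
    geometric tail analytically (expected ``2*Na`` further generations for a
    surviving pair).  ``method='survival-sum'`` iterates the state vector one
    generation at a time; ``method='fundamental'`` (default) uses the
    fundamental matrix of the transient block -- the two agree to ~1e-8
    relative and the latter is O(log Ts).
    """
    if Ts < 0:
        raise ParameterError("Ts must be non-negative")
    mats = build_chain_matrices(d, Na, p)
    steps, v = _selection_phase(mats, int(round(Ts)), method)
    w = np.concatenate([v, [0.0]]) @ mats.QSN  # mass on (**) survives
    return steps + w[0] * 2.0 * Na


def expected_TB_approx(d: float, Na: float, p: float, Ts: float) -> float:
    """Closed-form-style approximation ignoring recombination once the chain
    leaves ``(1,1)`` (upper-triangular selection matrix).  Underestimates the
    numeric value: returning to ``(1,1)`` -- where coalescence is impossible
    -- can only delay absorption."""
    if Ts < 0:
        raise ParameterError("Ts must be non-negative")
    mats = build_chain_matrices(d, Na, p)
    PSu = mats.PS.copy()
    for i, j in ((1, 0), (1, 2), (2, 0), (2, 1)):
        PSu[i, i] += PSu[i, j]
        PSu[i, j] = 0.0
    tri = ChainMatrices(PS=PSu, PN=mats.PN, QSN=mats.QSN, d=d, Na=Na, p=p)
    steps, v = _selection_phase(tri, int(round(Ts)), "fundamental")
    w = np.concatenate([v, [0.0]]) @ mats.QSN
    return steps + w[0] * 2.0 * Na


def age_from_present_to_Ts(
    age: float, params: ModelParams, stage1_gens: float | None = None
) -> float:
    """Convert a polymorphism age measured from the present into ``Ts``.

    The age from the present is ``Ts`` plus the expected lengths of stages I
    and II: the split time ``T``, the expected extra ancestral coalescence
    time ``E[max(t1, t2)]``, and ``stage1_gens`` for stage I (default
    ``4*Ne``).
    """
    if stage1_gens is None:
        stage1_gens = 4.0 * params.Ne
    Ts = age - params.T - stage2_time_mean(params.Na, params.p) - stage1_gens
    if Ts < 0:
        raise ParameterError("age from present must exceed the expected stage I+II span")
    return Ts


def expected_shared_snps(
    params: ModelParams,
    age: float | None = None,
    mode: str = "marginal",
    fixed_one_sided_bp: int | None = None,
    max_bp: int | None = None,
) -> float:
    """Expected number of shared SNPs in the ancestral segment (including the
    selected one).

    ``1 + sum_i P(site i inside the segment) * 2 * mu * E[T_B](d_i)`` summed
    over sites on both sides of the selected site, with ``d_i = r * i``.

    ``mode='marginal'`` weights each site by the one-sided segment survival
    ``P(X > d_i)``; ``mode='fixed'`` conditions on a segment extending
    ``fixed_one_sided_bp`` base pairs on each side.  ``age`` is measured from
    the present (converted through :func:`age_from_present_to_Ts`); if
    omitted, ``params.Ts`` is used directly.
    """
    mu = params.mu
    if mu == 0:
        return 1.0
    Ts = params.Ts if age is None else age_from_present_to_Ts(age, params)
    dist = one_sided_distribution(params)
    # per-side spans, truncated by the window when one is configured
    loc = params.locus
    window_sides = (loc.selected_pos, loc.L - 1 - loc.selected_pos)
    if mode == "fixed":
        if fixed_one_sided_bp is None:
            raise ParameterError("fixed mode needs fixed_one_sided_bp")
        span = int(fixed_one_sided_bp)
        weight = lambda i: 1.0
    elif mode == "marginal":
        span = max_bp if max_bp is not None else int(
            np.ceil(dist.quantile(1 - 1e-6, unit="bp"))
        )
        weight = lambda i: float(dist.survival(i, unit="bp"))
    else:
        raise ParameterError("mode must be 'marginal' or 'fixed'")
    total = 1.0
    tb_cache: dict[int, float] = {}
    for side_limit in window_sides:
        if loc.L > 1:
            side_span = min(span, side_limit)
        else:
            side_span = 0  # selected site only
        for i in range(1, side_span + 1):
            if i not in tb_cache:
                tb_cache[i] = expected_TB_numeric(params.r * i, params.Na, params.p, Ts)
            total += weight(i) * 2.0 * mu * tb_cache[i]
    return float(total)
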