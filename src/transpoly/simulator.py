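"""Structured-coalescent simulator conditional on a biallelic trans-species
balanced polymorphism.

The model follows the Hudson--Kaplan framework: the two allelic classes at
the selected site act as subpopulations of sizes ``p*N`` and ``q*N``; lineages
coalesce only within a class and move between classes by *class-switching*
recombination.  Backward in time the sample passes through three phases:

1. within each descendant species (diploid size ``Ne``) for ``T``
   generations, classes of frequencies ``p`` and ``q``;
2. in the ancestral species (size ``Na``), same class structure, until the
   balanced polymorphism arose;
3. at the origin every lineage on the derived (A1) background coalesces into
   the single founder chromosome; from then on a single neutral panmictic
   class of size ``Na``.

The origin is placed either ``Ts`` generations after the end of stage II
(when the selected site's lineages have coalesced to one per class --
``age_mode='Ts'``) or at an absolute time from the present
(``age_mode='age'``).

Multi-locus ancestry is tracked exactly (no sequentially-Markov
approximation): each lineage carries a list of ancestral-material segments in
continuous coordinates on the ``L``-bp window; crossovers fall uniformly on
the span between the lineage's material and the selected site, and the piece
on the far side of the crossover from the selected site lands on a background
drawn from the class frequencies.  The recorded nodes and edges are exported
as a :class:`tskit.TreeSequence`, so marginal trees, Newick output and
mutation dropping (infinite sites within the window, via ``msprime``) come
from the standard tools.
"""

from __future__ import annotations

from dataclasses import dataclass

import msprime
import numpy as np
import tskit

from .params import ModelParams, ParameterError, SamplingParams

__all__ = [
    "SimulatedSample",
    "FrequencyTrajectory",
    "simulate_sample",
    "classify_topology",
    "ancestral_segment_extent",
    "simulate_overdominance_trajectory",
]

TOPOLOGY_CLASSES = ("ancestral", "one-recombined", "species-long", "species-short")


class _Lineage:
    __slots__ = ("segs", "cls", "species")

    def __init__(self, segs, cls, species):
        self.segs = segs  # list of [left, right, node, n_samples]
        self.cls = cls  # 0 = derived A1, 1 = ancestral A2
        self.species = species  # 0/1, or -1 once in the ancestral species

    def span(self, sel: float) -> float:
        lo = min(self.segs[0][0], sel)
        hi = max(self.segs[-1][1], sel)
        return hi - lo

    def carries(self, x: float) -> bool:
        return any(l <= x < r for l, r, _, _ in self.segs)


@dataclass
class FrequencyTrajectory:
    """Per-generation frequency of the derived allele A1, indexed backward
    from the present, conditioned on segregation throughout."""

    freqs: np.ndarray
    s: float

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        if f.ndim != 1 or f.size < 1:
            raise ParameterError("trajectory must be a non-empty 1-d array")
        if np.any((f <= 0) | (f >= 1)):
            raise ParameterError("trajectory frequencies must lie in (0, 1)")
        self.freqs = f


@dataclass
class SimulatedSample:
    """Result of :func:`simulate_sample`.

    ``ts`` is a tskit tree sequence over the ``L``-bp window (continuous
    coordinates; site ``k`` occupies ``[k, k+1)``) carrying infinite-sites
    neutral mutations plus the selected site, whose column carries allele 1
    for samples in the derived class A1 (``classes == 0``).
    """

    params: ModelParams
    sampling: SamplingParams
    seed: int
    ts: tskit.TreeSequence
    species: np.ndarray  # per-sample species (0/1)
    classes: np.ndarray  # per-sample allelic class (0 = A1)
    selected_position: float
    stage2_end: float
    origin: float

    @property
    def haplotypes(self) -> np.ndarray:
        """Sites x samples 0/1 matrix (includes the selected column)."""
        return self.ts.genotype_matrix()

    @property
    def positions(self) -> np.ndarray:
        return self.ts.sites_position

    @property
    def selected_column(self) -> int:
        return int(np.searchsorted(self.positions, self.selected_position))

    def breakpoints(self) -> np.ndarray:
        return np.array(list(self.ts.breakpoints()))

    def topology_classes(self, threshold: float | None = None):
        """Per-tree topology class, as ``[(left, right, class), ...]``."""
        out = []
        for tree in self.ts.trees():
            cls = classify_topology(
                tree,
                species=self.species,
                classes=self.classes,
                split_time=self.params.T,
                Na=self.params.Na,
                threshold=threshold,
            )
            out.append((tree.interval.left, tree.interval.right, cls))
        return out

    def newick_trees(self) -> list[tuple[float, float, str]]:
        return [
            (t.interval.left, t.interval.right, t.as_newick()) for t in self.ts.trees()
        ]


def _wf_step(f: np.ndarray, N: float, s1: float, s2: float, rng) -> np.ndarray:
    """One Wright-Fisher generation with overdominance viabilities
    ``1-s1 : 1 : 1-s2`` for A1A1 : A1A2 : A2A2."""
    q = 1.0 - f
    wbar = 1.0 - s1 * f * f - s2 * q * q
    fsel = f * (1.0 - s1 * f) / wbar
    return rng.binomial(int(2 * N), fsel) / (2.0 * N)


def simulate_overdominance_trajectory(
    s: float,
    N: float,
    span: int,
    seed: int | None = None,
    equilibrium_p: float = 0.5,
    max_tries: int = 200,
) -> FrequencyTrajectory:
    """Discrete Wright-Fisher overdominance trajectory conditioned on
    segregation over ``span`` generations.

    ``s`` is the harmonic mean of the two homozygote selection coefficients;
    with equilibrium frequency ``p*`` the homozygote coefficients are
    ``s1 = s/(2p*)`` and ``s2 = s/(2q*)``, which reproduces both the harmonic
    mean (``2 s1 s2/(s1+s2) = s``) and the equilibrium
    (``s2/(s1+s2) = p*``).  Paths hitting 0 or 1 are rejected; exceeding the
    rejection budget raises with the observed conditioning failure rate.
    """
    return simulate_overdominance_trajectories(
        s, N, span, 1, seed=seed, equilibrium_p=equilibrium_p, max_tries=max_tries
    )[0]


def simulate_overdominance_trajectories(
    s: float,
    N: float,
    span: int,
    n_paths: int,
    seed: int | None = None,
    equilibrium_p: float = 0.5,
    max_tries: int = 2000,
) -> list[FrequencyTrajectory]:
    """Batch version of :func:`simulate_overdominance_trajectory`: one
    vectorized Wright-Fisher sweep yields many independent conditioned
    paths."""
    if s < 0 or span < 1:
        raise ParameterError("need s >= 0 and span >= 1")
    if not 0 < equilibrium_p < 1:
        raise ParameterError("equilibrium_p must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    s1 = s / (2.0 * equilibrium_p)
    s2 = s / (2.0 * (1.0 - equilibrium_p))
    out: list[FrequencyTrajectory] = []
    tries = 0
    while len(out) < n_paths and tries < max_tries:
        batch = max(16, n_paths - len(out))
        f = np.full(batch, equilibrium_p)
        alive = np.ones(batch, dtype=bool)
        path = np.empty((span, batch))
        for g in range(span):
            f = _wf_step(f, N, s1, s2, rng)
            alive &= (f > 0) & (f < 1)
            f = np.clip(f, 0.5 / (2 * N), 1 - 0.5 / (2 * N))  # keep arithmetic sane
            path[g] = f
        tries += batch
        for idx in np.flatnonzero(alive):
            if len(out) < n_paths:
                out.append(FrequencyTrajectory(freqs=path[:, idx].copy(), s=s))
    if len(out) < n_paths:
        raise ParameterError(
            f"conditioning on segregation failed: {len(out)}/{n_paths} paths in "
            f"{tries} tries (failure rate {1 - len(out) / max(tries, 1):.2f}); "
            "increase N*s or reduce span"
        )
    return out


# ---------------------------------------------------------------------------
# core backward simulation
# ---------------------------------------------------------------------------


def simulate_sample(
    params: ModelParams,
    sampling: SamplingParams | None = None,
    seed: int | None = None,
    age_mode: str = "Ts",
    age: float | None = None,
    trajectory: FrequencyTrajectory | None = None,
    mutate: bool = True,
    sample_config: list[tuple[int, int, int]] | None = None,
) -> SimulatedSample:
    """Simulate a conditioned sample around a balanced trans-species
    polymorphism.  Deterministic given ``seed``.

    ``sampling.class_counts`` fixes how many chromosomes per species carry
    each allele (default: balanced); at least one lineage per class per
    species is required, which conditions on the polymorphism being observed
    in both species.  ``age_mode='Ts'`` places the polymorphism's origin
    ``params.Ts`` generations after the end of stage II; ``age_mode='age'``
    places it ``age`` generations before the present.  ``trajectory``
    optionally replaces the constant ``p`` during the selection phases by a
    fluctuating per-generation frequency (piecewise-constant over 100-
    generation chunks).  ``sample_config`` -- a list of ``(species, class,
    count)`` tuples -- overrides the default balanced two-species sampling
    for special designs (e.g. two lineages, one per class, in one species);
    such configs skip the both-species conditioning check.
    """
    sampling = sampling or SamplingParams(n=2, class_counts=(1, 1))
    if sample_config is None:
        if sampling.class_counts is None:
            half = sampling.n // 2
            if half == 0 or sampling.n - half == 0:
                raise ParameterError("need at least one lineage per class per species")
            counts = (half, sampling.n - half)
        else:
            counts = sampling.class_counts
        if min(counts) < 1:
            raise ParameterError("need at least one lineage per class per species")
        sample_config = [
            (sp, cls, counts[cls]) for sp in (0, 1) for cls in (0, 1)
        ]
    if not any(cnt > 0 and cls == 0 for _, cls, cnt in sample_config) or not any(
        cnt > 0 and cls == 1 for _, cls, cnt in sample_config
    ):
        raise ParameterError("sample must include both allelic classes")
    if age_mode not in ("Ts", "age"):
        raise ParameterError("age_mode must be 'Ts' or 'age'")
    if age_mode == "age":
        if age is None:
            raise ParameterError("age_mode='age' requires an age")
        if age < params.T:
            raise ParameterError("age from present must exceed the split time")

    rng = np.random.default_rng(seed)
    L = float(params.locus.L)
    sel = params.locus.selected_pos + 0.5
    rr = params.r
    Ne, Na, T, Ts = params.Ne, params.Na, params.T, params.Ts

    # frequency lookup (chunked when a trajectory is supplied)
    chunk = 100.0
    if trajectory is not None:
        traj = trajectory.freqs
        n_chunks = int(np.ceil(traj.size / chunk))
        chunk_p = np.array(
            [traj[int(i * chunk) : int((i + 1) * chunk)].mean() for i in range(n_chunks)]
        )

        def p_at(t: float) -> float:
            i = int(t // chunk)
            return float(chunk_p[i]) if i < n_chunks else float(params.p)

        def next_chunk_bound(t: float) -> float:
            b = (int(t // chunk) + 1) * chunk
            return b if b <= n_chunks * chunk else np.inf

    else:
        p_at = lambda t: params.p
        next_chunk_bound = lambda t: np.inf

    # -- sample setup ------------------------------------------------------
    node_time: list[float] = []
    node_flags: list[int] = []
    edges: list[tuple[float, float, int, int]] = []
    species_lab: list[int] = []
    class_lab: list[int] = []
    lineages: list[_Lineage] = []
    for sp, cls, k in sample_config:
        for _ in range(k):
            nid = len(node_time)
            node_time.append(0.0)
            node_flags.append(tskit.NODE_IS_SAMPLE)
            species_lab.append(sp)
            class_lab.append(cls)
            lineages.append(_Lineage([[0.0, L, nid, 1]], cls, sp))
    n_total = len(lineages)

    def new_node(t: float) -> int:
        node_time.append(t)
        node_flags.append(0)
        return len(node_time) - 1

    def merge(group: list[_Lineage], t: float) -> _Lineage | None:
        """Coalesce the lineages in ``group`` into one at time ``t``."""
        parent = new_node(t)
        points = sorted({x for lin in group for s in lin.segs for x in (s[0], s[1])})
        out_segs = []
        for lo, hi in zip(points[:-1], points[1:]):
            carriers = []
            for lin in group:
                for l, r_, node, cnt in lin.segs:
                    if l <= lo and hi <= r_:
                        carriers.append((node, cnt))
                        break
            if not carriers:
                continue
            if len(carriers) == 1:
                out_segs.append([lo, hi, carriers[0][0], carriers[0][1]])
            else:
                total = 0
                for node, cnt in carriers:
                    edges.append((lo, hi, parent, node))
                    total += cnt
                if total < n_total:  # interval MRCA not yet reached
                    out_segs.append([lo, hi, parent, total])
        if not out_segs:
            return None
        # merge adjacent equal segments
        merged = [out_segs[0]]
        for seg in out_segs[1:]:
            last = merged[-1]
            if seg[0] == last[1] and seg[2] == last[2] and seg[3] == last[3]:
                last[1] = seg[1]
            else:
                merged.append(seg)
        return _Lineage(merged, group[0].cls, group[0].species)

    def sel_carrier_counts() -> tuple[int, int]:
        c = [0, 0]
        for lin in lineages:
            if lin.carries(sel):
                c[lin.cls] += 1
        return c[0], c[1]

    t = 0.0
    phase = 0  # 0: two species; 1: ancestral under selection; 2: neutral
    origin = age if age_mode == "age" else None
    stage2_end = None

    def maybe_close_stage2(now: float) -> None:
        nonlocal stage2_end, origin
        if stage2_end is not None or phase == 0:
            return
        c0, c1 = sel_carrier_counts()
        if c0 <= 1 and c1 <= 1:
            stage2_end = now
            if age_mode == "Ts":
                origin = now + max(Ts, 1e-6)

    while True:
        lineages = [lin for lin in lineages if lin.segs]
        if not lineages:
            break
        p_now = p_at(t) if phase < 2 else params.p
        q_now = 1.0 - p_now
        # group coalescence rates
        groups: dict[tuple, list[_Lineage]] = {}
        for lin in lineages:
            if phase == 0:
                key = (lin.species, lin.cls)
            elif phase == 1:
                key = (lin.cls,)
            else:
                key = ()
            groups.setdefault(key, []).append(lin)
        coal_rates = []
        for key, members in groups.items():
            k = len(members)
            if k < 2:
                coal_rates.append((key, 0.0))
                continue
            if phase == 2:
                rate = k * (k - 1) / 2.0 / (2.0 * Na)
            else:
                N = Ne if phase == 0 else Na
                f = p_now if key[-1] == 0 else q_now
                rate = k * (k - 1) / 2.0 / (2.0 * N * f)
            coal_rates.append((key, rate))
        rec_rates = [rr * lin.span(sel) for lin in lineages]
        R = sum(r_ for _, r_ in coal_rates) + sum(rec_rates)

        # next phase boundary
        bounds = []
        if phase == 0:
            bounds.append(T)
        if origin is not None and phase < 2:
            bounds.append(origin)
        if phase < 2:
            cb = next_chunk_bound(t)
            if np.isfinite(cb):
                bounds.append(cb)
        boundary = min(bounds) if bounds else np.inf

        t_next = t + rng.exponential(1.0 / R) if R > 0 else np.inf
        if t_next >= boundary:
            t = boundary
            if phase == 0 and t >= T:
                for lin in lineages:
                    lin.species = -1
                phase = 1
                maybe_close_stage2(t)
            if origin is not None and t >= origin and phase == 1:
                derived = [lin for lin in lineages if lin.cls == 0]
                if len(derived) >= 2:
                    parent = merge(derived, t)
                    lineages = [lin for lin in lineages if lin.cls != 0]
                    if parent is not None:
                        lineages.append(parent)
                phase = 2
            continue

        t = t_next
        u = rng.random() * R
        # recombination?
        for lin, rrate in zip(lineages, rec_rates):
            if u < rrate:
                lo = min(lin.segs[0][0], sel)
                hi = max(lin.segs[-1][1], sel)
                x = lo + rng.random() * (hi - lo)
                left, right = [], []
                for l, r_, node, cnt in lin.segs:
                    if r_ <= x:
                        left.append([l, r_, node, cnt])
                    elif l >= x:
                        right.append([l, r_, node, cnt])
                    else:
                        left.append([l, x, node, cnt])
                        right.append([x, r_, node, cnt])
                far = left if x <= sel else right  # piece away from sel
                near = right if x <= sel else left
                new_cls = (0 if rng.random() < p_now else 1) if phase < 2 else lin.cls
                if far and near:
                    lin.segs = near
                    lineages.append(_Lineage(far, new_cls, lin.species))
                elif far:
                    # crossover in the gap between material and the selected
                    # site: the whole lineage jumps to a random background
                    lin.cls = new_cls
                # far empty cannot happen: x separates material from sel side
                break
            u -= rrate
        else:
            for key, crate in coal_rates:
                if u < crate:
                    members = groups[key]
                    i, j = rng.choice(len(members), size=2, replace=False)
                    a, b = members[i], members[j]
                    parent = merge([a, b], t)
                    lineages = [lin for lin in lineages if lin is not a and lin is not b]
                    if parent is not None:
                        lineages.append(parent)
                    maybe_close_stage2(t)
                    break
                u -= crate

    if stage2_end is None:
        stage2_end = t
    if origin is None:
        origin = t

    # -- assemble tskit tables --------------------------------------------
    tables = tskit.TableCollection(sequence_length=L)
    for name in ("sp1", "sp2", "anc"):
        tables.populations.add_row(metadata=f'{{"name": "{name}"}}'.encode())
    for i, (tt, fl) in enumerate(zip(node_time, node_flags)):
        pop = species_lab[i] if i < n_total else 2
        tables.nodes.add_row(flags=fl, time=tt, population=pop)
    for lo, hi, parent, child in edges:
        tables.edges.add_row(left=lo, right=hi, parent=parent, child=child)
    tables.sort()
    ts = tables.tree_sequence()

    if mutate and params.mu > 0:
        mseed = int(rng.integers(1, 2**31))
        ts = msprime.sim_mutations(
            ts,
            rate=params.mu,
            random_seed=mseed,
            model=msprime.BinaryMutationModel(),
            discrete_genome=False,
        )
    # inject the selected-site column: '1' marks the derived class A1
    tables = ts.dump_tables()
    tree = ts.at(sel)
    a1_tips = [i for i in range(n_total) if class_lab[i] == 0]
    mrca = a1_tips[0] if len(a1_tips) == 1 else tree.mrca(*a1_tips)
    site = tables.sites.add_row(position=sel, ancestral_state="0")
    tables.mutations.add_row(site=site, node=mrca, derived_state="1")
    tables.sort()
    ts = tables.tree_sequence()

    return SimulatedSample(
        params=params,
        sampling=sampling,
        seed=-1 if seed is None else int(seed),
        ts=ts,
        species=np.array(species_lab),
        classes=np.array(class_lab),
        selected_position=sel,
        stage2_end=stage2_end,
        origin=origin,
    )


# ---------------------------------------------------------------------------
# topology classification
# ---------------------------------------------------------------------------


def _is_monophyletic(tree: tskit.Tree, tips: np.ndarray) -> bool:
    if len(tips) == 1:
        return True
    mrca = tree.mrca(*tips)
    return tree.num_samples(mrca) == len(tips)


def classify_topology(
    tree: tskit.Tree,
    species: np.ndarray,
    classes: np.ndarray,
    split_time: float,
    Na: float,
    threshold: float | None = None,
) -> str:
    """Classify a marginal genealogy by how it clusters.

    * ``ancestral`` -- both allelic classes monophyletic (clusters by allele);
    * ``one-recombined`` -- exactly one species monophyletic (a class switch
      occurred in one species before the split); mixed states with neither
      grouping monophyletic are also reported here, as the intermediate class;
    * ``species-long`` / ``species-short`` -- both species monophyletic
      (clusters by species); split by whether the root is older or younger
      than ``threshold`` (default ``split_time + 4*Na``), mirroring whether
      the two deep lineages carried different or identical selected alleles.
    """
    species = np.asarray(species)
    classes = np.asarray(classes)
    if species.size != tree.tree_sequence.num_samples:
        raise ParameterError("species/class labels must cover every sample tip")
    tips_c = [np.flatnonzero(classes == c) for c in (0, 1)]
    if all(_is_monophyletic(tree, tc) for tc in tips_c):
        return "ancestral"
    tips_s = [np.flatnonzero(species == s) for s in (0, 1)]
    mono = [_is_monophyletic(tree, tsp) for tsp in tips_s]
    if sum(mono) != 2:
        return "one-recombined"
    if threshold is None:
        threshold = split_time + 4.0 * Na
    root_time = tree.time(tree.root)
    return "species-long" if root_time >= threshold else "species-short"


def ancestral_segment_extent(
    sample: SimulatedSample, sites: bool = False
) -> tuple[float, float] | tuple[int, int]:
    """Contiguous ancestral-topology extent around the selected site.

    Returns the (left, right) distances from the selected site to the first
    non-ancestral genealogy on each side, in continuous bp; with
    ``sites=True``, as counts of whole sites per side (a window with no
    recombination gives ``(selected_pos, L - selected_pos - 1)``).
    """
    spans = sample.topology_classes()
    sel = sample.selected_position
    for lo, hi, cls in spans:
        if lo <= sel < hi and cls != "ancestral":
            raise ParameterError("selected-site genealogy is not ancestral")
    non_anc_left = [h for l, h, c in spans if c != "ancestral" and h <= sel]
    non_anc_right = [l for l, h, c in spans if c != "ancestral" and l > sel]
    left = sel - max(non_anc_left) if non_anc_left else sel
    right = min(non_anc_right) - sel if non_anc_right else sample.ts.sequence_length - sel
    if sites:
        return int(left), int(right)
    return float(left), float(right)
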