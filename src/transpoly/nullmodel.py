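"""Neutral two-species null model with recurrent (finite-sites) mutation.

Shared SNPs between well-diverged species can be identical by state rather
than by descent: the same site is hit independently in both species, mostly
at hypermutable CpG-like positions.  This module simulates the neutral
two-species coalescent with recombination (no selected site), drops
finite-sites mutations so identical-by-state shared SNPs arise, and tallies
how often pairs of shared SNPs fall close together and how strong and
phase-consistent their LD is -- the false-positive background for a
trans-species polymorphism scan.

The coalescent with recombination and the mutation process are delegated to
``msprime``; sites mutate under a biallelic flip-flop model (a recurrent hit
toggles between the same two alleles), so "same segregating alleles in both
species" reduces to "polymorphic in both species".

Because shared-SNP pairs are rare at realistic rates, the pair collector
re-simulates mutations repeatedly on cached genealogies (the r^2 and
coupling of a shared pair depend only on which branches carry the hits, not
on the per-site rate), which concentrates effort on the conditional
distribution of interest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import msprime
import numpy as np

from .ld import HaplotypeTable, coupling_phase, ld_significance, pairwise_ld
from .params import DemographyParams, ParameterError

__all__ = [
    "MutationModel",
    "NullSummary",
    "SharedPair",
    "simulate_neutral_pair",
    "tally_shared_pairs",
    "collect_shared_pairs",
]


@dataclass(frozen=True)
class MutationModel:
    """Finite-sites mutation with a hypermutable (CpG-like) site class.

    ``rate`` is the baseline per-site per-generation rate; a fraction
    ``hot_fraction`` of sites mutates at ``rate * hot_multiplier``.
    """

    rate: float = 1.2e-8
    hot_multiplier: float = 10.0
    hot_fraction: float = 0.02

    def __post_init__(self) -> None:
        if self.rate < 0 or self.hot_multiplier < 0:
            raise ParameterError("mutation rates must be non-negative")
        if not 0 <= self.hot_fraction <= 1:
            raise ParameterError("hot_fraction must lie in [0, 1]")


@dataclass
class SharedPair:
    """One pair of shared SNPs: positions and per-species LD summaries."""

    pos1: float
    pos2: float
    r2_sp1: float
    r2_sp2: float
    significant_both: bool
    phase: str  # same | opposite | indeterminate


@dataclass
class NullSummary:
    """Aggregate of :func:`tally_shared_pairs`."""

    replicates: int
    segments_with_pair: int
    n_pairs: int
    n_significant_coupled: int
    r2_values: np.ndarray = field(default_factory=lambda: np.empty(0))
    pair_counts: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    @property
    def fraction_segments_with_pair(self) -> float:
        return self.segments_with_pair / self.replicates if self.replicates else 0.0

    @property
    def fraction_significant_coupled(self) -> float:
        return self.n_significant_coupled / self.n_pairs if self.n_pairs else 0.0

    @property
    def mean_r2(self) -> float:
        return float(self.r2_values.mean()) if self.r2_values.size else float("nan")


def _demography(dem: DemographyParams) -> msprime.Demography:
    # samples are haploid chromosomes (ploidy=1), so the diploid sizes of the
    # package convention (pairwise rate 1/(2N)) enter msprime doubled
    d = msprime.Demography()
    d.add_population(name="sp1", initial_size=2 * dem.Ne)
    d.add_population(name="sp2", initial_size=2 * dem.Ne)
    d.add_population(name="anc", initial_size=2 * dem.Na)
    for start, end, size in dem.bottlenecks:
        for pop in ("sp1", "sp2"):
            d.add_population_parameters_change(
                time=start, population=pop, initial_size=2 * size
            )
            d.add_population_parameters_change(
                time=end, population=pop, initial_size=2 * dem.Ne
            )
    d.add_population_split(time=dem.T, derived=["sp1", "sp2"], ancestral="anc")
    d.sort_events()
    return d


def simulate_neutral_pair(
    region_bp: int,
    demography: DemographyParams,
    n: int,
    mut: MutationModel,
    r: float = 1.2e-8,
    seed: int | None = None,
    mutation_draws: int = 1,
):
    """Yield ``(positions, genotypes_sp1, genotypes_sp2)`` for each mutation
    draw on one simulated two-species genealogy.

    ``n`` chromosomes are sampled per species.  Hypermutable sites are
    implemented through an ``msprime`` rate map: a ``hot_fraction`` of
    evenly spaced unit intervals carries ``rate * hot_multiplier``.
    Positions are discrete (finite sites); genotypes are 0/1 under the
    flip-flop model.
    """
    if region_bp < 1:
        raise ParameterError("region_bp must be at least 1 bp")
    rng = np.random.default_rng(seed)
    ts = msprime.sim_ancestry(
        samples={"sp1": n, "sp2": n},
        demography=_demography(demography),
        ploidy=1,
        sequence_length=region_bp,
        recombination_rate=r,
        random_seed=int(rng.integers(1, 2**31)),
    )
    if mut.hot_fraction > 0 and mut.hot_multiplier != 1.0:
        # one hypermutable site at the end of every (1/hot_fraction)-bp block
        stride = max(2, int(round(1.0 / mut.hot_fraction)))
        block_starts = np.arange(0, region_bp, stride, dtype=float)
        hot_starts = np.minimum(block_starts + stride - 1, region_bp - 1)
        edges_pos = np.unique(
            np.concatenate([block_starts, hot_starts, hot_starts + 1, [region_bp]])
        )
        edges_pos = edges_pos[edges_pos <= region_bp]
        hot_set = set(hot_starts)
        rates = [
            mut.rate * (mut.hot_multiplier if lo in hot_set else 1.0)
            for lo in edges_pos[:-1]
        ]
        rate_map = msprime.RateMap(position=edges_pos, rate=rates)
    else:
        rate_map = mut.rate
    for _ in range(mutation_draws):
        mts = msprime.sim_mutations(
            ts,
            rate=rate_map,
            model=msprime.BinaryMutationModel(),
            random_seed=int(rng.integers(1, 2**31)),
            discrete_genome=True,
        )
        if mts.num_sites == 0:
            yield np.empty(0), np.empty((0, n), dtype=np.int8), np.empty(
                (0, n), dtype=np.int8
            )
            continue
        G = mts.genotype_matrix()
        pos_arr = mts.sites_position
        yield pos_arr, G[:, :n], G[:, n:]


def _shared_indices(G1: np.ndarray, G2: np.ndarray) -> np.ndarray:
    if G1.shape[0] == 0:
        return np.empty(0, dtype=int)
    f1 = G1.mean(axis=1)
    f2 = G2.mean(axis=1)
    return np.flatnonzero((f1 > 0) & (f1 < 1) & (f2 > 0) & (f2 < 1))


def _pairs_from_draw(
    pos: np.ndarray,
    G1: np.ndarray,
    G2: np.ndarray,
    window_bp: float,
    alpha: float,
) -> list[SharedPair]:
    out = []
    idx = _shared_indices(G1, G2)
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            i, j = idx[a], idx[b]
            if pos[j] - pos[i] > window_bp:
                break
            t1 = HaplotypeTable.from_haplotypes(G1[i], G1[j])
            t2 = HaplotypeTable.from_haplotypes(G2[i], G2[j])
            _, _, sig1 = ld_significance(t1, alpha)
            _, _, sig2 = ld_significance(t2, alpha)
            phase = coupling_phase(t1, t2)
            out.append(
                SharedPair(
                    pos1=float(pos[i]),
                    pos2=float(pos[j]),
                    r2_sp1=pairwise_ld(t1).r2,
                    r2_sp2=pairwise_ld(t2).r2,
                    significant_both=bool(sig1 and sig2),
                    phase=phase,
                )
            )
    return out


def tally_shared_pairs(
    replicates: int,
    region_bp: int,
    demography: DemographyParams,
    n: int = 50,
    mut: MutationModel | None = None,
    r: float = 1.2e-8,
    window_bp: float = 400.0,
    alpha: float = 0.05,
    seed: int | None = None,
    mutation_draws: int = 1,
) -> NullSummary:
    """Simulate ``replicates`` independent segments and aggregate shared-SNP
    pair statistics within ``window_bp``.

    A *shared SNP* is a site polymorphic in both species (identical allele
    pair under the flip-flop model); a pair is *significantly coupled* when
    the chi-square LD test rejects in both species and the coupling phase is
    the same.  ``mutation_draws > 1`` re-simulates mutations on each cached
    genealogy (each draw counts as one segment).
    """
    mut = mut or MutationModel()
    rng = np.random.default_rng(seed)
    pairs: list[SharedPair] = []
    pair_counts = []
    segments = 0
    segments_with = 0
    for _ in range(replicates):
        for pos, G1, G2 in simulate_neutral_pair(
            region_bp,
            demography,
            n,
            mut,
            r,
            seed=int(rng.integers(1, 2**31)),
            mutation_draws=mutation_draws,
        ):
            found = _pairs_from_draw(pos, G1, G2, window_bp, alpha)
            segments += 1
            pair_counts.append(len(found))
            if found:
                segments_with += 1
                pairs.extend(found)
    r2_vals = np.array([v for sp in pairs for v in (sp.r2_sp1, sp.r2_sp2)])
    n_sig_coupled = sum(1 for sp in pairs if sp.significant_both and sp.phase == "same")
    return NullSummary(
        replicates=segments,
        segments_with_pair=segments_with,
        n_pairs=len(pairs),
        n_significant_coupled=n_sig_coupled,
        r2_values=r2_vals,
        pair_counts=np.array(pair_counts, dtype=int),
    )


def collect_shared_pairs(
    min_pairs: int,
    demography: DemographyParams,
    n: int = 50,
    region_bp: int = 3000,
    r: float = 1.2e-8,
    window_bp: float = 400.0,
    alpha: float = 0.05,
    seed: int | None = None,
    rate_multiplier: float = 50.0,
    mutation_draws: int = 8,
    max_ancestries: int = 20_000,
) -> NullSummary:
    """Collect at least ``min_pairs`` shared-SNP pairs by conditioned
    resampling: mutations are re-drawn repeatedly on cached genealogies at an
    elevated per-site rate.

    The elevated rate plays the role of the hypermutable-site class: it
    raises the chance that a site is hit in both species without changing
    which branch configurations produce a shared pair, so the conditional
    r^2 / coupling distribution is preserved while rare events become
    affordable.
    """
    mut = MutationModel(rate=1.2e-8 * rate_multiplier, hot_multiplier=1.0, hot_fraction=0.0)
    rng = np.random.default_rng(seed)
    pairs: list[SharedPair] = []
    segments = 0
    segments_with = 0
    for _ in range(max_ancestries):
        if len(pairs) >= min_pairs:
            break
        for pos, G1, G2 in simulate_neutral_pair(
            region_bp,
            demography,
            n,
            mut,
            r,
            seed=int(rng.integers(1, 2**31)),
            mutation_draws=mutation_draws,
        ):
            found = _pairs_from_draw(pos, G1, G2, window_bp, alpha)
            segments += 1
            if found:
                segments_with += 1
                pairs.extend(found)
    r2_vals = np.array([v for sp in pairs for v in (sp.r2_sp1, sp.r2_sp2)])
    n_sig_coupled = sum(1 for sp in pairs if sp.significant_both and sp.phase == "same")
    return NullSummary(
        replicates=segments,
        segments_with_pair=segments_with,
        n_pairs=len(pairs),
        n_significant_coupled=n_sig_coupled,
        r2_values=r2_vals,
        pair_counts=np.empty(0, dtype=int),
    )
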