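# Methods

## Model and conventions

Two panmictic species of constant diploid size `Ne` split `T` generations
ago (no subsequent gene flow) from an ancestor of diploid size `Na`.  A
biallelic polymorphism (derived allele A1 at equilibrium frequency `p`,
ancestral A2 at `q = 1 - p`) is maintained by balancing selection with no
mutation at the selected site, so all copies of an allele are identical by
descent.  Backward in time the genealogy of a conditioned sample passes
through three stages: (I) within-species coalescence down to one lineage per
allelic class per species, (II) four lineages down to two class ancestors in
the ancestral species, (III) the final coalescence of the two class
ancestors.  The polymorphism's age `Ts` is measured backward from the end of
stage II.

Conventions used everywhere: time in generations (years convert at a
user-supplied generation time, default 20 y, appropriate for apes); diploid
population sizes (pairwise coalescence rate `1/(2N)`); `p` is the frequency
of the *derived* allele — the class whose lineages are forced to coalesce at
the polymorphism's origin; genetic distances `d = r × bp` in Morgans.
Following the structured-coalescent treatment of balanced polymorphisms,
allelic classes act as demes of sizes `pN` and `qN`, and the "migration"
event is class-switching recombination: an A1 lineage switches at rate
`d·q`, an A2 lineage at `d·p` (a crossover lands the site on a background
drawn from the class frequencies).

## Segment length (`segment_length`)

The one-sided length `X` of the ancestral segment is the distance to the
nearest class-switching crossover accumulated by the four stage-II lineages
over `T + t` generations, `t = max(t1, t2)` being the extra ancestral
coalescence time of the two classes (`t1 ~ Exp(1/(2Na p))`,
`t2 ~ Exp(1/(2Na q))`).  Summing the four per-Morgan switching hazards gives
total rate `2(p + q) = 2` per generation — independent of `p`, which is why
the distribution is insensitive to the equilibrium frequency.  Marginalizing
`X | t ~ Exp(2(T+t))` over the exact density of the maximum of two
exponentials yields the closed three-term survival function implemented in
`LengthDistribution`; density, mean and quantiles follow analytically
(quantiles by bracketed root-finding at relative tolerance 1e-12; the mean
by quadrature of the survival function with absolute tolerance 1e-14).  A
quadrature marginalization over the stage-II time density provides an
independent cross-check in the tests.

**Known approximation.**  All four lineages are treated as exposed until the
*later* class coalescence.  In the window between the two class
coalescences only three lineages exist (and a switch of an already-coalesced
class MRCA only sometimes disturbs the topology), so the law slightly
understates the true segment length — by construction, not by accident; the
effect scales with `Na/T`.  At `Na/T = 0.2` (human–chimpanzee) the exact
process, measured from the conditional simulator, runs ~5–7% longer in the
mean.  A Kolmogorov–Smirnov comparison with enough replicates (10^4)
resolves this difference; the test suite therefore carries one test that
documents the deviation (the strict KS check) alongside one that verifies
the simulator sits inside the expected envelope (analytic mean ≤ simulated
mean ≤ 1.12 × analytic).  Users fitting real data should treat the analytic
law as a slight lower bound on segment lengths.

The two-sided length is the self-convolution of the one-sided law, computed
by FFT on a uniform grid (default resolution 0.05 bp-equivalent; a coarser
grid than ~100 points raises a configuration error).  The two-sided mean is
reported exactly as twice the one-sided mean (independence of the two
sides); the grid mean agrees to ~1e-4 relative and serves as a grid-quality
check.

## Coalescent times and shared SNPs (`coalescent_times`)

For an infinitely old polymorphism, first-step analysis of the two-deme
island model gives linear equations for `T1`, `T2`, `TB` (solved exactly;
`d = 0` returns the isolated-deme limit with `TB` infinite, signalled rather
than raised).  For finite age, a discrete per-generation chain over
`(n1, n2)` states is built exactly as a stochastic matrix (each lineage
first recombines, then co-located pairs coalesce); the expected absorption
time accumulates survival probabilities through `Ts` selection-phase steps,
applies the phase-boundary rule — a derived-background pair is forced into
the coalesced state, because every A1 chromosome descends from the single
founder — and closes the neutral tail analytically (`2Na` expected further
generations).  Two evaluation routes (step-by-step survival summation and
the fundamental matrix of the transient block, with `P^Ts` by
exponentiation-by-squaring) agree to 1e-8 and the fast route is O(log Ts).
The closed-form-style approximation zeroes the transitions that return to
earlier states (upper-triangular selection matrix); it can only
underestimate the numeric value, since excursions back to `(1,1)` — where
coalescence is impossible — only delay absorption.

The expected shared-SNP count is `1 + Σ_sites w(d_i) · 2μ · E[TB(d_i)]`,
where `w` is either the one-sided survival function (marginal mode, the
default) or an indicator for a fixed segment (fixed mode) — both are exposed
because the marginalization choice is a genuine modelling option.  Ages
measured from the present convert to `Ts` by subtracting `T`, the expected
stage-II extra time `E[max(t1,t2)]`, and a stage-I allowance (default
`4Ne`); the split is configurable.  With genome-average human rates
(`μ = r = 1.2e-8`) and an age of 20 Myr the default computation gives ≈ 3–4
SNPs in total (the selected one plus 2–3 neutral); the exact value depends
on the marginalization mode and the mutation rate chosen, both of which are
order-of-magnitude inputs here.

## LD (`ld`)

`D`, `D'` and `r²` are computed from phased 2×2 haplotype counts; the LD
significance test is the 1-df χ² statistic `n·r²` without continuity
correction (phased data, so no EM step).  Monomorphic loci yield an
"undefined" result object rather than an exception.  Coupling phase
compares `sign(D)` across species under a label-stable allele ordering
(lexicographic by nucleotide).  The stage-I retention probability `R_n` is
approximated by `exp(-d·q·E[T_mrca])` with `E[T_mrca] = 4·Ne·p·(1-1/n)`; by
Jensen's inequality this understates retention (hence the LD it implies), so
it is a conservative bound, and a Monte-Carlo estimator of
`E[exp(-d·q·T_mrca)]` over the random class coalescent is shipped as the
reference implementation.

## Conditional simulator (`simulator`)

The simulator is an exact multi-locus structured coalescent (no
sequentially-Markov approximation): lineages carry interval lists of
ancestral material over a window of `L` discrete sites in continuous
coordinates, crossovers fall uniformly on the span between a lineage's
material and the selected site, and the piece on the far side of the
crossover re-draws its allelic background from the class frequencies.
Within-class coalescence follows Kingman rates per (species × class) group;
at `T` the species merge; at the polymorphism's origin *all*
derived-background lineages merge into the founder chromosome (a single
multifurcating node); afterwards a single neutral class of size `Na`
remains.  In `Ts` mode the origin is placed `Ts` generations after the
observed end of stage II at the selected site (plus a 1e-6-generation guard
so the forced node is strictly older than its children); an absolute-age
mode is also available.  Nodes and edges are recorded Hudson-style
(intervals that reach full sample coverage stop being tracked) and exported
as a tskit tree sequence, so marginal trees, Newick output, genotype
matrices and infinite-sites mutation dropping (msprime, binary alleles,
continuous positions) use the standard tools; the selected-site column is
injected as a mutation above the derived-class MRCA, which is monophyletic
at the selected site by construction.

Topology classes per marginal tree: *ancestral* (both allelic classes
monophyletic), *one-recombined* (exactly one species monophyletic — the
intermediate state; rare fully-mixed trees in larger samples are also
reported here), and *species-long* / *species-short* (both species
monophyletic, split at a root-age threshold, default `T + 4Na`, mirroring
whether the two deep lineages carried different or identical alleles — a
reporting convention, not a model quantity).  The ancestral-segment extent
is the contiguous run of ancestral-topology intervals around the selected
site.

The overdominance mode simulates a discrete Wright–Fisher trajectory with
viabilities `1-s1 : 1 : 1-s2` where `s1 = s/(2p*)`, `s2 = s/(2q*)` — the
unique symmetric-load parameterization with harmonic-mean coefficient `s`
and equilibrium `p*` — conditioned on segregation by rejection (batched and
vectorized; the failure rate is reported if the budget is exhausted).  A
supplied trajectory enters the coalescent as piecewise-constant class
frequencies over 100-generation chunks; with `2·Ne·s ≥ 100` the frequency
is pinned near the equilibrium and chunking error is negligible, which is
exactly the regime where the constant-frequency theory is claimed (and
tested) to hold.

## Neutral null model (`nullmodel`)

The neutral two-species coalescent with recombination is delegated to
msprime (haploid samples; the package's diploid sizes enter doubled to
preserve the `1/(2N)` convention), with finite-sites binary flip-flop
mutations so identical-by-state shared SNPs arise; hypermutable CpG-like
sites are one position per `1/hot_fraction`-bp block (defaults: 2% of
sites, 10× rate — round numbers of the right order for ape CpG contexts;
exact empirical values vary by dataset and are configurable).
`tally_shared_pairs` measures the unconditional rarity of close shared-SNP
pairs; `collect_shared_pairs` estimates their conditional r²/coupling
distribution by re-drawing mutations on cached genealogies at an elevated
rate — valid because which *branch configurations* yield a shared pair, not
the per-site rate, determines those statistics; the elevated rate only
tilts the sample toward configurations with more than the minimal two hits,
and the estimate is verified (in the tests) against a branch-sampling oracle
that places exactly one mutation per species subtree.  Both routes agree
that with 50 chromosomes per species the mean r² among shared pairs is
≈ 0.2 at human-chimp-like parameters (median ≈ 0.02: the distribution is
L-shaped, with most pairs in negligible LD and a minority of same-branch
coincidences at r² = 1).

## Scanner (`scan`)

Shared SNPs require literal allele-pair identity at the same position
(0-based internally; VCF converts at the boundary); mismatched pairs are
excluded and counted, surfacing strand inconsistencies.  Clusters are
single-linkage at the window size (default 400 bp, the ancestral-segment
scale); a cluster's span is the distance between its outermost SNPs that are
in significant LD (χ², per-test α, no multiple-testing correction — the
scan reports raw p-values and leaves genome-wide FDR control to the user)
with another member in both species.  CpG flags come from the trinucleotide
reference context (CG dinucleotide on either strand; unknown context gives
"unknown", never "false").  No allele-frequency filters are applied by
default.

## Problem sizes in tests and the acceptance script

Analytic checks are exact or near-instant.  Stochastic cross-checks use
sizes chosen for stable 2-SE comparisons at interactive runtimes: 10^4
replicates for the simulator-vs-length-law KS check, 3–10 × 10^3 replicates
for coalescent-time oracles, ~10^3 segments for the recurrent-mutation
rarity checks, and ≥ 2000 collected pairs for the null r² estimate; the
overdominance comparison runs at reduced population sizes (Ne = 500) where
trajectories and coalescence are fast but `2·Ne·s = 200` preserves the
strong-selection regime.

## What the synthetic data do and do not show

The fixture generator and simulators emulate idealized data: constant
population sizes, uniform rates, perfect phasing, no genotyping error, no
gene conversion, crossover-only recombination, a single biallelic selected
site, and alignment-consistent coordinates between species.  Passing tests
therefore demonstrate internal consistency of theory, simulation and
scanning on this idealized model — not robustness to hotspot turnover, gene
conversion (which erodes the footprint and can create fixed differences
inside the segment), allelic turnover at the selected site, multiallelic
balancing selection, population structure, or cross-species alignment
error.  Detection of balanced polymorphisms that were *lost* in one species
is out of scope by design.
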