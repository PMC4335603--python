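"""Conditional structured-coalescent simulator: determinism, topology
structure, cross-checks against the analytic length law and coalescent-time
chain, and the fluctuating-frequency overdominance mode."""

import numpy as np
import pytest
import tskit

from transpoly.coalescent_times import expected_TB_numeric
from transpoly.params import ParameterError, SamplingParams, model_params
from transpoly.segment_length import one_sided_distribution
from transpoly.simulator import (
    ancestral_segment_extent,
    classify_topology,
    simulate_overdominance_trajectories,
    simulate_overdominance_trajectory,
    simulate_sample,
)

APE = dict(Ne=10_000, Na=50_000, T=160_000, p=0.5, r=1.25e-8, Ts=600_000)


def ape_params(mu=0.0, L=10_000):
    return model_params(mu=mu, L=L, selected_pos=L // 2, **APE)


FOUR = SamplingParams(n=2, class_counts=(1, 1))


class TestBasics:
    def test_deterministic_given_seed(self):
        a = simulate_sample(ape_params(mu=1.2e-8), FOUR, seed=42)
        b = simulate_sample(ape_params(mu=1.2e-8), FOUR, seed=42)
        assert np.array_equal(a.haplotypes, b.haplotypes)
        assert np.array_equal(a.positions, b.positions)
        assert a.ts.tables.edges == b.ts.tables.edges

    def test_without_mutation_only_selected_column(self):
        s = simulate_sample(ape_params(mu=0.0), FOUR, seed=1)
        assert s.ts.num_sites == 1
        assert s.positions[0] == s.selected_position
        # the selected column separates the two classes
        col = s.haplotypes[0]
        assert np.array_equal(col == 1, s.classes == 0)

    def test_selected_site_topology_is_ancestral(self):
        for seed in range(5):
            s = simulate_sample(ape_params(), FOUR, seed=seed)
            tree = s.ts.at(s.selected_position)
            cls = classify_topology(tree, s.species, s.classes, s.params.T, s.params.Na)
            assert cls == "ancestral"

    def test_requires_both_classes(self):
        with pytest.raises(ParameterError):
            simulate_sample(ape_params(), SamplingParams(n=1, class_counts=(1, 0)))

    def test_breakpoints_strictly_increasing(self):
        s = simulate_sample(ape_params(), FOUR, seed=7)
        bp = s.breakpoints()
        assert np.all(np.diff(bp) > 0)

    def test_node_times_ordered_rootward(self):
        s = simulate_sample(ape_params(), FOUR, seed=8)
        for tree in s.ts.trees():
            for u in tree.nodes():
                parent = tree.parent(u)
                if parent != tskit.NULL:
                    assert tree.time(parent) > tree.time(u)


class TestTopologyStructure:
    def test_ancestral_segment_flanked_by_one_recombined(self):
        """Along the sequence the ancestral segment is always flanked by the
        intermediate (one-species-recombined) topology before any
        species-clustered segment appears."""
        checked = 0
        for seed in range(40):
            s = simulate_sample(ape_params(), FOUR, seed=seed)
            spans = s.topology_classes()
            labels = [c for _, _, c in spans]
            sel_idx = next(
                i for i, (lo, hi, _) in enumerate(spans)
                if lo <= s.selected_position < hi
            )
            # walk out from the selected tree: first non-ancestral must be
            # one-recombined on each side (when any non-ancestral exists)
            for direction in (-1, 1):
                i = sel_idx
                while 0 <= i < len(labels) and labels[i] == "ancestral":
                    i += direction
                if 0 <= i < len(labels):
                    assert labels[i] == "one-recombined"
                    checked += 1
        assert checked > 10  # the window is wide enough that most runs recombine

    def test_classify_constructed_fixtures(self):
        # four tips ((s1A1, s2A1), (s1A2, s2A2)): clusters by allele
        tables = tskit.TableCollection(sequence_length=1.0)
        for _ in range(4):
            tables.nodes.add_row(flags=tskit.NODE_IS_SAMPLE, time=0.0)
        n01 = tables.nodes.add_row(time=1.0)
        n23 = tables.nodes.add_row(time=2.0)
        root = tables.nodes.add_row(time=3.0)
        for child, parent in ((0, n01), (1, n01), (2, n23), (3, n23), (n01, root), (n23, root)):
            tables.edges.add_row(left=0, right=1, parent=parent, child=child)
        tables.sort()
        tree = tables.tree_sequence().first()
        species = np.array([0, 1, 0, 1])
        classes = np.array([0, 0, 1, 1])
        assert classify_topology(tree, species, classes, 1.0, 1.0) == "ancestral"
        # same tree read as species clusters with a deep root: long branch class
        species2 = np.array([0, 0, 1, 1])
        classes2 = np.array([0, 1, 0, 1])
        assert (
            classify_topology(tree, species2, classes2, split_time=1.0, Na=0.1)
            == "species-long"
        )
        assert (
            classify_topology(tree, species2, classes2, split_time=1.0, Na=10.0)
            == "species-short"
        )
        # one species monophyletic only
        species3 = np.array([0, 0, 1, 1])
        classes3 = np.array([0, 1, 1, 0])
        tables2 = tskit.TableCollection(sequence_length=1.0)
        for _ in range(4):
            tables2.nodes.add_row(flags=tskit.NODE_IS_SAMPLE, time=0.0)
        a = tables2.nodes.add_row(time=1.0)  # joins 0,1 (species 0)
        b = tables2.nodes.add_row(time=2.0)  # joins a with 2
        r = tables2.nodes.add_row(time=3.0)
        for child, parent in ((0, a), (1, a), (a, b), (2, b), (b, r), (3, r)):
            tables2.edges.add_row(left=0, right=1, parent=parent, child=child)
        tables2.sort()
        tree2 = tables2.tree_sequence().first()
        assert classify_topology(tree2, species3, classes3, 1.0, 1.0) == "one-recombined"


class TestExtent:
    def test_window_without_recombination(self):
        params = model_params(mu=0.0, L=100, selected_pos=30, **APE)
        # 100 bp window: switching within it is very unlikely
        for seed in range(50):
            s = simulate_sample(params, FOUR, seed=seed)
            if s.ts.num_trees == 1:
                assert ancestral_segment_extent(s, sites=True) == (30, 69)
                return
        raise AssertionError("no recombination-free replicate in 50 tries")

    def test_mean_extent_brackets_analytic_law(self):
        """The analytic law slightly understates the true segment length
        (its hazard convention counts all four lineages to the later class
        coalescence); the simulated mean must sit at or above the analytic
        mean but within the ~12% envelope that convention implies."""
        dist = one_sided_distribution(ape_params())
        rng = np.random.default_rng(77)
        xs = []
        for _ in range(400):
            s = simulate_sample(
                ape_params(), FOUR, seed=int(rng.integers(1, 2**31)), mutate=False
            )
            xs.extend(ancestral_segment_extent(s))
        mean = np.mean(xs)
        se = np.std(xs) / np.sqrt(len(xs))
        assert dist.mean_bp - 2 * se <= mean <= 1.12 * dist.mean_bp + 2 * se

    def test_extent_insensitive_to_sample_size(self):
        """Larger samples lengthen the segment only negligibly (stage I is
        much shorter than stage II)."""
        rng = np.random.default_rng(5)
        means = []
        for n in (2, 8):
            xs = []
            for _ in range(150):
                s = simulate_sample(
                    ape_params(),
                    SamplingParams(n=n, class_counts=(n // 2, n // 2)),
                    seed=int(rng.integers(1, 2**31)),
                    mutate=False,
                )
                xs.extend(ancestral_segment_extent(s))
            means.append(np.mean(xs))
        assert abs(means[1] - means[0]) / means[0] < 0.15


class TestCoalescentCrossCheck:
    def test_two_lineage_tmrca_matches_chain(self):
        """Two lineages, one per class, at distance d: the simulated mean
        coalescence time at the neutral site matches the chain expectation."""
        d = 5e-6
        Na, p, Ts = 50_000, 0.5, 200_000
        params = model_params(
            Ne=10_000, Na=Na, T=1e-3, p=p, Ts=Ts, r=d, mu=0.0, L=2, selected_pos=0
        )
        expected = expected_TB_numeric(d, Na, p, Ts)
        rng = np.random.default_rng(11)
        times = []
        for _ in range(3000):
            s = simulate_sample(
                params,
                seed=int(rng.integers(1, 2**31)),
                sample_config=[(0, 0, 1), (0, 1, 1)],
                mutate=False,
            )
            tree = s.ts.at(1.5)
            times.append(tree.tmrca(0, 1))
        mean = np.mean(times)
        se = np.std(times) / np.sqrt(len(times))
        assert abs(mean - expected) < 2 * se


class TestSharedSNPs:
    @staticmethod
    def shared_neutral(s):
        G = s.haplotypes
        sel_col = s.selected_column
        sp1 = s.species == 0
        sp2 = s.species == 1
        out = []
        for k in range(G.shape[0]):
            if k == sel_col:
                continue
            f1, f2 = G[k, sp1].mean(), G[k, sp2].mean()
            if 0 < f1 < 1 and 0 < f2 < 1:
                out.append(k)
        return out

    def test_four_sample_shared_snps_in_perfect_ld(self):
        """With one chromosome per class per species, every shared neutral
        SNP inside the ancestral segment is in perfect LD with the selected
        site in both species."""
        params = model_params(mu=5e-8, L=2000, selected_pos=1000, **APE)
        rng = np.random.default_rng(13)
        n_checked = 0
        for _ in range(200):
            s = simulate_sample(params, FOUR, seed=int(rng.integers(1, 2**31)))
            left, right = ancestral_segment_extent(s)
            G = s.haplotypes
            sel_col = s.selected_column
            for k in self.shared_neutral(s):
                pos = s.positions[k]
                if -left < pos - s.selected_position < right:
                    for sp in (0, 1):
                        mask = s.species == sp
                        x, y = G[sel_col, mask], G[k, mask]
                        r2 = np.corrcoef(x, y)[0, 1] ** 2
                        assert r2 == pytest.approx(1.0)
                    n_checked += 1
        assert n_checked >= 20

    def test_mean_shared_count_matches_expectation(self):
        """Per-replicate shared neutral SNP counts average to the analytic
        expectation (selected site excluded on both sides)."""
        from transpoly.coalescent_times import expected_shared_snps

        params = model_params(mu=1.2e-8, L=2001, selected_pos=1000, **APE)
        expected = expected_shared_snps(params) - 1.0
        rng = np.random.default_rng(17)
        counts = []
        for _ in range(600):
            s = simulate_sample(params, FOUR, seed=int(rng.integers(1, 2**31)))
            counts.append(len(self.shared_neutral(s)))
        mean = np.mean(counts)
        se = np.std(counts) / np.sqrt(len(counts))
        assert abs(mean - expected) < max(2 * se, 0.15 * expected)


class TestOverdominance:
    def test_strong_selection_pins_frequency(self):
        traj = simulate_overdominance_trajectory(0.1, 2_000, 10_000, seed=3)
        assert traj.freqs.std() < np.sqrt(0.25 / (2 * 2_000) * 100)  # << drift scale
        assert abs(traj.freqs.mean() - 0.5) < 0.05

    def test_neutral_conditioned_path_is_valid(self):
        traj = simulate_overdominance_trajectory(0.0, 500, 2_000, seed=4)
        assert traj.freqs.size == 2_000
        assert np.all((traj.freqs > 0) & (traj.freqs < 1))

    def test_asymmetric_equilibrium_parameterization(self):
        traj = simulate_overdominance_trajectory(
            0.2, 5_000, 5_000, seed=5, equilibrium_p=0.3
        )
        assert abs(traj.freqs.mean() - 0.3) < 0.05

    def test_fluctuating_frequencies_leave_summaries_unchanged(self):
        """With 2*Ne*s >= 100 the summaries are statistically
        indistinguishable from the constant-frequency model."""
        scale = dict(Ne=500, Na=4_000, T=10_000, p=0.5, r=2e-7, Ts=12_000)
        params = model_params(mu=0.0, L=2_000, selected_pos=1_000, **scale)
        span = 26_000
        rng = np.random.default_rng(23)
        trajs = simulate_overdominance_trajectories(0.2, scale["Ne"], span, 100, seed=99)
        means = {}
        for mode in ("constant", "fluctuating"):
            xs = []
            for rep in range(100):
                traj = trajs[rep] if mode == "fluctuating" else None
                s = simulate_sample(
                    params,
                    FOUR,
                    seed=int(rng.integers(1, 2**31)),
                    trajectory=traj,
                    mutate=False,
                )
                xs.extend(ancestral_segment_extent(s))
            means[mode] = (np.mean(xs), np.std(xs) / np.sqrt(len(xs)))
        diff = abs(means["constant"][0] - means["fluctuating"][0])
        se = np.hypot(means["constant"][1], means["fluctuating"][1])
        assert diff < max(3 * se, 0.15 * means["constant"][0])
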