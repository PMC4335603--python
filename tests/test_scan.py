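"""Two-species scanner: shared-SNP detection, clustering, spans, phases,
CpG flags, and round trips through the fixture generator and the simulator."""

import json

import numpy as np
import pytest

from transpoly.fixtures import generate_fixtures
from transpoly.formats import write_vcf
from transpoly.params import ParameterError, SamplingParams, model_params
from transpoly.scan import (
    Variant,
    cluster_and_report,
    cpg_flag,
    find_shared_snps,
    read_vcf_haplotypes,
)
from transpoly.simulator import simulate_sample


def _variant(pos, ref, alt, hap):
    return Variant(pos=pos, ref=ref, alt=alt, haplotypes=np.asarray(hap))


class TestFindShared:
    def test_disjoint_positions_give_empty_list(self):
        v1 = [_variant(10, "A", "G", [0, 1, 0, 1])]
        v2 = [_variant(20, "A", "G", [0, 1, 0, 1])]
        shared, mism = find_shared_snps(v1, v2)
        assert shared == [] and mism == 0

    def test_allele_mismatches_are_excluded_and_counted(self):
        h = [0, 1, 0, 1]
        v1 = [_variant(10, "A", "G", h), _variant(20, "A", "C", h), _variant(30, "T", "C", h)]
        v2 = [_variant(10, "A", "G", h), _variant(20, "A", "T", h), _variant(30, "C", "T", h)]
        shared, mism = find_shared_snps(v1, v2)
        # position 30: same {C,T} pair with ref/alt swapped still matches
        assert [s.pos for s in shared] == [10, 30]
        assert mism == 1

    def test_canonical_allele_coding_is_label_stable(self):
        # ref/alt swapped between species: columns recoded to the same labels
        v1 = [_variant(10, "A", "G", [0, 0, 1, 1])]
        v2 = [_variant(10, "G", "A", [1, 1, 0, 0])]
        shared, _ = find_shared_snps(v1, v2)
        assert np.array_equal(shared[0].hap_sp1, shared[0].hap_sp2)

    def test_unsorted_input_rejected(self):
        v = [_variant(20, "A", "G", [0, 1]), _variant(10, "A", "G", [0, 1])]
        with pytest.raises(ParameterError):
            find_shared_snps(v, v)

    def test_toy_fixture_truth_table(self, tmp_path):
        paths = generate_fixtures("toy-vcf-pair", 7, tmp_path)
        v1 = read_vcf_haplotypes(str(paths[0]))
        v2 = read_vcf_haplotypes(str(paths[1]))
        ref = "".join(
            l.strip() for l in open(paths[2]) if not l.startswith(">")
        )
        truth = json.loads(paths[3].read_text())
        shared, mism = find_shared_snps(v1, v2, reference=ref)
        assert [s.pos for s in shared] == truth["shared"]
        assert mism == len(truth["mismatch"])
        assert {s.pos: s.cpg for s in shared} == {
            int(k): v for k, v in truth["cpg"].items()
        }

    def test_simulator_round_trip(self):
        """Scanning simulator output recovers the selected site plus its
        shared neutral SNPs exactly."""
        params = model_params(
            Ne=10_000, Na=50_000, T=160_000, p=0.5, Ts=600_000,
            r=1.25e-8, mu=1e-7, L=2_000, selected_pos=1_000,
        )
        for seed in (3, 5, 11):
            s = simulate_sample(params, SamplingParams(n=4, class_counts=(2, 2)), seed=seed)
            G = s.haplotypes
            pos = np.floor(s.positions).astype(int)
            if len(set(pos)) != len(pos):
                continue  # integer collision of continuous positions: skip
            expected = []
            variants = {0: [], 1: []}
            bases = ("A", "G")
            for k in range(G.shape[0]):
                for sp in (0, 1):
                    col = G[k, s.species == sp]
                    if 0 < col.mean() < 1:
                        variants[sp].append(
                            _variant(pos[k], bases[0], bases[1], col)
                        )
                f1 = G[k, s.species == 0].mean()
                f2 = G[k, s.species == 1].mean()
                if 0 < f1 < 1 and 0 < f2 < 1:
                    expected.append(pos[k])
            shared, mism = find_shared_snps(variants[0], variants[1])
            assert [x.pos for x in shared] == expected
            assert int(np.floor(s.selected_position)) in expected
            assert mism == 0


class TestClusterReport:
    def test_single_snp_cluster_has_zero_span(self):
        snp = find_shared_snps(
            [_variant(10, "A", "G", [0, 1, 0, 1])],
            [_variant(10, "A", "G", [0, 1, 1, 0])],
        )[0]
        rep = cluster_and_report(snp)
        assert len(rep.clusters) == 1
        assert rep.clusters[0].span == 0

    def test_two_coupled_snps_form_cluster_with_span(self):
        col = np.array([0] * 10 + [1] * 10)
        v1 = [_variant(100, "A", "G", col), _variant(200, "C", "T", col)]
        v2 = [_variant(100, "A", "G", col), _variant(200, "C", "T", col)]
        shared, _ = find_shared_snps(v1, v2)
        rep = cluster_and_report(shared, window_bp=400)
        c = rep.clusters[0]
        assert (c.span, c.n_shared, c.phase) == (100, 2, "same")

    def test_planted_cluster_fixture_recovered_exactly(self, tmp_path):
        paths = generate_fixtures("planted-cluster", 3, tmp_path)
        v1 = read_vcf_haplotypes(str(paths[0]))
        v2 = read_vcf_haplotypes(str(paths[1]))
        truth = json.loads(paths[3].read_text())
        shared, _ = find_shared_snps(v1, v2)
        rep = cluster_and_report(shared, window_bp=400)
        assert [c.positions for c in rep.clusters] == truth["clusters"]
        assert [c.span for c in rep.clusters] == truth["spans"]
        assert [c.phase for c in rep.clusters] == truth["within_phase"]
        assert rep.between_cluster_phase[(0, 1)] == truth["between_phase"]

    def test_fixed_difference_flag(self):
        col = np.array([0, 0, 1, 1])
        shared_v1 = [_variant(100, "A", "G", col), _variant(300, "C", "T", col)]
        shared_v2 = [_variant(100, "A", "G", col), _variant(300, "C", "T", col)]
        # a fixed ALT in species 1 only, inside the span
        v1 = shared_v1 + [_variant(200, "A", "T", np.ones(4, dtype=int))]
        v1.sort(key=lambda v: v.pos)
        shared, _ = find_shared_snps(v1, shared_v2)
        rep = cluster_and_report(shared, variants_sp1=v1, variants_sp2=shared_v2)
        assert rep.clusters[0].has_fixed_difference is True


class TestCpG:
    @pytest.mark.parametrize(
        "context,expected",
        [("ACG", True), ("CGT", True), ("ATA", False), ("GCA", False), (None, None)],
    )
    def test_flag(self, context, expected):
        assert cpg_flag(context) is expected


class TestDeterminism:
    def test_fixtures_byte_identical_across_runs(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        for kind in ("toy-vcf-pair", "planted-cluster", "simulator-replicates"):
            p1 = generate_fixtures(kind, 11, d1)
            p2 = generate_fixtures(kind, 11, d2)
            for a, b in zip(p1, p2):
                assert a.read_bytes() == b.read_bytes()

    def test_vcf_round_trip(self, tmp_path):
        H = np.array([[0, 1, 0, 1], [1, 0, 0, 1]])
        path = tmp_path / "t.vcf"
        write_vcf(path, [9, 42], ["A", "C"], ["G", "T"], H)
        v = read_vcf_haplotypes(str(path))
        assert [x.pos for x in v] == [9, 42]
        assert np.array_equal(v[0].haplotypes, H[0])
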