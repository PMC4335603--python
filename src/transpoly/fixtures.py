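"""Deterministic toy datasets for tests and demonstrations.

Three kinds are provided:

* ``toy-vcf-pair`` -- a pair of small phased VCFs (plus reference FASTA and a
  JSON truth table) containing identical-allele shared SNPs, allele-mismatch
  sites and CpG / non-CpG contexts;
* ``planted-cluster`` -- a VCF pair emulating the two-cluster
  opposite-phase pattern seen at real candidate loci: two clusters of shared
  SNPs, perfectly coupled within clusters, with the coupling phase flipped
  between clusters in one species;
* ``simulator-replicates`` -- cached conditional-simulator output in
  ms-style format.

Everything is a pure function of the seed: the same seed yields
byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .params import SamplingParams, model_params
from .formats import ms_block, sample_annotations, write_fasta, write_ms, write_vcf
from .simulator import simulate_sample

__all__ = ["generate_fixtures", "FIXTURE_KINDS"]

FIXTURE_KINDS = ("toy-vcf-pair", "planted-cluster", "simulator-replicates")

_BASES = np.array(list("ACGT"))


def _reference(rng, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def generate_fixtures(kind: str, seed: int, outdir: str | Path) -> list[Path]:
    """Write the fixture files for ``kind`` under ``outdir`` and return the
    paths (deterministic given ``seed``)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if kind == "toy-vcf-pair":
        return _toy_vcf_pair(seed, outdir)
    if kind == "planted-cluster":
        return _planted_cluster(seed, outdir)
    if kind == "simulator-replicates":
        return _simulator_replicates(seed, outdir)
    raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")


def _toy_vcf_pair(seed: int, outdir: Path) -> list[Path]:
    rng = np.random.default_rng(seed)
    L = 500
    ref = list(_reference(rng, L))
    n_hap = 8  # per species

    shared_pos = [100, 150, 340]
    mismatch_pos = [220, 260]
    private_pos = [50, 410]

    # make position 100 a CpG context and 150/340 non-CpG
    ref[100], ref[101] = "C", "G"
    ref[149], ref[150], ref[151] = "A", "T", "A"
    ref[339], ref[340], ref[341] = "T", "G", "T"

    def alt_of(pos, forbid=()):
        choices = [b for b in "ACGT" if b != ref[pos] and b not in forbid]
        return str(rng.choice(choices))

    v1, v2 = [], []
    truth = {"shared": shared_pos, "mismatch": mismatch_pos, "cpg": {100: True, 150: False, 340: False}}
    for pos in shared_pos:
        alt = alt_of(pos)
        h1 = (rng.random(n_hap) < 0.5).astype(int)
        h2 = (rng.random(n_hap) < 0.5).astype(int)
        h1[0], h1[1] = 0, 1  # keep polymorphic
        h2[0], h2[1] = 0, 1
        v1.append((pos, ref[pos], alt, h1))
        v2.append((pos, ref[pos], alt, h2))
    for pos in mismatch_pos:
        alt1 = alt_of(pos)
        alt2 = alt_of(pos, forbid=(alt1,))
        h = (rng.random(n_hap) < 0.5).astype(int)
        h[0], h[1] = 0, 1
        v1.append((pos, ref[pos], alt1, h))
        v2.append((pos, ref[pos], alt2, h.copy()))
    v1.append((private_pos[0], ref[private_pos[0]], alt_of(private_pos[0]), np.array([0, 1] * (n_hap // 2))))
    v2.append((private_pos[1], ref[private_pos[1]], alt_of(private_pos[1]), np.array([0, 1] * (n_hap // 2))))

    paths = []
    for name, recs in (("sp1", v1), ("sp2", v2)):
        recs.sort(key=lambda t: t[0])
        path = outdir / f"toy_{name}.vcf"
        write_vcf(
            path,
            [p for p, *_ in recs],
            [r for _, r, _, _ in recs],
            [a for _, _, a, _ in recs],
            np.array([h for *_, h in recs]),
            contig_length=L,
        )
        paths.append(path)
    fasta = outdir / "toy_reference.fa"
    write_fasta(fasta, "1", "".join(ref))
    truth_path = outdir / "toy_truth.json"
    truth_path.write_text(json.dumps(truth, indent=2, default=str) + "\n")
    return paths + [fasta, truth_path]


def _planted_cluster(seed: int, outdir: Path) -> list[Path]:
    rng = np.random.default_rng(seed)
    L = 2000
    ref = list(_reference(rng, L))
    n_hap = 20
    core = (rng.random(n_hap) < 0.5).astype(int)
    core[0], core[1] = 0, 1

    cluster1 = [300, 380, 450]  # span 150
    cluster2 = [1300, 1400]  # 850 bp away: separate cluster at 400-bp linkage
    v1, v2 = [], []
    for pos in cluster1 + cluster2:
        ref[pos] = "A"
        if pos + 1 < L and ref[pos + 1] == "G":
            ref[pos + 1] = "T"  # keep planted sites non-CpG
        if ref[pos - 1] == "C":
            ref[pos - 1] = "T"
        alt = "G"
        h1 = core.copy()
        # species 2: same coupling within each cluster, but cluster 2 rides
        # the opposite phase relative to cluster 1
        h2 = core.copy() if pos in cluster1 else 1 - core.copy()
        v1.append((pos, "A", alt, h1))
        v2.append((pos, "A", alt, h2))
    paths = []
    for name, recs in (("sp1", v1), ("sp2", v2)):
        path = outdir / f"planted_{name}.vcf"
        write_vcf(
            path,
            [p for p, *_ in recs],
            [r for _, r, _, _ in recs],
            [a for _, _, a, _ in recs],
            np.array([h for *_, h in recs]),
            contig_length=L,
        )
        paths.append(path)
    fasta = outdir / "planted_reference.fa"
    write_fasta(fasta, "1", "".join(ref))
    truth = {
        "clusters": [cluster1, cluster2],
        "spans": [cluster1[-1] - cluster1[0], cluster2[-1] - cluster2[0]],
        "within_phase": ["same", "same"],
        "between_phase": "opposite",
    }
    truth_path = outdir / "planted_truth.json"
    truth_path.write_text(json.dumps(truth, indent=2) + "\n")
    return paths + [fasta, truth_path]


def _simulator_replicates(seed: int, outdir: Path, replicates: int = 5) -> list[Path]:
    params = model_params(
        Ne=10_000, Na=50_000, T=160_000, p=0.5, Ts=600_000,
        r=1.25e-8, mu=1.2e-8, L=10_000, selected_pos=5_000,
    )
    rng = np.random.default_rng(seed)
    blocks = []
    for rep in range(replicates):
        s = simulate_sample(
            params,
            SamplingParams(n=2, class_counts=(1, 1)),
            seed=int(rng.integers(1, 2**31)),
        )
        comments = sample_annotations(s.species, s.classes)
        comments.append(f"# replicate {rep} selected_position {s.selected_position}")
        blocks.append(
            ms_block(s.positions, s.haplotypes, s.ts.sequence_length, comments)
        )
    path = outdir / "simulator_replicates.ms"
    write_ms(path, blocks, command_line=f"transpoly simulate (seed {seed})")
    return [path]
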