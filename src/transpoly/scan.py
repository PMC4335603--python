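"""Scan two-species variant data for trans-species polymorphism candidates.

Finds shared SNPs (same homologous position, identical segregating allele
pair in both species), clusters them, tests pairwise LD and coupling phase in
each species, annotates CpG context, and reports cluster spans -- the span of
a region being the distance between the two outermost shared SNPs that are in
significant LD in both species.

Coordinates are 0-based half-open internally; VCF's 1-based positions are
converted at the boundary.  Allele matching requires literal identity (no
strand-complement rescue): between closely related species the alignment
strand is assumed consistent, and the mismatch count surfaces potential
strand problems.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .ld import HaplotypeTable, coupling_phase, ld_significance, pairwise_ld
from .params import ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "Variant",
    "SharedSNP",
    "ClusterReport",
    "SharedSNPReport",
    "read_vcf_haplotypes",
    "find_shared_snps",
    "cluster_and_report",
    "cpg_flag",
]


@dataclass(frozen=True)
class Variant:
    """One biallelic variant: 0-based position, REF/ALT alleles, and the
    phased 0/1 haplotype column (0 = REF)."""

    pos: int
    ref: str
    alt: str
    haplotypes: np.ndarray

    @property
    def allele_pair(self) -> frozenset:
        return frozenset((self.ref, self.alt))

    def canonical_column(self) -> np.ndarray:
        """Haplotype column recoded so that 0 is the lexicographically
        smaller allele (label-stable across species)."""
        h = np.asarray(self.haplotypes, dtype=np.int8)
        return h if self.ref < self.alt else (1 - h)


@dataclass(frozen=True)
class SharedSNP:
    """A polymorphism with the identical allele pair in both species."""

    pos: int
    alleles: tuple[str, str]  # lexicographic order
    freq_sp1: float  # frequency of alleles[1]
    freq_sp2: float
    hap_sp1: np.ndarray = field(repr=False)
    hap_sp2: np.ndarray = field(repr=False)
    cpg: bool | None = None  # None = context unknown


@dataclass
class ClusterReport:
    cluster_id: int
    positions: list[int]
    span: int
    n_shared: int
    n_non_cpg: int | None
    phase: str  # same | opposite | mixed | indeterminate
    min_r2: float
    n_significant_pairs: int
    has_fixed_difference: bool | None


@dataclass
class SharedSNPReport:
    clusters: list[ClusterReport]
    between_cluster_phase: dict[tuple[int, int], str]
    n_shared: int
    n_allele_mismatch: int
    window_bp: int
    alpha: float


def read_vcf_haplotypes(path: str) -> list[Variant]:
    """Read biallelic, fully phased variants from a VCF into
    :class:`Variant` records (positions converted to 0-based).

    Multiallelic records are skipped with a warning; missing or unphased
    genotypes are an error (LD needs phased haplotypes).
    """
    from cyvcf2 import VCF

    out: list[Variant] = []
    skipped = 0
    for rec in VCF(path):
        if len(rec.ALT) != 1:
            skipped += 1
            continue
        gts = np.array(rec.genotypes)  # (n_indiv, ploidy+1); last col = phased
        if gts.shape[1] > 2 and not np.all(gts[:, -1]):
            raise ParameterError(f"{path}: unphased genotype at {rec.POS}")
        hap = gts[:, :-1].reshape(-1)
        if np.any(hap < 0):
            raise ParameterError(f"{path}: missing genotype at {rec.POS}")
        out.append(
            Variant(pos=rec.POS - 1, ref=rec.REF, alt=rec.ALT[0], haplotypes=hap)
        )
    if skipped:
        logger.warning("%s: skipped %d multiallelic records", path, skipped)
    if any(b.pos < a.pos for a, b in zip(out, out[1:])):
        raise ParameterError(f"{path}: variants are not position-sorted")
    return out


def find_shared_snps(
    variants_sp1: list[Variant],
    variants_sp2: list[Variant],
    reference: str | None = None,
) -> tuple[list[SharedSNP], int]:
    """Identify shared SNPs and count allele-pair mismatches.

    Both inputs must be position-sorted on a common coordinate system.  A
    position polymorphic in both species enters the shared list only when the
    allele pairs are literally identical; mismatched pairs are excluded and
    counted.  ``reference`` (the window's reference sequence, same
    coordinates) enables CpG annotation; without it the CpG flag is None.
    """
    for v in (variants_sp1, variants_sp2):
        if any(b.pos <= a.pos for a, b in zip(v, v[1:])):
            raise ParameterError("input variants must be sorted by position")
    by_pos2 = {v.pos: v for v in variants_sp2}
    shared: list[SharedSNP] = []
    mismatched = 0
    for v1 in variants_sp1:
        v2 = by_pos2.get(v1.pos)
        if v2 is None:
            continue
        if v1.allele_pair != v2.allele_pair:
            mismatched += 1
            logger.info("allele mismatch at %d: %s/%s vs %s/%s",
                        v1.pos, v1.ref, v1.alt, v2.ref, v2.alt)
            continue
        h1, h2 = v1.canonical_column(), v2.canonical_column()
        if len(set(h1)) < 2 or len(set(h2)) < 2:
            continue  # monomorphic in one species: not a shared SNP
        alleles = tuple(sorted(v1.allele_pair))
        ctx = None
        if reference is not None and 1 <= v1.pos < len(reference) - 1:
            ctx = reference[v1.pos - 1 : v1.pos + 2]
        shared.append(
            SharedSNP(
                pos=v1.pos,
                alleles=alleles,
                freq_sp1=float(h1.mean()),
                freq_sp2=float(h2.mean()),
                hap_sp1=h1,
                hap_sp2=h2,
                cpg=cpg_flag(ctx),
            )
        )
    return shared, mismatched


def _pair_stats(a: SharedSNP, b: SharedSNP, alpha: float):
    t1 = HaplotypeTable.from_haplotypes(a.hap_sp1, b.hap_sp1)
    t2 = HaplotypeTable.from_haplotypes(a.hap_sp2, b.hap_sp2)
    _, _, sig1 = ld_significance(t1, alpha)
    _, _, sig2 = ld_significance(t2, alpha)
    r2s = (pairwise_ld(t1).r2, pairwise_ld(t2).r2)
    return sig1 and sig2, coupling_phase(t1, t2), r2s


def _consensus(phases: list[str]) -> str:
    det = [p for p in phases if p != "indeterminate"]
    if not det:
        return "indeterminate"
    if all(p == "same" for p in det):
        return "same"
    if all(p == "opposite" for p in det):
        return "opposite"
    return "mixed"


def cluster_and_report(
    shared: list[SharedSNP],
    window_bp: int = 400,
    alpha: float = 0.05,
    variants_sp1: list[Variant] | None = None,
    variants_sp2: list[Variant] | None = None,
) -> SharedSNPReport:
    """Single-linkage clustering of shared SNPs at ``window_bp``, with
    per-cluster spans, counts, LD/coupling summaries, and (when the full
    per-species variant lists are supplied) a flag for fixed inter-species
    differences inside the span.

    The reported span is the distance between the two outermost shared SNPs
    of the cluster that are in significant LD (with another cluster member)
    in both species; a single-SNP cluster has span 0.
    """
    shared = sorted(shared, key=lambda s: s.pos)
    clusters: list[list[SharedSNP]] = []
    for snp in shared:
        if clusters and snp.pos - clusters[-1][-1].pos <= window_bp:
            clusters[-1].append(snp)
        else:
            clusters.append([snp])

    reports: list[ClusterReport] = []
    for ci, members in enumerate(clusters):
        phases: list[str] = []
        r2_all: list[float] = []
        n_sig = 0
        supported: set[int] = set()
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                sig, phase, r2s = _pair_stats(members[i], members[j], alpha)
                phases.append(phase)
                r2_all.extend(r2s)
                if sig:
                    n_sig += 1
                    supported.update((members[i].pos, members[j].pos))
        span = (max(supported) - min(supported)) if len(supported) >= 2 else 0
        cpgs = [m.cpg for m in members]
        n_non_cpg = None if any(c is None for c in cpgs) else sum(1 for c in cpgs if not c)
        fixed = None
        if variants_sp1 is not None and variants_sp2 is not None and span > 0:
            lo, hi = min(supported), max(supported)
            fixed = _has_fixed_difference(variants_sp1, variants_sp2, lo, hi)
        reports.append(
            ClusterReport(
                cluster_id=ci,
                positions=[m.pos for m in members],
                span=span,
                n_shared=len(members),
                n_non_cpg=n_non_cpg,
                phase=_consensus(phases),
                min_r2=float(np.nanmin(r2_all)) if r2_all else float("nan"),
                n_significant_pairs=n_sig,
                has_fixed_difference=fixed,
            )
        )

    between: dict[tuple[int, int], str] = {}
    for i in range(len(clusters)):
        for j in range(i + 1, len(clusters)):
            phases = [
                _pair_stats(a, b, alpha)[1] for a in clusters[i] for b in clusters[j]
            ]
            between[(i, j)] = _consensus(phases)

    return SharedSNPReport(
        clusters=reports,
        between_cluster_phase=between,
        n_shared=len(shared),
        n_allele_mismatch=0,
        window_bp=window_bp,
        alpha=alpha,
    )


def _has_fixed_difference(
    v1: list[Variant], v2: list[Variant], lo: int, hi: int
) -> bool:
    """A fixed difference inside [lo, hi]: a site where one species is fixed
    for one allele and the other for a different allele.  With per-species
    VCFs, a variant position present in exactly one species and fixed-derived
    there qualifies; sites absent from both files are assumed identical."""
    in1 = {v.pos: v for v in v1 if lo <= v.pos <= hi}
    in2 = {v.pos: v for v in v2 if lo <= v.pos <= hi}
    for pos in set(in1) | set(in2):
        a, b = in1.get(pos), in2.get(pos)
        if a is not None and b is not None:
            fa, fb = a.canonical_column().mean(), b.canonical_column().mean()
            if (fa == 0 and fb == 1) or (fa == 1 and fb == 0):
                return True
            continue
        v = a or b
        if v.canonical_column().mean() in (0.0, 1.0):
            f = v.haplotypes.mean()
            if f == 1.0:  # fixed for ALT in one species, REF (implicitly) in the other
                return True
    return False


def cpg_flag(context: str | None) -> bool | None:
    """True if the focal (middle) base of a trinucleotide context sits in a
    CG dinucleotide on either strand (CG is its own reverse complement, so
    the forward check suffices); None when the context is unavailable."""
    if context is None or len(context) != 3:
        return None
    ctx = context.upper()
    return ctx[0:2] == "CG" or ctx[1:3] == "CG"
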