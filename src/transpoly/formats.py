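"""Text output formats: ms-style haplotype blocks, Newick trees, minimal VCF
writing, TSV tables and JSON run metadata.

All outputs are plain text and deterministic: TSV files carry a single
``#``-prefixed header line and floats at six significant digits, so byte
identity is a meaningful reproducibility check.
"""

from __future__ import annotations

import json
import platform
import time
from pathlib import Path

import numpy as np

from . import __version__


def fmt(x) -> str:
    """Six-significant-digit float formatting (integers pass through)."""
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    if isinstance(x, float) and float(x).is_integer() and abs(x) < 1e15:
        return str(int(x))
    return f"{x:.6g}"


def write_tsv(path: str | Path, header: list[str], rows: list[list]) -> None:
    lines = ["#" + "\t".join(header)]
    for row in rows:
        lines.append("\t".join(fmt(v) if isinstance(v, (int, float, np.floating, np.integer)) else str(v) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def write_metadata(path: str | Path, command: str, parameters: dict, seed=None) -> None:
    """JSON sidecar recording everything needed to reproduce an artifact."""
    meta = {
        "command": command,
        "parameters": parameters,
        "seed": seed,
        "version": __version__,
        "python": platform.python_version(),
        "walltime_unix": time.time(),
    }
    Path(path).write_text(json.dumps(meta, indent=2, default=str) + "\n")


def ms_block(
    positions: np.ndarray,
    genotypes: np.ndarray,
    sequence_length: float,
    header_comments: list[str] | None = None,
) -> str:
    """One ms-style replicate block: ``//``, ``segsites:``, ``positions:``
    (relative to the window) and one 0/1 row per haplotype.

    ``genotypes`` is sites x haplotypes; annotation lines (species, class)
    go in as ``#`` comments before the block.
    """
    lines = list(header_comments or [])
    lines.append("//")
    lines.append(f"segsites: {len(positions)}")
    rel = np.asarray(positions, dtype=float) / sequence_length
    lines.append("positions: " + " ".join(f"{x:.6f}" for x in rel))
    H = np.asarray(genotypes).T  # haplotypes x sites
    for row in H:
        lines.append("".join(str(int(v)) for v in row))
    return "\n".join(lines) + "\n"


def write_ms(path: str | Path, blocks: list[str], command_line: str = "transpoly") -> None:
    Path(path).write_text(command_line + "\n\n" + "".join(blocks))


def sample_annotations(species: np.ndarray, classes: np.ndarray) -> list[str]:
    return [
        "# sample\tspecies\tclass",
        *(
            f"# {i}\tsp{s + 1}\t{'A1' if c == 0 else 'A2'}"
            for i, (s, c) in enumerate(zip(species, classes))
        ),
    ]


def write_vcf(
    path: str | Path,
    positions: list[int],
    refs: list[str],
    alts: list[str],
    haplotypes: np.ndarray,
    chrom: str = "1",
    contig_length: int = 1_000_000,
) -> None:
    """Minimal phased VCF 4.2 writer (haplotypes paired into diploid
    individuals; positions 0-based in, 1-based out)."""
    H = np.asarray(haplotypes)
    n_hap = H.shape[1]
    if n_hap % 2:
        raise ValueError("need an even number of haplotypes to form diploids")
    n_ind = n_hap // 2
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={chrom},length={contig_length}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(f"ind{i}" for i in range(n_ind)),
    ]
    for k, (pos, ref, alt) in enumerate(zip(positions, refs, alts)):
        gts = "\t".join(f"{H[k, 2 * i]}|{H[k, 2 * i + 1]}" for i in range(n_ind))
        lines.append(f"{chrom}\t{pos + 1}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_fasta(path: str | Path, name: str, sequence: str, width: int = 70) -> None:
    chunks = [sequence[i : i + width] for i in range(0, len(sequence), width)]
    Path(path).write_text(">" + name + "\n" + "\n".join(chunks) + "\n")
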