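"""Thin readers/writers for the plain-text formats the pipeline exchanges.

FASTA/FASTQ parsing is delegated to pysam's C parser; writing is plain
emission (Sanger Phred+33 for FASTQ).
"""

from __future__ import annotations

import os
from typing import Iterable, Iterator

import numpy as np
import pysam

PHRED_OFFSET = 33


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """FASTA file -> {name: sequence} (order-preserving)."""
    out: dict[str, str] = {}
    with pysam.FastxFile(str(path)) as fh:
        for rec in fh:
            out[rec.name] = rec.sequence.upper()
    return out


def write_fasta(path: str | os.PathLike, records: Iterable[tuple[str, str]],
                width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def iter_fastq(path: str | os.PathLike) -> Iterator[tuple[str, str, str]]:
    """Yield (name, sequence, quality string) from a FASTQ file."""
    with pysam.FastxFile(str(path)) as fh:
        for rec in fh:
            if rec.quality is None:
                raise ValueError(f"FASTQ record without quality: {rec.name}")
            yield rec.name, rec.sequence.upper(), rec.quality


def write_fastq(path: str | os.PathLike,
                records: Iterable[tuple[str, str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq, qual in records:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def qual_to_phred(qual: str) -> np.ndarray:
    return np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(
        np.int32
    ) - PHRED_OFFSET


def phred_to_qual(phred: np.ndarray) -> str:
    return (phred.astype(np.uint8) + np.uint8(PHRED_OFFSET)).tobytes().decode(
        "ascii"
    )


def mean_error_prob(qual: str) -> float:
    """Mean per-base error probability implied by a Phred quality string."""
    q = qual_to_phred(qual)
    return float(np.mean(10.0 ** (-q / 10.0)))


def mean_accuracy(qual: str) -> float:
    """Phred-implied mean accuracy (1 - mean error probability).

    Uniform Q20 gives 0.99; uniform Q30 gives 0.999.
    """
    return 1.0 - mean_error_prob(qual)
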