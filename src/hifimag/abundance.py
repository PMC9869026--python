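"""Depth-based community composition.

Reads are assigned to genomes by shared minimizers (a lightweight stand-in
for full read mapping, adequate for communities of divergent taxa); each
genome's mean coverage depth is the total assigned reference span divided
by genome length; relative abundance at a taxonomic rank is each taxon's
summed depth as a fraction of total depth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._kmers import minimizers
from .taxonomy import RANKS, taxon_at_rank

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReadAssignment:
    read_id: str
    genome_id: str
    ref_start: int
    ref_end: int
    read_length: int
    n_shared: int


@dataclass
class DepthProfile:
    genomes: dict[str, tuple[float, int, int]]  # id -> (depth, bases, reads)
    total_assigned_fraction: float

    def depth(self, gid: str) -> float:
        return self.genomes.get(gid, (0.0, 0, 0))[0]


@dataclass
class MinimizerIndex:
    k: int
    w: int
    genomes: dict[str, tuple[np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )  # id -> (sorted hashes, positions in hash order)
    lengths: dict[str, int] = field(default_factory=dict)


def index_genomes(
    genomes: dict[str, str], k: int = 17, w: int = 11
) -> MinimizerIndex:
    idx = MinimizerIndex(k, w)
    for gid, seq in genomes.items():
        h, pos = minimizers(seq, k, w)
        order = np.argsort(h, kind="stable")
        idx.genomes[gid] = (h[order], pos[order])
        idx.lengths[gid] = len(seq)
    return idx


def assign_reads(
    reads: list[tuple[str, str]] | "iter",
    index: MinimizerIndex,
    min_shared: int = 10,
) -> list[ReadAssignment]:
    """Assign each read to the genome sharing the most minimizers.

    A read is unassigned when no genome shares more than ``min_shared``
    minimizers; ties go to the lexicographically smallest genome id (and
    are logged). The covered reference interval is estimated from the
    min/max positions of the matched minimizers after localising them
    around the median match (repeated elements — e.g. identical rRNA
    operon copies — otherwise inflate the span across distant loci).
    """
    out: list[ReadAssignment] = []
    gids = sorted(index.genomes)
    for read_id, seq in reads:
        rh, _ = minimizers(seq, index.k, index.w)
        rh = np.unique(rh)
        best_gid = None
        best_n = min_shared
        best_span = (0, 0)
        for gid in gids:
            gh, gpos = index.genomes[gid]
            lo = np.searchsorted(gh, rh, side="left")
            hi = np.searchsorted(gh, rh, side="right")
            hit = hi > lo
            n = int(hit.sum())
            if n > best_n:
                pos = np.sort(gpos[lo[hit]])
                # largest run of positions with gaps below the read length
                breaks = np.flatnonzero(np.diff(pos) > 1.5 * len(seq))
                starts = np.concatenate([[0], breaks + 1])
                ends = np.concatenate([breaks + 1, [pos.size]])
                gi_best = int(np.argmax(ends - starts))
                local = pos[starts[gi_best] : ends[gi_best]]
                best_gid, best_n = gid, n
                best_span = (int(local.min()), int(local.max()) + index.k)
            elif n == best_n and best_gid is not None and n > min_shared:
                log.info("minimizer tie for read %s: %s kept over %s",
                         read_id, best_gid, gid)
        if best_gid is not None:
            out.append(
                ReadAssignment(read_id, best_gid, best_span[0],
                               best_span[1], len(seq), best_n)
            )
    return out


def mean_depth(
    assignments: list[ReadAssignment],
    lengths: dict[str, int],
    n_reads_total: int | None = None,
) -> DepthProfile:
    """Per-genome mean coverage depth from assigned reference intervals."""
    bases: dict[str, int] = {g: 0 for g in lengths}
    counts: dict[str, int] = {g: 0 for g in lengths}
    for a in assignments:
        span = a.ref_end - a.ref_start
        # a read can never cover more than its own length or the genome
        span = min(span, a.read_length, lengths[a.genome_id])
        bases[a.genome_id] += span
        counts[a.genome_id] += 1
    genomes = {
        g: (bases[g] / lengths[g], bases[g], counts[g]) for g in lengths
    }
    n_total = n_reads_total if n_reads_total is not None else len(assignments)
    frac = len(assignments) / n_total if n_total else 0.0
    return DepthProfile(genomes, frac)


def rank_profile(
    depths: DepthProfile,
    taxonomy: dict[str, str],
    rank: str,
) -> dict[str, float]:
    """Depth-weighted relative abundance at a taxonomic rank.

    abundance(taxon) = sum of depths of genomes in the taxon / total depth.
    Genomes without a lineage fall under "unclassified" with a warning.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    weights: dict[str, float] = {}
    for gid, (depth, _, _) in depths.genomes.items():
        if depth <= 0:
            continue
        path = taxonomy.get(gid)
        if path is None:
            log.warning("genome %s has no taxonomy; grouped as unclassified",
                        gid)
            taxon = "unclassified"
        else:
            taxon = taxon_at_rank(path, rank)
        weights[taxon] = weights.get(taxon, 0.0) + depth
    total = sum(weights.values())
    if total == 0:
        return {}
    return {t: w / total for t, w in sorted(weights.items())}


def depth_table(depths: DepthProfile) -> str:
    lines = ["genome_id\tmean_depth_x\tbases_assigned\tn_reads\tbase_fraction"]
    total_bases = sum(b for _, b, _ in depths.genomes.values()) or 1
    for gid in sorted(depths.genomes):
        d, b, n = depths.genomes[gid]
        lines.append(f"{gid}\t{d:.3f}\t{b}\t{n}\t{b / total_bases:.6f}")
    return "\n".join(lines) + "\n"
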