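"""Synthetic HiFi metagenome communities with machine-readable ground truth.

This module fabricates everything a desk-scale run of the pipeline needs:

* replicon sequences (circular chromosomes, plasmids, viruses) with planted
  rRNA operons (16S-23S-5S), tRNA genes and a universal single-copy marker
  panel, all coordinates recorded;
* HiFi-like reads (lognormal lengths targeting a chosen N50, per-base Phred
  qualities whose implied accuracy is an unbiased estimate of the planted
  substitution rate);
* GFA1 assembly graphs exhibiting the three contig topologies (circular,
  strain-tangled "circular", linear);
* a truth manifest binding every read, gene and graph component to its
  source, so downstream stages can be scored against known answers.

The default community is a 12-taxon mixed bacterial/archaeal assemblage with
log-normal abundances and one taxon forced to >= 60%, emulating the strongly
skewed composition of a food-waste anaerobic digester.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import refdata
from ._kmers import revcomp
from .io import write_fasta, write_fastq, phred_to_qual
from .taxonomy import default_taxon_path, n_default_taxa, taxon_at_rank

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _stable_hash(text: str) -> int:
    return int.from_bytes(hashlib.md5(text.encode()).digest()[:4], "big") % (
        2**31
    )


def genus_index_for(taxon_path: str) -> int:
    """Stable template index for a lineage's genus label.

    ``GenusNN`` labels map to NN-1 (so the default community lines up with
    the packaged reference 16S set); anything else hashes deterministically.
    """
    genus = taxon_path.split(";")[-1]
    if genus.startswith("Genus") and genus[5:].isdigit():
        return int(genus[5:]) - 1
    return _stable_hash(genus) % 10_000


# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class RepliconSpec:
    id: str
    length_bp: int
    topology: str  # circular | linear
    replicon_class: str  # chromosome | plasmid | virus
    gc_fraction: float = 0.5
    rrn_operon_copies: int = 0
    trna_types: tuple[str, ...] = ()
    taxon_path: str = "Bacteria"

    def validate(self) -> None:
        if self.length_bp < 1_000:
            raise ValueError(f"{self.id}: replicon shorter than 1 kb")
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"{self.id}: bad topology {self.topology!r}")
        if self.replicon_class not in ("chromosome", "plasmid", "virus"):
            raise ValueError(f"{self.id}: bad class {self.replicon_class!r}")
        if self.replicon_class == "chromosome" and self.length_bp < 1_000_000:
            raise ValueError(f"{self.id}: chromosomes must be >= 1 Mb")
        if self.replicon_class != "chromosome" and self.length_bp >= 1_000_000:
            raise ValueError(f"{self.id}: plasmid/virus must be < 1 Mb")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError(f"{self.id}: GC outside [0,1]")
        if not 0 <= self.rrn_operon_copies <= 15:
            raise ValueError(f"{self.id}: rRNA operon copies outside 0..15")
        unknown = set(self.trna_types) - set(refdata.STANDARD_TRNA_ISOTYPES)
        if unknown:
            raise ValueError(f"{self.id}: unknown tRNA isotypes {unknown}")


@dataclass(frozen=True)
class CommunitySpec:
    replicons: tuple[RepliconSpec, ...]
    abundances: tuple[float, ...]
    strain_variants: dict[str, tuple[int, float]] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if len(self.replicons) != len(self.abundances):
            raise ValueError("replicons and abundances differ in length")
        if any(a <= 0 for a in self.abundances):
            raise ValueError("abundances must be positive")
        if abs(sum(self.abundances) - 1.0) > 1e-9:
            raise ValueError("abundances must sum to 1")
        ids = {r.id for r in self.replicons}
        for r in self.replicons:
            r.validate()
        for rid in self.strain_variants:
            if rid not in ids:
                raise ValueError(f"strain variants for unknown replicon {rid}")


@dataclass(frozen=True)
class ReadModel:
    """Read-length and quality model for HiFi-like reads.

    Lengths are lognormal; the base-weighted median of a lognormal(mu, s)
    is exp(mu + s^2), so mu is set from the target N50. Per-read base
    quality is drawn from a 5-wide integer window around a calibrated
    centre, with +/-2 per-base jitter; substitutions are then drawn at the
    per-base Phred-implied error probability, which makes the quality
    strings an unbiased accuracy estimate by construction.
    """

    length_n50_bp: int = 14_254
    min_length_bp: int = 1_000
    mean_accuracy: float = 0.9994
    length_sigma: float = 0.55
    indel_fraction: float = 0.0  # reserved; substitution-only by default

    def validate(self) -> None:
        if self.mean_accuracy <= 0.99:
            raise ValueError("mean_accuracy must exceed 0.99")
        if self.min_length_bp < 1:
            raise ValueError("min_length_bp must be positive")
        if self.indel_fraction != 0.0:
            raise NotImplementedError("indel errors are not implemented")

    @property
    def length_mu(self) -> float:
        return float(np.log(self.length_n50_bp) - self.length_sigma**2)


# ---------------------------------------------------------------------------
# truth containers


@dataclass(frozen=True)
class Feature:
    kind: str  # rRNA_16S | rRNA_23S | rRNA_5S | tRNA | marker
    feature_id: str
    start: int  # 0-based, half-open, replicon coordinates
    end: int
    strand: str
    operon: int | None = None
    isotype: str | None = None


@dataclass
class RepliconTruth:
    spec: RepliconSpec
    abundance: float
    features: list[Feature]

    def ssu_intervals(self) -> list[tuple[int, int, str, int]]:
        return [
            (f.start, f.end, f.strand, f.operon)
            for f in self.features
            if f.kind == "rRNA_16S"
        ]


@dataclass(frozen=True)
class ReadTruth:
    read_id: str
    replicon_id: str
    start: int
    end: int  # may exceed replicon length for origin-spanning reads
    strand: str
    length: int
    n_sub: int
    ssu: tuple[tuple[int, int, str, int], ...]  # read coords, strand, operon


@dataclass
class CommunityTruth:
    replicons: dict[str, RepliconTruth]
    reads: dict[str, ReadTruth] = field(default_factory=dict)

    def copy_number_table(self, rank: str = "genus") -> dict[str, float]:
        """Taxon -> 16S copies per genome at the given rank (chromosomes)."""
        table: dict[str, float] = {}
        for rt in self.replicons.values():
            if rt.spec.replicon_class != "chromosome":
                continue
            taxon = taxon_at_rank(rt.spec.taxon_path, rank)
            table[taxon] = float(rt.spec.rrn_operon_copies)
        return table

    def cell_proportions(self, rank: str = "genus") -> dict[str, float]:
        """True cell-fraction profile over chromosome-bearing taxa."""
        weights: dict[str, float] = {}
        for rt in self.replicons.values():
            if rt.spec.replicon_class != "chromosome":
                continue
            taxon = taxon_at_rank(rt.spec.taxon_path, rank)
            weights[taxon] = weights.get(taxon, 0.0) + rt.abundance
        total = sum(weights.values())
        return {t: w / total for t, w in weights.items()}


# ---------------------------------------------------------------------------
# replicon generation


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=n, p=p)


def _mutate_str(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    idx = np.flatnonzero(rng.random(arr.size) < rate)
    enc = {65: 0, 67: 1, 71: 2, 84: 3}
    for i in idx:
        cur = enc[arr[i]]
        arr[i] = _BASES[(cur + rng.integers(1, 4)) % 4]
    return arr.tobytes().decode("ascii")


def _operon_sequence(genus_idx: int) -> str:
    """Complete rRNA operon: 16S, spacer, 23S, spacer, 5S (one strand)."""
    rng = np.random.default_rng(refdata._MASTER_SEED + 4000 + genus_idx)
    sp1 = _random_bases(rng, 60, 0.5).tobytes().decode()
    sp2 = _random_bases(rng, 40, 0.5).tobytes().decode()
    return (
        refdata.genus_ssu(genus_idx)
        + sp1
        + refdata.genus_lsu(genus_idx)
        + sp2
        + refdata.genus_s5(genus_idx)
    )


def generate_replicon(
    spec: RepliconSpec, seed: int
) -> tuple[str, list[Feature]]:
    """Build a replicon sequence with planted features and exact truth.

    Operons are planted as contiguous 16S-23S-5S blocks on one strand
    (about 4.7 kb, well inside a 10 kb operon window); one copy of every
    listed tRNA isotype is planted; chromosomes additionally carry one
    verbatim copy of each universal single-copy marker. Deterministic for a
    fixed (spec, seed).
    """
    spec.validate()
    rng = np.random.default_rng([seed, _stable_hash(spec.id)])
    gidx = genus_index_for(spec.taxon_path)

    # assemble the feature blocks: (sequence, block descriptor)
    blocks: list[tuple[str, str, dict]] = []
    operon = _operon_sequence(gidx)
    for c in range(spec.rrn_operon_copies):
        strand = "+" if rng.random() < 0.5 else "-"
        blocks.append((operon, "operon", {"operon": c, "strand": strand}))
    for iso in spec.trna_types:
        strand = "+" if rng.random() < 0.5 else "-"
        blocks.append(
            (refdata.trna_genes()[iso], "tRNA",
             {"isotype": iso, "strand": strand})
        )
    if spec.replicon_class == "chromosome":
        for mid, mseq in refdata.marker_panel().items():
            blocks.append((mseq, "marker", {"marker": mid, "strand": "+"}))

    total_feat = sum(len(b[0]) for b in blocks)
    slack = spec.length_bp - total_feat
    if slack < 0:
        raise ValueError(
            f"{spec.id}: planted features ({total_feat} bp) exceed replicon "
            f"length ({spec.length_bp} bp)"
        )

    order = rng.permutation(len(blocks))
    gaps = rng.multinomial(slack, np.full(len(blocks) + 1,
                                          1.0 / (len(blocks) + 1)))
    arr = _random_bases(rng, spec.length_bp, spec.gc_fraction)
    features: list[Feature] = []
    pos = int(gaps[0])
    ssu_len, sp1 = refdata.SSU_LEN, 60
    lsu_len, sp2 = refdata.LSU_LEN, 40
    for gi, bi in enumerate(order):
        bseq, kind, info = blocks[bi]
        strand = info["strand"]
        planted = bseq if strand == "+" else revcomp(bseq)
        arr[pos : pos + len(bseq)] = np.frombuffer(
            planted.encode("ascii"), dtype=np.uint8
        )
        if kind == "operon":
            c = info["operon"]
            # sub-gene coordinates within the (possibly flipped) block
            parts = [
                ("rRNA_16S", 0, ssu_len),
                ("rRNA_23S", ssu_len + sp1, ssu_len + sp1 + lsu_len),
                ("rRNA_5S", ssu_len + sp1 + lsu_len + sp2, len(bseq)),
            ]
            for pkind, ps, pe in parts:
                if strand == "+":
                    s, e = pos + ps, pos + pe
                else:
                    s, e = pos + len(bseq) - pe, pos + len(bseq) - ps
                features.append(
                    Feature(pkind, f"{spec.id}_op{c}_{pkind}", s, e, strand,
                            operon=c)
                )
        elif kind == "tRNA":
            features.append(
                Feature("tRNA", f"{spec.id}_trna_{info['isotype']}", pos,
                        pos + len(bseq), strand, isotype=info["isotype"])
            )
        else:
            features.append(
                Feature("marker", f"{spec.id}_{info['marker']}", pos,
                        pos + len(bseq), strand)
            )
        pos += len(bseq) + int(gaps[gi + 1])
    features.sort(key=lambda f: (f.start, f.feature_id))
    return arr.tobytes().decode("ascii"), features


# ---------------------------------------------------------------------------
# read simulation


def _calibrate_q_center(target_err: float) -> tuple[int, float]:
    """Integer quality centre and mixing weight so the window + jitter
    distribution has exactly the target mean error probability."""

    def mean_err(center: int) -> float:
        qs = np.add.outer(np.arange(center - 2, center + 3),
                          np.arange(-2, 3)).ravel()
        qs = np.clip(qs, 2, 60)
        return float(np.mean(10.0 ** (-qs / 10.0)))

    c = 2
    while mean_err(c + 1) > target_err and c < 59:
        c += 1
    lo, hi = mean_err(c), mean_err(c + 1)
    w = (target_err - hi) / (lo - hi) if lo != hi else 1.0
    return c, float(np.clip(w, 0.0, 1.0))


def _sample_read_lengths(
    rng: np.random.Generator, model: ReadModel, target_bases: int,
    max_len: int
) -> np.ndarray:
    """Lognormal lengths accumulated until target coverage is reached."""
    lengths: list[int] = []
    total = 0
    while total < target_bases:
        draw = rng.lognormal(model.length_mu, model.length_sigma,
                             size=64).astype(np.int64)
        for L in draw:
            L = int(min(max(L, model.min_length_bp), max_len))
            lengths.append(L)
            total += L
            if total >= target_bases:
                break
    return np.array(lengths, dtype=np.int64)


def _wrap_intervals(
    truth: RepliconTruth, L: int, start: int, end: int
) -> list[tuple[int, int, str, int]]:
    """Planted 16S intervals fully inside read span [start, end) (may wrap)."""
    out = []
    for gs, ge, strand, op in truth.ssu_intervals():
        for shift in (0, L):
            s, e = gs + shift, ge + shift
            if s >= start and e <= end:
                out.append((s - start, e - start, strand, op))
    return out


def simulate_hifi_reads(
    community: CommunitySpec,
    model: ReadModel,
    depth_target: float | dict[str, float],
    seed: int,
    sequences: dict[str, str] | None = None,
    truth: CommunityTruth | None = None,
) -> tuple[list[tuple[str, str, str]], CommunityTruth]:
    """Simulate HiFi-like reads for a community.

    A scalar ``depth_target`` D means an expected total of D * sum(lengths)
    bases, allocated to replicons proportional to abundance x length (so D
    is the unweighted mean per-replicon coverage; a single replicon gets
    plain coverage D). A mapping gives explicit per-replicon coverage.

    Returns (reads, truth): reads as (id, sequence, quality string); the
    truth manifest records source coordinates, strand, substitution counts
    and the planted 16S intervals of every read.
    """
    community.validate()
    model.validate()
    if sequences is None or truth is None:
        sequences, truth = build_community(community, seed)
    specs = {r.id: r for r in community.replicons}
    ab = dict(zip((r.id for r in community.replicons), community.abundances))

    if isinstance(depth_target, dict):
        depth = {rid: float(depth_target.get(rid, 0.0)) for rid in specs}
    else:
        if depth_target <= 0:
            raise ValueError("depth_target must be positive")
        tot_len = sum(s.length_bp for s in specs.values())
        wsum = sum(ab[r] * specs[r].length_bp for r in specs)
        depth = {
            rid: depth_target * tot_len * ab[rid] / wsum for rid in specs
        }

    target_err = 1.0 - model.mean_accuracy
    qc, qw = _calibrate_q_center(target_err)
    reads: list[tuple[str, str, str]] = []
    ridx = 0
    for i, rid in enumerate(sorted(specs)):
        spec = specs[rid]
        if depth[rid] <= 0:
            continue
        rng = np.random.default_rng([seed, 7, _stable_hash(rid)])
        base_seq = sequences[rid]
        variants = [base_seq]
        if rid in community.strain_variants:
            n_var, div = community.strain_variants[rid]
            vrng = np.random.default_rng([seed, 11, _stable_hash(rid)])
            variants += [
                _mutate_str(base_seq, div, vrng) for _ in range(n_var - 1)
            ]
        L = spec.length_bp
        circular = spec.topology == "circular"
        max_len = L if not circular else L  # one wrap at most
        lengths = _sample_read_lengths(
            rng, model, int(round(depth[rid] * L)), max_len
        )
        ext = [v + v[: int(lengths.max())] if circular else v
               for v in variants]
        for Lr in lengths:
            Lr = int(Lr)
            vi = int(rng.integers(len(variants)))
            if circular:
                start = int(rng.integers(L))
            else:
                start = int(rng.integers(max(L - Lr, 0) + 1))
            frag = ext[vi][start : start + Lr]
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                frag = revcomp(frag)
            # per-base quality and substitution errors
            center = qc if rng.random() < qw else qc + 1
            q0 = int(center + rng.integers(-2, 3))
            q = np.clip(q0 + rng.integers(-2, 3, size=Lr), 2, 60)
            perr = 10.0 ** (-q / 10.0)
            sub = rng.random(Lr) < perr
            n_sub = int(sub.sum())
            if n_sub:
                arr = np.frombuffer(frag.encode("ascii"),
                                    dtype=np.uint8).copy()
                enc = np.zeros(256, dtype=np.uint8)
                enc[_BASES] = np.arange(4)
                shift = rng.integers(1, 4, size=n_sub)
                pos_sub = np.flatnonzero(sub)
                arr[pos_sub] = _BASES[(enc[arr[pos_sub]] + shift) % 4]
                frag = arr.tobytes().decode("ascii")
            read_id = f"r{ridx:07d}"
            ridx += 1
            ssu = _wrap_intervals(truth.replicons[rid], L, start, start + Lr)
            if strand == "-":
                ssu = [
                    (Lr - e, Lr - s, ("-" if st == "+" else "+"), op)
                    for s, e, st, op in ssu
                ]
            ssu.sort()
            reads.append((read_id, frag, phred_to_qual(q)))
            truth.reads[read_id] = ReadTruth(
                read_id, rid, start, start + Lr, strand, Lr, n_sub,
                tuple(ssu),
            )
    return reads, truth


def build_community(
    community: CommunitySpec, seed: int
) -> tuple[dict[str, str], CommunityTruth]:
    """Generate every replicon of a community; returns sequences + truth."""
    community.validate()
    sequences: dict[str, str] = {}
    replicons: dict[str, RepliconTruth] = {}
    for spec, a in zip(community.replicons, community.abundances):
        seq, feats = generate_replicon(spec, seed)
        sequences[spec.id] = seq
        replicons[spec.id] = RepliconTruth(spec, a, feats)
    return sequences, CommunityTruth(replicons)


# ---------------------------------------------------------------------------
# assembly-graph construction


@dataclass(frozen=True)
class GfaComponent:
    """One requested graph component.

    ``segments`` are (name, sequence); ``overlap`` > 0 on a circular
    component means the segment already carries that many duplicated head
    bases at its tail (as real assemblers emit) and the self-link CIGAR
    records it. Explicit ``links`` (from, fo, to, to_orient) override the
    default wiring of tangled components.
    """

    segments: tuple[tuple[str, str], ...]
    topology: str  # circular | tangled_circular | linear
    overlap: int = 0
    links: tuple[tuple[str, str, str, str], ...] | None = None


def build_gfa(
    components: list[GfaComponent], seed: int = 0
) -> tuple[str, list[dict]]:
    """Emit a GFA1 file for the requested components, plus truth labels.

    circular -> one segment with a head-to-tail self-link; tangled_circular
    -> >= 2 segments wired into a cycle (or explicit links); linear -> one
    isolated segment.
    """
    lines = ["H\tVN:Z:1.0"]
    labels: list[dict] = []
    for ci, comp in enumerate(components):
        n = len(comp.segments)
        if comp.topology == "circular" and n != 1:
            raise ValueError("circular component must have exactly 1 segment")
        if comp.topology == "linear" and n != 1:
            raise ValueError("linear component must have exactly 1 segment")
        if comp.topology == "tangled_circular" and n < 2:
            raise ValueError("tangled component needs >= 2 segments")
        if comp.topology not in ("circular", "tangled_circular", "linear"):
            raise ValueError(f"unknown topology {comp.topology!r}")
        for name, seq in comp.segments:
            lines.append(f"S\t{name}\t{seq}")
            labels.append(
                {
                    "segment": name,
                    "component": f"comp{ci:04d}",
                    "topology": comp.topology,
                    "length": len(seq),
                }
            )
        if comp.topology == "circular":
            name = comp.segments[0][0]
            lines.append(f"L\t{name}\t+\t{name}\t+\t{comp.overlap}M")
        elif comp.topology == "tangled_circular":
            links = comp.links
            if links is None:
                names = [s[0] for s in comp.segments]
                links = tuple(
                    (names[i], "+", names[(i + 1) % n], "+")
                    for i in range(n)
                )
            for a, ao, b, bo in links:
                lines.append(f"L\t{a}\t{ao}\t{b}\t{bo}\t0M")
    return "\n".join(lines) + "\n", labels


def tangle_from_variants(
    base_id: str,
    base_seq: str,
    n_variants: int,
    divergence: float,
    n_pieces: int,
    seed: int,
) -> GfaComponent:
    """Strain tangle: variants of one replicon cut at shared boundaries.

    Pieces of all variants are cross-linked at every junction, producing a
    multi-segment component whose link graph contains cycles — the
    "tangled circular" pattern strain mixtures create in assembly graphs.
    """
    if n_variants < 2 or n_pieces < 2:
        raise ValueError("need >= 2 variants and >= 2 pieces")
    rng = np.random.default_rng([seed, _stable_hash(base_id)])
    variants = [base_seq] + [
        _mutate_str(base_seq, divergence, rng) for _ in range(n_variants - 1)
    ]
    L = len(base_seq)
    cuts = [0] + sorted(
        int(c) for c in rng.integers(L // 10, L - L // 10, size=n_pieces - 1)
    ) + [L]
    segments = []
    for vi, v in enumerate(variants):
        for pi in range(n_pieces):
            segments.append(
                (f"{base_id}_v{vi}p{pi}", v[cuts[pi] : cuts[pi + 1]])
            )
    links = []
    for pi in range(n_pieces):
        nxt = (pi + 1) % n_pieces
        for vi in range(n_variants):
            for vj in range(n_variants):
                links.append(
                    (f"{base_id}_v{vi}p{pi}", "+",
                     f"{base_id}_v{vj}p{nxt}", "+")
                )
    return GfaComponent(tuple(segments), "tangled_circular",
                        links=tuple(links))


# ---------------------------------------------------------------------------
# default community and on-disk fixture


def default_community(seed: int) -> CommunitySpec:
    """12-taxon digester-like community: skewed log-normal abundances with
    the dominant taxon forced to >= 60%, plus two plasmids and one virus."""
    rng = np.random.default_rng([seed, 101])
    n = n_default_taxa()
    replicons: list[RepliconSpec] = []
    for i in range(n):
        path = default_taxon_path(i)
        archaeal = path.startswith("Archaea")
        copies = int(rng.integers(1, 4 if archaeal else 6))
        n_trna = 20 if rng.random() < 0.8 else int(rng.integers(18, 20))
        isotypes = tuple(
            sorted(
                rng.choice(
                    len(refdata.STANDARD_TRNA_ISOTYPES), size=n_trna,
                    replace=False,
                )
            )
        )
        replicons.append(
            RepliconSpec(
                id=f"chr{i + 1:02d}",
                length_bp=int(rng.integers(1_000_000, 1_300_001)),
                topology="circular",
                replicon_class="chromosome",
                gc_fraction=float(rng.uniform(0.35, 0.65)),
                rrn_operon_copies=copies,
                trna_types=tuple(
                    refdata.STANDARD_TRNA_ISOTYPES[j] for j in isotypes
                ),
                taxon_path=path,
            )
        )
    # skewed log-normal weights, dominant forced to the first taxon
    w = rng.lognormal(0.0, 1.5, size=n)
    w = np.sort(w)[::-1]
    w = w / w.sum()
    if w[0] < 0.6:
        w = np.concatenate([[0.7], 0.3 * w[1:] / w[1:].sum()])
    weights = {r.id: float(w[i]) for i, r in enumerate(replicons)}
    # mobile elements riding along with two hosts
    extras = [
        RepliconSpec("pls01", int(rng.integers(40_000, 80_001)), "circular",
                     "plasmid", float(rng.uniform(0.4, 0.6)),
                     taxon_path=replicons[1].taxon_path),
        RepliconSpec("pls02", int(rng.integers(40_000, 80_001)), "circular",
                     "plasmid", float(rng.uniform(0.4, 0.6)),
                     taxon_path=replicons[2].taxon_path),
        RepliconSpec("vir01", int(rng.integers(30_000, 50_001)), "circular",
                     "virus", float(rng.uniform(0.4, 0.6)),
                     taxon_path=replicons[3].taxon_path),
    ]
    for ex, host in zip(extras, (replicons[1], replicons[2], replicons[3])):
        weights[ex.id] = 0.05 * weights[host.id]
    replicons += extras
    total = sum(weights.values())
    abundances = tuple(weights[r.id] / total for r in replicons)
    return CommunitySpec(tuple(replicons), abundances, seed=seed)


def community_gfa(
    sequences: dict[str, str],
    truth: CommunityTruth,
    seed: int,
    overlap: int = 100,
    tangle_replicon: str | None = "auto",
    junk_linear: int = 3,
) -> tuple[str, list[dict]]:
    """Assembly graph for a simulated community.

    Circular replicons become self-linked segments with ``overlap``
    duplicated head bases; optionally the lowest-abundance chromosome is
    presented instead as a strain tangle (what a real assembler produces
    when strains co-occur); a few junk linear contigs are added.
    """
    chroms = {
        rid: rt for rid, rt in truth.replicons.items()
        if rt.spec.replicon_class == "chromosome"
    }
    if tangle_replicon == "auto":
        tangle_replicon = min(chroms, key=lambda r: chroms[r].abundance)
    comps: list[GfaComponent] = []
    for rid in sorted(truth.replicons):
        seq = sequences[rid]
        if rid == tangle_replicon:
            comps.append(
                tangle_from_variants(rid, seq, n_variants=2, divergence=0.01,
                                     n_pieces=3, seed=seed)
            )
        else:
            comps.append(
                GfaComponent((((rid, seq + seq[:overlap])),),
                             "circular", overlap=overlap)
            )
    rng = np.random.default_rng([seed, 202])
    for j in range(junk_linear):
        n = int(rng.integers(1_500, 60_000))
        seq = _random_bases(rng, n, 0.5).tobytes().decode("ascii")
        comps.append(GfaComponent(((f"lin{j:02d}", seq),), "linear"))
    return build_gfa(comps, seed)


def make_variant_genomes(
    n_species: int,
    n_variants: int,
    length_bp: int,
    divergence: float,
    seed: int,
) -> tuple[dict[str, str], dict[str, str]]:
    """Unrelated species, each with near-identical variants.

    Returns (genomes, species map genome_id -> species_id); used to
    exercise clustering/dereplication where chromosome-scale realism is not
    needed.
    """
    rng = np.random.default_rng([seed, 303])
    genomes: dict[str, str] = {}
    species: dict[str, str] = {}
    for s in range(n_species):
        base = _random_bases(rng, length_bp, 0.5).tobytes().decode("ascii")
        for v in range(n_variants):
            gid = f"sp{s:02d}_v{v}"
            genomes[gid] = base if v == 0 else _mutate_str(
                base, divergence, rng
            )
            species[gid] = f"sp{s:02d}"
    return genomes, species


# ---------------------------------------------------------------------------
# fixture writer


def write_fixture(
    outdir: str | os.PathLike,
    seed: int,
    depth_target: float = 10.0,
    model: ReadModel | None = None,
    community: CommunitySpec | None = None,
    tangle_replicon: str | None = "auto",
) -> CommunityTruth:
    """Write a complete synthetic fixture to ``outdir``.

    Emits reads.fastq, assembly.gfa (+ labels), replicon FASTA, truth
    tables (reads, replicons, features GFF3), a reference 16S training set
    with taxonomy, and the 16S copy-number table.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    model = model or ReadModel()
    community = community or default_community(seed)
    sequences, truth = build_community(community, seed)
    reads, truth = simulate_hifi_reads(
        community, model, depth_target, seed, sequences, truth
    )
    write_fastq(out / "reads.fastq", reads)
    write_fasta(out / "replicons.fasta", sorted(sequences.items()))
    gfa, labels = community_gfa(sequences, truth, seed,
                                tangle_replicon=tangle_replicon)
    (out / "assembly.gfa").write_text(gfa)
    with open(out / "gfa_labels.tsv", "w") as fh:
        fh.write("segment\tcomponent\ttopology\tlength\n")
        for row in labels:
            fh.write(
                f"{row['segment']}\t{row['component']}\t{row['topology']}"
                f"\t{row['length']}\n"
            )
    _write_truth_tables(out, truth)
    # classifier training references + copy numbers
    genera = sorted(
        {
            genus_index_for(rt.spec.taxon_path)
            for rt in truth.replicons.values()
            if rt.spec.replicon_class == "chromosome"
        }
    )
    refs = refdata.reference_ssu_set(max(genera) + 1)
    write_fasta(out / "ref_16s.fasta", [(n, s) for n, _, s in refs])
    with open(out / "ref_16s_taxonomy.tsv", "w") as fh:
        fh.write("sequence_id\ttaxon_path\n")
        for n, path, _ in refs:
            fh.write(f"{n}\t{path}\n")
    with open(out / "copy_numbers.tsv", "w") as fh:
        fh.write("taxon\tcopies\n")
        for taxon, c in sorted(truth.copy_number_table().items()):
            fh.write(f"{taxon}\t{c}\n")
    with open(out / "community.json", "w") as fh:
        json.dump(
            {
                "seed": seed,
                "depth_target": depth_target,
                "replicons": [asdict(r) for r in community.replicons],
                "abundances": list(community.abundances),
            },
            fh,
            indent=1,
        )
    return truth


def _write_truth_tables(out: Path, truth: CommunityTruth) -> None:
    with open(out / "truth_replicons.tsv", "w") as fh:
        fh.write(
            "replicon\tclass\ttopology\tlength\tgc\ttaxon_path\t"
            "rrn_copies\tn_trna_types\tabundance\n"
        )
        for rid in sorted(truth.replicons):
            rt = truth.replicons[rid]
            s = rt.spec
            fh.write(
                f"{rid}\t{s.replicon_class}\t{s.topology}\t{s.length_bp}\t"
                f"{s.gc_fraction:.3f}\t{s.taxon_path}\t"
                f"{s.rrn_operon_copies}\t{len(set(s.trna_types))}\t"
                f"{rt.abundance:.8g}\n"
            )
    with open(out / "truth_reads.tsv", "w") as fh:
        fh.write(
            "read_id\treplicon\tstart\tend\tstrand\tlength\tn_sub\t"
            "ssu_intervals\n"
        )
        for rid in sorted(truth.reads):
            rt = truth.reads[rid]
            ssu = ";".join(
                f"{s}-{e}-{st}-{op}" for s, e, st, op in rt.ssu
            )
            fh.write(
                f"{rt.read_id}\t{rt.replicon_id}\t{rt.start}\t{rt.end}\t"
                f"{rt.strand}\t{rt.length}\t{rt.n_sub}\t{ssu}\n"
            )
    with open(out / "truth_features.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for rid in sorted(truth.replicons):
            for f in truth.replicons[rid].features:
                attrs = f"ID={f.feature_id}"
                if f.isotype:
                    attrs += f";isotype={f.isotype}"
                if f.operon is not None:
                    attrs += f";operon={f.operon}"
                fh.write(
                    f"{rid}\tsynthio\t{f.kind}\t{f.start + 1}\t{f.end}\t.\t"
                    f"{f.strand}\t.\t{attrs}\n"
                )
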