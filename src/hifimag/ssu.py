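"""Amplification-free full-length 16S rRNA profiling from HiFi reads.

Full-length 16S genes are detected directly on reads by co-occurrence of
conserved-region anchor k-mers (a lightweight stand-in for covariance-model
search, valid on data where the anchors are present), filtered by the
standard full-length bounds (1,200-1,700 bp) and a Q20 mean-accuracy
cutoff, classified with a naive-Bayes bootstrap (8-mer) classifier, and
aggregated into a community profile with per-taxon 16S copy-number
correction so abundances reflect cells rather than gene copies.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from . import refdata
from ._kmers import encode, kmer_codes, revcomp
from .io import mean_error_prob, qual_to_phred
from .taxonomy import RANKS, split_path

log = logging.getLogger(__name__)

SENTINEL = np.uint64(0xFFFFFFFFFFFFFFFF)
ANCHOR_LEN = 15
DEFAULT_COPY_NUMBER = 2.0


@dataclass
class SsuGene:
    read_id: str
    start: int  # on the original read, 0-based half-open
    end: int
    strand: str
    sequence: str  # oriented 5'->3' of the gene
    quality: str  # oriented with the sequence
    truncated: bool  # candidate hit a read edge

    @property
    def length_bp(self) -> int:
        return len(self.sequence)

    @property
    def mean_error_prob(self) -> float:
        return mean_error_prob(self.quality)

    @property
    def mean_accuracy(self) -> float:
        return 1.0 - self.mean_error_prob


# ---------------------------------------------------------------------------
# detection


@lru_cache(maxsize=1)
def _anchor_index() -> tuple[np.ndarray, np.ndarray]:
    """(sorted codes, ref offsets) of conserved anchors + 1-mismatch halo."""
    codes: list[int] = []
    offs: list[int] = []
    for off, anchor in refdata.ssu_anchor_kmers(ANCHOR_LEN):
        for var in refdata.anchor_variants_1mm(anchor):
            c = kmer_codes(encode(var), ANCHOR_LEN)
            codes.append(int(c[0]))
            offs.append(off)
    codes_arr = np.array(codes, dtype=np.uint64)
    offs_arr = np.array(offs, dtype=np.int64)
    order = np.argsort(codes_arr, kind="stable")
    codes_arr, offs_arr = codes_arr[order], offs_arr[order]
    keep = np.ones(codes_arr.size, dtype=bool)
    keep[1:] = codes_arr[1:] != codes_arr[:-1]
    return codes_arr[keep], offs_arr[keep]


def _scan_strand(seq: str) -> list[tuple[int, int]]:
    """(read position, reference offset) anchor hits on one strand."""
    codes = kmer_codes(encode(seq), ANCHOR_LEN)
    acodes, aoffs = _anchor_index()
    lo = np.searchsorted(acodes, codes, side="left")
    lo = np.minimum(lo, acodes.size - 1)
    hit = (acodes[lo] == codes) & (codes != SENTINEL)
    pos = np.flatnonzero(hit)
    return list(zip(pos.tolist(), aoffs[lo[pos]].tolist()))


def _cluster_hits(
    hits: list[tuple[int, int]], diag_tol: int
) -> list[list[tuple[int, int]]]:
    """Group anchor hits by diagonal (read pos - ref offset)."""
    ordered = sorted(hits, key=lambda h: (h[0] - h[1], h[1]))
    groups: list[list[tuple[int, int]]] = []
    for h in ordered:
        d = h[0] - h[1]
        if groups and d - (groups[-1][-1][0] - groups[-1][-1][1]) <= diag_tol:
            groups[-1].append(h)
        else:
            groups.append([h])
    return groups


def detect_ssu(
    read_id: str,
    sequence: str,
    quality: str,
    min_anchors: int = 3,
    diag_tol: int | None = None,
) -> list[SsuGene]:
    """Detect full-length 16S candidates on one read (both strands).

    A candidate is reported where >= ``min_anchors`` conserved anchors
    co-occur on one strand at mutually consistent spacing (diagonal
    tolerance defaults to 20% of the reference length); boundaries are the
    outermost anchors extended to the reference ends. Reverse-strand hits
    are reverse-complemented with their qualities reversed.
    """
    if diag_tol is None:
        diag_tol = int(0.2 * refdata.SSU_LEN)
    L = len(sequence)
    out: list[SsuGene] = []
    for strand, seq, qual in (
        ("+", sequence, quality),
        ("-", revcomp(sequence), quality[::-1]),
    ):
        hits = _scan_strand(seq)
        for group in _cluster_hits(hits, diag_tol):
            if len({off for _, off in group}) < min_anchors:
                continue
            first, last = group[0], group[-1]
            start = first[0] - first[1]
            end = last[0] + (refdata.SSU_LEN - last[1])
            truncated = start < 0 or end > L
            s, e = max(start, 0), min(end, L)
            gene_seq, gene_q = seq[s:e], qual[s:e]
            if strand == "-":
                rs, re = L - e, L - s
            else:
                rs, re = s, e
            out.append(
                SsuGene(read_id, rs, re, strand, gene_seq, gene_q, truncated)
            )
    out.sort(key=lambda g: (g.start, g.strand))
    return out


def detect_ssu_in_reads(
    reads, min_anchors: int = 3
) -> list[SsuGene]:
    """Run detection over an iterable of (read_id, sequence, quality)."""
    genes: list[SsuGene] = []
    for read_id, seq, qual in reads:
        genes.extend(detect_ssu(read_id, seq, qual, min_anchors=min_anchors))
    return genes


def filter_ssu(
    candidates: list[SsuGene],
    min_bp: int = 1200,
    max_bp: int = 1700,
    min_accuracy: float = 0.99,
) -> list[SsuGene]:
    """Length (1,200-1,700 bp) and Q20 mean-accuracy filter."""
    return [
        g
        for g in candidates
        if min_bp <= g.length_bp <= max_bp and g.mean_accuracy >= min_accuracy
    ]


# ---------------------------------------------------------------------------
# naive-Bayes bootstrap classifier


@dataclass
class SsuClassifier:
    """Per-genus 8-mer word-presence model with (count + 0.5)/(n + 1)
    smoothing and bootstrap confidence over 1/8 word subsamples."""

    word_size: int
    genera: list[str]  # genus labels, index = column
    paths: dict[str, str]  # genus -> full taxon path
    vocab: np.ndarray  # sorted word codes
    logp: np.ndarray  # (len(vocab), n_genera) log10 P(w|genus)
    default_logp: np.ndarray  # per-genus log10 P for unseen words

    def to_json(self) -> str:
        return json.dumps(
            {
                "word_size": self.word_size,
                "genera": self.genera,
                "paths": self.paths,
                "vocab": [int(v) for v in self.vocab],
                "logp": self.logp.tolist(),
                "default_logp": self.default_logp.tolist(),
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "SsuClassifier":
        d = json.loads(text)
        return cls(
            d["word_size"],
            d["genera"],
            d["paths"],
            np.array(d["vocab"], dtype=np.uint64),
            np.array(d["logp"], dtype=np.float64),
            np.array(d["default_logp"], dtype=np.float64),
        )


def _word_set(seq: str, word_size: int) -> np.ndarray:
    codes = kmer_codes(encode(seq), word_size)
    return np.unique(codes[codes != SENTINEL])


def train_classifier(
    references: list[tuple[str, str, str]],
    word_size: int = 8,
) -> SsuClassifier:
    """Train on (sequence id, taxon path, sequence) triples.

    Requires >= 2 genera; duplicate sequence ids are an error. P(w|genus)
    = (number of genus sequences containing w + 0.5) / (genus size + 1).
    """
    ids = [r[0] for r in references]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate sequence ids in training set")
    by_genus: dict[str, list[str]] = {}
    paths: dict[str, str] = {}
    for _, path, seq in references:
        genus = split_path(path).get("genus", path.split(";")[-1])
        by_genus.setdefault(genus, []).append(seq)
        paths[genus] = path
    if len(by_genus) < 2:
        raise ValueError("training set must contain at least 2 genera")
    genera = sorted(by_genus)
    word_sets = {
        g: [_word_set(s, word_size) for s in by_genus[g]] for g in genera
    }
    vocab = np.unique(np.concatenate(sum(word_sets.values(), [])))
    logp = np.empty((vocab.size, len(genera)), dtype=np.float64)
    default_logp = np.empty(len(genera), dtype=np.float64)
    for gi, g in enumerate(genera):
        m = np.zeros(vocab.size, dtype=np.float64)
        for ws in word_sets[g]:
            m[np.searchsorted(vocab, ws)] += 1.0
        n = len(word_sets[g])
        logp[:, gi] = np.log10((m + 0.5) / (n + 1.0))
        default_logp[gi] = np.log10(0.5 / (n + 1.0))
    return SsuClassifier(word_size, genera, paths, vocab, logp, default_logp)


@dataclass
class Classification:
    gene: SsuGene
    calls: dict[str, tuple[str, float]]  # rank -> (taxon, confidence)
    assigned_rank: str | None  # deepest rank with confident call
    genus: str
    confidence: float

    def taxon_at(self, rank: str, conf_min: float = 0.8) -> str:
        call = self.calls.get(rank)
        if call is None or call[1] < conf_min:
            return "unclassified"
        return call[0]


def classify_ssu(
    gene: SsuGene,
    model: SsuClassifier,
    n_bootstrap: int = 100,
    conf_min: float = 0.8,
    seed: int = 0,
) -> Classification:
    """Classify one gene: genus by maximum joint likelihood over the full
    word set; confidence per rank as the fraction of bootstrap trials
    (each scoring a random 1/8 subsample of the gene's words) agreeing at
    that rank; calls below ``conf_min`` roll up to the last confident
    rank."""
    if gene.length_bp < model.word_size:
        raise ValueError("gene shorter than the classifier word size")
    words = _word_set(gene.sequence, model.word_size)
    idx = np.searchsorted(model.vocab, words)
    idx = np.minimum(idx, model.vocab.size - 1)
    known = model.vocab[idx] == words
    mat = np.where(
        known[:, None], model.logp[idx], model.default_logp[None, :]
    )
    full = mat.sum(axis=0)
    genus_i = int(np.argmax(full))
    genus = model.genera[genus_i]
    rng = np.random.default_rng([seed, len(words)])
    n_sub = max(1, words.size // 8)
    trials = rng.integers(0, words.size, size=(n_bootstrap, n_sub))
    scores = mat[trials].sum(axis=1)  # (n_bootstrap, n_genera)
    winners = np.argmax(scores, axis=1)
    called_path = split_path(model.paths[genus])
    winner_paths = [split_path(model.paths[model.genera[w]])
                    for w in winners]
    calls: dict[str, tuple[str, float]] = {}
    assigned = None
    for rank in RANKS:
        taxon = called_path.get(rank)
        if taxon is None:
            break
        agree = sum(
            1 for wp in winner_paths if wp.get(rank) == taxon
        ) / n_bootstrap
        calls[rank] = (taxon, agree)
        if agree >= conf_min:
            assigned = rank
    genus_conf = calls.get("genus", (genus, 0.0))[1]
    return Classification(gene, calls, assigned, genus, genus_conf)


def classify_all(
    genes: list[SsuGene],
    model: SsuClassifier,
    n_bootstrap: int = 100,
    conf_min: float = 0.8,
    seed: int = 0,
) -> list[Classification]:
    return [
        classify_ssu(g, model, n_bootstrap, conf_min, seed=seed + i)
        for i, g in enumerate(genes)
    ]


# ---------------------------------------------------------------------------
# copy-number-adjusted profile


@dataclass(frozen=True)
class CopyNumberTable:
    table: dict[str, float]  # taxon label (any rank) -> copies per genome
    default: float = DEFAULT_COPY_NUMBER

    def validate(self) -> None:
        if self.default <= 0 or any(c <= 0 for c in self.table.values()):
            raise ValueError("16S copy numbers must be positive")

    def lookup(self, taxon: str, path: dict[str, str] | None = None) -> float:
        if taxon in self.table:
            return self.table[taxon]
        if path:
            for rank in reversed(RANKS):  # nearest ancestor first
                label = path.get(rank)
                if label and label in self.table:
                    return self.table[label]
        return self.default


def copy_adjusted_profile(
    classifications: list[Classification],
    copies: CopyNumberTable,
    rank: str = "genus",
    conf_min: float = 0.8,
) -> dict[str, float]:
    """Cell-level relative abundance at ``rank``.

    abundance(t) = (count_t / copies_t) / sum_u (count_u / copies_u);
    genes not confidently classified at the rank are pooled under
    "unclassified" at the default copy number.
    """
    copies.validate()
    counts: dict[str, int] = {}
    paths: dict[str, dict[str, str]] = {}
    for c in classifications:
        taxon = c.taxon_at(rank, conf_min)
        counts[taxon] = counts.get(taxon, 0) + 1
        if taxon != "unclassified":
            paths[taxon] = {r: v[0] for r, v in c.calls.items()}
    adjusted = {
        t: n / copies.lookup(t, paths.get(t)) for t, n in counts.items()
    }
    total = sum(adjusted.values())
    return {t: v / total for t, v in sorted(adjusted.items())}


def raw_count_profile(
    classifications: list[Classification],
    rank: str = "genus",
    conf_min: float = 0.8,
) -> dict[str, int]:
    counts: dict[str, int] = {}
    for c in classifications:
        taxon = c.taxon_at(rank, conf_min)
        counts[taxon] = counts.get(taxon, 0) + 1
    return dict(sorted(counts.items()))
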